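import numpy as np
import pytest

from hybridms.synthetic import CohortConfig, RaterConfig, simulate_cohort, simulate_raters


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient cohort used across tests; deterministic."""
    return simulate_cohort(CohortConfig(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def small_ratings(small_cohort):
    n = small_cohort.n_records
    return simulate_raters(
        small_cohort,
        RaterConfig(n_raters=10, records_per_rater=min(30, n), seed=7),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def pair_count_auc(scores, labels):
    """O(n^2) positive-negative pair oracle for the tie-aware AUC."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)
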