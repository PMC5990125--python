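"""Synthetic-cohort generator: determinism, label structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import spearmanr

from hybridms.errors import ConfigError
from hybridms.evaluation import mann_whitney_auc
from hybridms.synthetic import (
    CohortConfig,
    RaterConfig,
    make_fixtures,
    simulate_cohort,
    simulate_ensemble_agent,
    simulate_raters,
)


def closed_form_prevalence(h, config):
    """Independent oracle: P(remaining <= h) = E_z[1 - exp(-h e^{bz} / s)],
    z ~ N(0,1), integrated numerically."""
    def integrand(z):
        rate = np.exp(config.risk_coefficient * z) / config.hazard_scale
        return np.exp(-z * z / 2) / np.sqrt(2 * np.pi) * (1 - np.exp(-h * rate))

    val, _ = integrate.quad(integrand, -8, 8)
    return val


class TestCohort:
    def test_same_seed_identical_cohorts(self):
        a = simulate_cohort(CohortConfig(seed=5))
        b = simulate_cohort(CohortConfig(seed=5))
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        assert np.array_equal(a.truth.remaining_days, b.truth.remaining_days)

    @pytest.mark.parametrize("seed", range(10))
    def test_labels_monotone_across_horizons(self, seed):
        c = simulate_cohort(CohortConfig(n_patients=20, seed=seed))
        lab = c.outcomes[["T_180", "T_360", "T_720"]].to_numpy()
        assert (np.diff(lab, axis=1) >= 0).all()
        prev = lab.mean(axis=0)
        assert prev[0] <= prev[1] <= prev[2]

    def test_no_transitions_in_slow_hazard_limit(self):
        c = simulate_cohort(CohortConfig(seed=1, hazard_scale=1e12))
        assert (c.outcomes.to_numpy() == 0).all()

    def test_shape_matches_config(self):
        c = simulate_cohort(CohortConfig(n_patients=30, seed=2))
        assert c.records["patient_id"].nunique() == 30
        assert c.records["record_id"].is_unique
        # every record maps to exactly one patient
        assert (c.records.groupby("record_id")["patient_id"].nunique() == 1).all()

    def test_degenerate_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(hazard_scale=0.0)
        with pytest.raises(ConfigError):
            CohortConfig(n_patients=1)

    def test_prevalence_matches_closed_form(self):
        """Monte-Carlo prevalence across cohorts agrees with the hazard law's
        survival function to within 3 standard errors (scaled-down version of
        the full calibration check in the acceptance suite)."""
        cfg = CohortConfig(seed=0)
        n_cohorts = 300
        means = {h: [] for h in cfg.horizons}
        for seed in range(n_cohorts):
            c = simulate_cohort(CohortConfig(seed=seed))
            for h in cfg.horizons:
                means[h].append(c.outcomes[f"T_{h}"].mean())
        for h in cfg.horizons:
            arr = np.array(means[h])
            se = arr.std(ddof=1) / np.sqrt(n_cohorts)
            assert abs(arr.mean() - closed_form_prevalence(h, cfg)) < 3 * se


class TestRaters:
    def test_perfect_skill_no_coupling_all_raters_agree(self):
        c = simulate_cohort(CohortConfig(n_patients=15, seed=3))
        r = simulate_raters(c, RaterConfig(n_raters=8, records_per_rater=40,
                                           skill=1.0, dispersion_coupling=0.0,
                                           seed=3))
        spread = r.groupby(["record_id", "horizon"])["score"].nunique()
        assert (spread == 1).all()
        # and the shared value is the discretised smoothed outcome indicator
        m = c.truth.membership[360]
        sub = r[r.horizon == 360].drop_duplicates("record_id")
        expected = np.clip(np.floor(m[sub.record_id.to_numpy()] * 6), 0, 5)
        assert np.array_equal(sub.score.to_numpy(), expected.astype(int))

    def test_zero_skill_auc_centred_at_half(self):
        """With no skill the per-rater AUC distribution centres on chance."""
        c = simulate_cohort(CohortConfig(seed=4))
        aucs = []
        for seed in range(8):
            r = simulate_raters(c, RaterConfig(n_raters=30, records_per_rater=50,
                                               skill=0.0, dispersion_coupling=0.0,
                                               seed=seed))
            y = c.outcomes["T_720"]
            for _, grp in r[r.horizon == 720].groupby("rater_id"):
                labels = y.loc[grp.record_id].to_numpy()
                if 0 < labels.sum() < labels.size:
                    aucs.append(mann_whitney_auc(grp.score.to_numpy(), labels))
        aucs = np.array(aucs)
        assert len(aucs) > 200
        se = aucs.std(ddof=1) / np.sqrt(aucs.size)
        assert abs(aucs.mean() - 0.5) < 3 * se

    def test_mean_coverage_equals_expectation(self):
        c = simulate_cohort(CohortConfig(seed=6))
        cfg = RaterConfig(n_raters=42, records_per_rater=50, seed=6)
        r = simulate_raters(c, cfg)
        per_record = r[r.horizon == 180].groupby("record_id").size()
        total = per_record.reindex(c.outcomes.index, fill_value=0)
        assert total.mean() == pytest.approx(42 * 50 / c.n_records)

    def test_too_many_records_per_rater_rejected(self):
        c = simulate_cohort(CohortConfig(n_patients=4, seed=1))
        with pytest.raises(ConfigError):
            simulate_raters(c, RaterConfig(records_per_rater=c.n_records + 1))

    def test_same_seed_identical_ratings(self, small_cohort):
        kw = dict(n_raters=5, records_per_rater=20, seed=9)
        a = simulate_raters(small_cohort, RaterConfig(**kw))
        b = simulate_raters(small_cohort, RaterConfig(**kw))
        pd.testing.assert_frame_equal(a, b)


class TestEnsembleAgent:
    def test_no_noise_all_unitary_identical(self, small_cohort):
        fs = simulate_ensemble_agent(small_cohort, dispersion_coupling=0.0,
                                     base_noise=0.0, seed=2)
        for h, f in fs.items():
            assert (f.dispersion == 0).all()
            assert (f.unitary == f.unitary[:, [0]]).all()

    def test_perfect_skill_near_perfect_auc(self):
        for seed in range(3):
            c = simulate_cohort(CohortConfig(seed=seed))
            fs = simulate_ensemble_agent(c, n_unitary=50, skill=1.0, seed=seed)
            y = c.outcomes["T_360"].to_numpy()
            assert mann_whitney_auc(fs[360].mean, y) > 0.98

    def test_same_seed_identical_forecasts(self, small_cohort):
        a = simulate_ensemble_agent(small_cohort, seed=8)
        b = simulate_ensemble_agent(small_cohort, seed=8)
        for h in a:
            assert np.array_equal(a[h].unitary, b[h].unitary)

    def test_dispersion_tracks_misclassification(self):
        """With coupling on, scattered records are the ones the agent gets
        wrong: rank correlation between dispersion and absolute forecast
        error is positive."""
        for seed in (0, 1, 2):
            c = simulate_cohort(CohortConfig(seed=seed))
            f = simulate_ensemble_agent(c, dispersion_coupling=1.0, seed=seed)[360]
            y = c.outcomes["T_360"].to_numpy()
            rho, _ = spearmanr(f.dispersion, np.abs(y - f.mean))
            assert rho > 0


def test_make_fixtures_round_trip(tmp_path):
    from hybridms import records_io

    paths = make_fixtures(tmp_path, CohortConfig(n_patients=10, seed=11),
                          RaterConfig(n_raters=4, records_per_rater=20, seed=11),
                          {"seed": 11})
    outcomes = records_io.read_outcomes(paths["outcomes"])
    ratings = records_io.read_human_predictions(paths["ratings"])
    scores = records_io.read_ensemble_predictions(paths["scores"])
    assert len(outcomes) == len(scores)
    assert ratings["record_id"].isin(outcomes.index).all()
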