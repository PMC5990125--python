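"""ROC/AUC computation and bootstrap inference.

The AUC is the Mann-Whitney probability that a randomly chosen positive
record outranks a randomly chosen negative one, with half credit for score
ties; it equals the trapezoidal area under the tie-aware ROC curve.
Uncertainty is quantified by a nonparametric bootstrap: records (or whole
patients, since records within a patient are correlated) are resampled with
replacement and the AUC is recomputed on each resample.  Percentile
confidence intervals are the default; bias-corrected accelerated (BCa)
intervals are available.  Differences between two agents scored on the same
records use a *paired* bootstrap: the same resample indices are applied to
both score vectors, so shared sampling noise cancels from the difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

from .errors import ConfigError, UndefinedAUCError

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "BootstrapSummary",
    "AucDifference",
    "mann_whitney_auc",
    "roc_auc",
    "bootstrap_auc",
    "auc_difference",
]


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y.astype(np.int8)


def mann_whitney_auc(scores, labels) -> float:
    """Tie-aware AUC via the rank-sum identity.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg),
    with average ranks for tied scores (each tied positive-negative pair
    contributes 1/2).

    Raises
    ------
    UndefinedAUCError
        If only one label class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(n_pos, n_neg)
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class RocResult:
    """AUC plus the tie-aware ROC curve it summarises."""

    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(scores, labels) -> RocResult:
    """AUC and ROC curve for one score vector against binary labels.

    The curve always starts at (0, 0) and ends at (1, 1); tied scores share a
    single threshold so the curve, integrated by trapezoids, reproduces the
    Mann-Whitney AUC exactly.
    """
    auc = mann_whitney_auc(scores, labels)
    y = _as_binary_labels(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    if fpr[0] != 0.0 or tpr[0] != 0.0:  # roc_curve prepends (0, 0) already
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return RocResult(auc=auc, n_pos=int(y.sum()), n_neg=int((1 - y).sum()),
                     fpr=fpr, tpr=tpr)


@dataclass(frozen=True)
class BootstrapSummary:
    """Resampled AUC distribution with quartiles and a confidence interval.

    ``quartiles`` and ``full_range`` carry the box-plot semantics used for
    reporting: boxes are quartiles, whiskers the full range of replicates.
    """

    point_auc: float
    replicates: np.ndarray = field(repr=False)
    quartiles: tuple[float, float, float]
    ci: tuple[float, float]
    level: float
    n_boot: int
    seed: int | None
    unit: str
    n_redrawn: int = 0

    @property
    def full_range(self) -> tuple[float, float]:
        return float(self.replicates.min()), float(self.replicates.max())


def _resample_units(rng, n_records, unit, patient_ids):
    """Indices for one bootstrap resample at record or patient level."""
    if unit == "record":
        return rng.integers(0, n_records, size=n_records)
    groups = patient_ids  # list of index arrays, one per patient
    chosen = rng.integers(0, len(groups), size=len(groups))
    return np.concatenate([groups[c] for c in chosen])


def _prepare_unit(unit, n, patient_ids):
    if unit not in ("record", "patient"):
        raise ConfigError(f"unknown bootstrap unit {unit!r}")
    if unit == "patient":
        if patient_ids is None:
            raise ConfigError("patient-unit bootstrap requires patient_ids")
        pid = np.asarray(patient_ids)
        if pid.size != n:
            raise ConfigError("patient_ids must align with scores")
        return [np.flatnonzero(pid == p) for p in np.unique(pid)]
    return None


def _bootstrap_replicates(rng, stat, n, n_boot, unit, groups, max_redraw=100):
    """Draw n_boot resamples, redrawing any that make the statistic undefined."""
    reps = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraw):
            idx = _resample_units(rng, n, unit, groups)
            try:
                reps[b] = stat(idx)
                break
            except UndefinedAUCError:
                n_redrawn += 1
        else:
            raise ConfigError(
                "bootstrap could not draw a two-class resample; "
                "labels are too unbalanced"
            )
    return reps, n_redrawn


def _percentile_ci(reps, level):
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _bca_ci(reps, point, jackknife, level):
    alpha = (1.0 - level) / 2.0
    prop = np.clip(np.mean(reps < point), 1e-12, 1 - 1e-12)
    z0 = norm.ppf(prop)
    jk = np.asarray(jackknife)
    d = jk.mean() - jk
    denom = 6.0 * (d**2).sum() ** 1.5
    a = (d**3).sum() / denom if denom > 0 else 0.0
    qs = []
    for z in (norm.ppf(alpha), norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        qs.append(np.clip(norm.cdf(adj), 0.0, 1.0))
    lo, hi = np.quantile(reps, qs)
    return float(lo), float(hi)


def bootstrap_auc(
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    unit: str = "record",
    patient_ids=None,
    seed: int | None = None,
    method: str = "percentile",
) -> BootstrapSummary:
    """Bootstrap distribution of the AUC under resampling with replacement.

    Parameters
    ----------
    unit
        ``"record"`` resamples individual records; ``"patient"`` resamples
        whole patients (requires ``patient_ids``), a robustness option for
        within-patient correlation.
    method
        ``"percentile"`` (default) or ``"bca"``.

    One-class resamples are redrawn rather than dropped so exactly ``n_boot``
    replicates are returned; the redraw count is logged and recorded.
    """
    if n_boot < 2:
        raise ConfigError("n_boot must be at least 2")
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    point = mann_whitney_auc(s, y)
    groups = _prepare_unit(unit, s.size, patient_ids)
    rng = np.random.default_rng(seed)

    reps, n_redrawn = _bootstrap_replicates(
        rng, lambda idx: mann_whitney_auc(s[idx], y[idx]), s.size, n_boot, unit, groups
    )
    if n_redrawn:
        logger.info("bootstrap_auc: redrew %d one-class resamples", n_redrawn)

    if method == "percentile":
        ci = _percentile_ci(reps, level)
    elif method == "bca":
        jack = []
        for i in range(s.size):
            mask = np.arange(s.size) != i
            try:
                jack.append(mann_whitney_auc(s[mask], y[mask]))
            except UndefinedAUCError:
                jack.append(point)
        ci = _bca_ci(reps, point, jack, level)
    else:
        raise ConfigError(f"unknown CI method {method!r}")

    q1, med, q3 = np.quantile(reps, [0.25, 0.5, 0.75])
    return BootstrapSummary(
        point_auc=point, replicates=reps, quartiles=(float(q1), float(med), float(q3)),
        ci=ci, level=level, n_boot=n_boot, seed=seed, unit=unit, n_redrawn=n_redrawn,
    )


@dataclass(frozen=True)
class AucDifference:
    """Paired-bootstrap summary of AUC_a - AUC_b on shared records."""

    delta: float
    ci: tuple[float, float]
    p_value: float
    excludes_zero: bool
    level: float
    replicates: np.ndarray = field(repr=False)
    n_boot: int = 0
    seed: int | None = None


def auc_difference(
    scores_a,
    scores_b,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    unit: str = "record",
    patient_ids=None,
    seed: int | None = None,
) -> AucDifference:
    """Paired bootstrap for the difference of two agents' AUCs.

    The same resample indices are applied to both score vectors, so the
    replicate differences reflect genuine performance gaps rather than
    independent sampling noise.  Significance is reported two ways: whether
    the percentile CI excludes zero, and a two-sided bootstrap p-value from
    the tail mass of the replicate distribution at zero (with the standard
    +1 continuity correction).
    """
    if n_boot < 2:
        raise ConfigError("n_boot must be at least 2")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _as_binary_labels(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise KeyError("scores_a, scores_b and labels must cover the same records")
    delta = mann_whitney_auc(a, y) - mann_whitney_auc(b, y)
    groups = _prepare_unit(unit, a.size, patient_ids)
    rng = np.random.default_rng(seed)

    def stat(idx):
        return mann_whitney_auc(a[idx], y[idx]) - mann_whitney_auc(b[idx], y[idx])

    reps, n_redrawn = _bootstrap_replicates(rng, stat, a.size, n_boot, unit, groups)
    if n_redrawn:
        logger.info("auc_difference: redrew %d one-class resamples", n_redrawn)
    ci = _percentile_ci(reps, level)
    smaller_tail = min(int((reps <= 0).sum()), int((reps >= 0).sum()))
    p = min(1.0, 2.0 * (smaller_tail + 1) / (n_boot + 1))
    return AucDifference(
        delta=float(delta), ci=ci, p_value=float(p),
        excludes_zero=not (ci[0] <= 0.0 <= ci[1]), level=level,
        replicates=reps, n_boot=n_boot, seed=seed,
    )
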