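"""Crowd aggregation of human ratings: Singles, Pairs, and Group conditions.

Ratings on the 6-point questionnaire scale are normalised to [0, 1] by
dividing by 5 (any strictly monotone map yields the same AUCs; the fixed
choice matters only for downstream consistency weighting).  Three collective
conditions are evaluated at each horizon:

* **Singles** — each rater's AUC on exactly the records they rated; the
  condition is summarised as mean +/- SD across raters.  Raters whose rated
  records contain a single label class have no defined AUC and are excluded
  (and logged).
* **Pairs** — per record rated by at least two raters, the mean of two
  randomly chosen ratings; AUC over those records.  Stochastic when records
  have more than two ratings, so it is reported as a mean over repeated
  random draws by default.
* **Group** — per record, the mean of all its normalised ratings; a single
  deterministic AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import substream
from .errors import EmptyResultError, ValidationError
from .evaluation import mann_whitney_auc
from .errors import UndefinedAUCError

logger = logging.getLogger(__name__)

__all__ = ["normalize_rating", "singles_auc", "pairs_auc", "group_auc",
           "SinglesResult", "PairsResult", "GroupResult"]


def normalize_rating(score):
    """Map integer questionnaire scores 0..5 onto [0, 1] by dividing by 5."""
    s = np.asarray(score)
    if not np.issubdtype(s.dtype, np.number) or np.any(s != np.round(s)):
        raise ValidationError("ratings must be integers")
    if np.any((s < 0) | (s > 5)):
        raise ValidationError("ratings must lie in 0..5")
    out = s / 5.0
    return float(out) if np.isscalar(score) or s.ndim == 0 else out


def _ratings_at(ratings: pd.DataFrame, horizon: int) -> pd.DataFrame:
    sub = ratings.loc[ratings["horizon"] == int(horizon)].copy()
    if sub.empty:
        raise EmptyResultError(f"no ratings at horizon {horizon}")
    sub["p"] = normalize_rating(sub["score"].to_numpy())
    return sub


def _labels_for(outcomes: pd.DataFrame, record_ids, horizon: int) -> np.ndarray:
    return outcomes.loc[record_ids, f"T_{horizon}"].to_numpy()


@dataclass(frozen=True)
class SinglesResult:
    """Per-rater AUCs with their mean and SD; one-class raters excluded."""

    per_rater: pd.DataFrame  # rater_id, auc, n_records
    mean: float
    sd: float
    excluded_raters: list = field(default_factory=list)
    horizon: int = 0


def singles_auc(ratings: pd.DataFrame, outcomes: pd.DataFrame,
                horizon: int) -> SinglesResult:
    """AUC of each individual rater on the records they rated."""
    sub = _ratings_at(ratings, horizon)
    rows, excluded = [], []
    for rater, grp in sub.groupby("rater_id", sort=False):
        y = _labels_for(outcomes, grp["record_id"].to_numpy(), horizon)
        try:
            auc = mann_whitney_auc(grp["p"].to_numpy(), y)
        except UndefinedAUCError:
            excluded.append(rater)
            continue
        rows.append((rater, auc, len(grp)))
    if excluded:
        logger.info("singles_auc@%d: excluded %d one-class rater(s): %s",
                    horizon, len(excluded), excluded[:10])
    if not rows:
        raise EmptyResultError(f"no rater has both label classes at {horizon} d")
    per_rater = pd.DataFrame(rows, columns=["rater_id", "auc", "n_records"])
    return SinglesResult(per_rater=per_rater,
                         mean=float(per_rater["auc"].mean()),
                         sd=float(per_rater["auc"].std(ddof=1)),
                         excluded_raters=excluded, horizon=int(horizon))


@dataclass(frozen=True)
class PairsResult:
    """AUC of two-rating averages over records with >= 2 ratings."""

    auc: float                 # mean over draws
    per_draw: np.ndarray = field(repr=False)
    n_records: int = 0
    horizon: int = 0


def pairs_auc(ratings: pd.DataFrame, outcomes: pd.DataFrame, horizon: int,
              seed: int | None = None, n_repeats: int = 100) -> PairsResult:
    """Pairs condition: average two randomly chosen ratings per eligible record.

    Records with fewer than two ratings are excluded.  When every eligible
    record has exactly two ratings the result is deterministic; otherwise the
    random 2-subsampling is repeated ``n_repeats`` times and the mean AUC is
    reported, with the per-draw values available for inspection.
    """
    sub = _ratings_at(ratings, horizon)
    counts = sub.groupby("record_id")["p"].count()
    eligible = counts.index[counts >= 2].to_numpy()
    if eligible.size == 0:
        raise EmptyResultError(f"no record has >= 2 ratings at {horizon} d")
    pool = {rid: grp["p"].to_numpy()
            for rid, grp in sub.groupby("record_id") if rid in set(eligible)}
    y = _labels_for(outcomes, eligible, horizon)
    deterministic = all(v.size == 2 for v in pool.values())
    draws = 1 if deterministic else int(n_repeats)
    rng = substream(seed if seed is not None else 0, "pairs", horizon)
    aucs = np.empty(draws)
    for d in range(draws):
        means = np.array([
            pool[rid].mean() if pool[rid].size == 2
            else rng.choice(pool[rid], size=2, replace=False).mean()
            for rid in eligible
        ])
        aucs[d] = mann_whitney_auc(means, y)
    return PairsResult(auc=float(aucs.mean()), per_draw=aucs,
                       n_records=int(eligible.size), horizon=int(horizon))


@dataclass(frozen=True)
class GroupResult:
    """AUC of the all-rater mean per record (deterministic)."""

    auc: float
    record_means: pd.Series = field(repr=False)
    n_records: int = 0
    horizon: int = 0


def group_auc(ratings: pd.DataFrame, outcomes: pd.DataFrame,
              horizon: int) -> GroupResult:
    """Group condition: mean of all normalised ratings per rated record."""
    sub = _ratings_at(ratings, horizon)
    means = sub.groupby("record_id")["p"].mean()
    unrated = outcomes.index.difference(means.index)
    if len(unrated):
        logger.info("group_auc@%d: %d unrated record(s) excluded",
                    horizon, len(unrated))
    y = _labels_for(outcomes, means.index.to_numpy(), horizon)
    auc = mann_whitney_auc(means.to_numpy(), y)
    return GroupResult(auc=float(auc), record_means=means,
                       n_records=int(means.size), horizon=int(horizon))
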