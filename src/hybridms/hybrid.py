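"""Concordance-ranked hybrid combination of a human and a machine agent.

Each agent's per-record *concordance* is measured by the sample standard
deviation of its unitary predictions (students' normalised scores, or the
probabilities of the trained models): small dispersion means the agent's
members agree, i.e. the agent is "sure".  Records are then ranked per agent
by concordance and the rank is normalised to [0, 1] — 1 for the most
consistent record, 0 for the most scattered, average ranks for ties.

Combination modes
-----------------
``weighted`` (default)
    Squared-rank-weighted average of the two forecast means,
    ``(r_H^2 * m_H + r_M^2 * m_M) / (r_H^2 + r_M^2)``; squaring emphasises
    the more consistent agent.  Falls back to the plain mean when both
    squared ranks are 0.  This uses the squared consistency ranks as weights
    and yields a probability in [0, 1].
``sum_sq_ranks``
    The bare sum ``r_H^2 + r_M^2`` in [0, 2].  It scores consistency only —
    the forecast direction does not enter — and is retained as a documented
    variant for fidelity to the consistency-rank recipe.
``linear_ranks``
    Like ``weighted`` but with unsquared rank weights; an ablation that
    dilutes the most-consistent-agent signal.
``unranked``
    Inverse-dispersion weights without ranking; the second ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, UndefinedConcordanceError
from .forecasts import ForecastSet

logger = logging.getLogger(__name__)

MODES = ("weighted", "sum_sq_ranks", "linear_ranks", "unranked")

__all__ = ["MODES", "concordance", "concordance_ranks", "hybrid_score",
           "combine_forecasts", "HybridResult"]


def concordance(unitary) -> float:
    """Dispersion of one record's unitary predictions (sample SD, ddof=1).

    Zero exactly when all unitary predictions agree; smaller = more
    concordant.  Requires at least two values.
    """
    v = np.asarray(unitary, dtype=float)
    if v.size < 2:
        raise UndefinedConcordanceError(
            f"concordance needs >= 2 unitary predictions, got {v.size}"
        )
    if np.ptp(v) == 0:  # exact zero at full agreement
        return 0.0
    return float(v.std(ddof=1))


def concordance_ranks(dispersions) -> np.ndarray:
    """Normalised consistency ranks: 1 = most consistent, 0 = most scattered.

    Records are ranked by dispersion ascending with average ranks for ties;
    the raw rank R in 1..N is mapped to (N - R) / (N - 1).  If every
    dispersion is equal all records get 0.5.  NaN dispersions (records whose
    agent had a single unitary value) also get the neutral rank 0.5.
    """
    d = np.asarray(dispersions, dtype=float)
    if d.size < 2:
        raise ConfigError("concordance ranking needs >= 2 records")
    out = np.full(d.size, 0.5)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n >= 2:
        r = rankdata(d[ok])
        out[ok] = (n - r) / (n - 1)
        if np.ptp(d[ok]) == 0:
            logger.warning("all %d dispersions equal; all ranks set to 0.5", n)
    elif n == 1:
        out[ok] = 0.5
    if (~ok).any():
        logger.info("%d record(s) without dispersion assigned neutral rank 0.5",
                    int((~ok).sum()))
    return out


def hybrid_score(m_human, m_machine, r_human, r_machine,
                 mode: str = "weighted",
                 d_human=None, d_machine=None):
    """Combine two agents' forecast means under a named mode (vectorised).

    ``d_human`` / ``d_machine`` (raw dispersions) are required only for the
    ``unranked`` mode.
    """
    mh, mm = np.asarray(m_human, float), np.asarray(m_machine, float)
    rh, rm = np.asarray(r_human, float), np.asarray(r_machine, float)
    if mode == "sum_sq_ranks":
        return rh**2 + rm**2
    if mode == "weighted":
        wh, wm = rh**2, rm**2
    elif mode == "linear_ranks":
        wh, wm = rh, rm
    elif mode == "unranked":
        if d_human is None or d_machine is None:
            raise ConfigError("unranked mode needs raw dispersions")
        eps = 1e-6
        wh = 1.0 / (np.asarray(d_human, float) + eps)
        wm = 1.0 / (np.asarray(d_machine, float) + eps)
    else:
        raise ConfigError(f"unknown hybrid mode {mode!r}; choose from {MODES}")
    tot = wh + wm
    with np.errstate(invalid="ignore"):
        score = np.where(tot > 0, (wh * mh + wm * mm) / np.where(tot > 0, tot, 1.0),
                         0.5 * (mh + mm))
    # agreeing agents pass through exactly (no round-off from the division)
    return np.where(mh == mm, mh, score)


@dataclass(frozen=True)
class HybridResult:
    """Per-record hybrid scores with the ranks that produced them."""

    table: pd.DataFrame  # record_id, m_human, m_machine, r_human, r_machine, score
    mode: str
    horizon: int

    @property
    def record_ids(self) -> np.ndarray:
        return self.table["record_id"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()


def combine_forecasts(human: ForecastSet, machine: ForecastSet,
                      mode: str = "weighted", strict: bool = False) -> HybridResult:
    """Hybridise two agents' forecasts over their shared records.

    Ranks are computed per agent over the shared record set at this horizon.
    Records present in only one agent are skipped with a log entry, or raise
    a KeyError under ``strict=True``.
    """
    if human.horizon != machine.horizon:
        raise ConfigError("agents must be combined at the same horizon")
    h_idx = {rid: i for i, rid in enumerate(human.record_ids)}
    m_idx = {rid: i for i, rid in enumerate(machine.record_ids)}
    shared = [rid for rid in human.record_ids if rid in m_idx]
    missing = (set(human.record_ids) ^ set(machine.record_ids))
    if missing:
        if strict:
            raise KeyError(
                f"record sets differ; symmetric difference: {sorted(missing)[:20]}"
            )
        logger.info("combine_forecasts: skipped %d unshared record(s)",
                    len(missing))
    if len(shared) < 2:
        raise ConfigError("need >= 2 shared records to rank")
    hi = np.array([h_idx[r] for r in shared])
    mi = np.array([m_idx[r] for r in shared])
    mh, mm = human.mean[hi], machine.mean[mi]
    dh, dm = human.dispersion[hi], machine.dispersion[mi]
    rh = concordance_ranks(dh)
    rm = concordance_ranks(dm)
    # records without a defined dispersion get their agent's mean dispersion
    # so inverse-dispersion weighting stays finite
    def _fill(d):
        finite = d[~np.isnan(d)]
        fill = finite.mean() if finite.size else 0.0
        return np.where(np.isnan(d), fill, d)

    score = hybrid_score(mh, mm, rh, rm, mode=mode,
                         d_human=_fill(dh), d_machine=_fill(dm))
    table = pd.DataFrame({
        "record_id": shared, "m_human": mh, "m_machine": mm,
        "d_human": dh, "d_machine": dm, "r_human": rh, "r_machine": rm,
        "score": score,
    })
    return HybridResult(table=table, mode=mode, horizon=human.horizon)
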