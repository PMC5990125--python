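"""Synthetic cohorts, raters and ensemble agents.

The real clinical feature table is not public, so downstream stages are
exercised on a generative stand-in with the same statistical skeleton:

* Each patient carries a latent risk ``z ~ N(0, 1)``.  Time from a visit to
  the relapsing-remitting -> secondary-progressive transition follows an
  exponential law with proportional hazard ``rate = exp(beta * z) / scale``
  (log-linear in risk), so horizon labels are 1 iff the remaining time is at
  most the horizon and are automatically monotone across horizons.  The
  closed-form survival function gives an independent check of label
  prevalences.  The default ``hazard_scale = 1495`` days and
  ``risk_coefficient = 0.531`` were calibrated once against the study
  cohort's reported prevalences (12.3% / 23.7% / 40.0% at 180/360/720 days).
* Visit counts per patient follow a truncated geometric distribution whose
  mean reproduces the unbalanced 527-records / 84-patients shape.
* Features are affine in the record's log remaining time plus independent
  Gaussian noise scaled by ``1 / signal_strength``, so a learner can in
  principle recover the outcome and ``signal_strength -> inf`` makes records
  perfectly separable.
* Raters and simulated ensemble agents observe a smoothed indicator of the
  true outcome, blended with noise according to a ``skill`` in [0, 1]; their
  unitary predictions are additionally scattered in proportion to
  ``dispersion_coupling`` times the record's *hardness* (closeness of the
  remaining time to the horizon).  This couples per-record dispersion to
  misclassification probability — the structure the hybrid combiner exploits.

All draws flow from one master seed through named substreams (cohort /
raters / ensemble) so components are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import substream
from .errors import ConfigError
from .forecasts import ForecastSet
from .records_io import HORIZONS

__all__ = [
    "CohortConfig",
    "RaterConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_raters",
    "simulate_ensemble_agent",
    "make_fixtures",
]

#: hazard-law defaults calibrated to the study cohort's label prevalences
DEFAULT_HAZARD_SCALE = 1495.0
DEFAULT_RISK_COEFFICIENT = 0.531


@dataclass(frozen=True)
class CohortConfig:
    """Shape and signal of a synthetic cohort.

    ``membership_sharpness`` controls how steeply the agents' information
    about a record degrades near the decision boundary (the smoothed outcome
    indicator is ``1 / (1 + (u / h) ** sharpness)`` in remaining time ``u``).
    """

    n_patients: int = 84
    mean_visits: float = 527 / 84
    max_visits: int = 20
    n_features: int = 8
    signal_strength: float = 0.17
    hazard_scale: float = DEFAULT_HAZARD_SCALE
    risk_coefficient: float = DEFAULT_RISK_COEFFICIENT
    membership_sharpness: float = 4.0
    horizons: tuple[int, ...] = HORIZONS
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.mean_visits < 1:
            raise ConfigError("mean_visits must be >= 1")
        if self.hazard_scale <= 0:
            raise ConfigError("hazard_scale must be positive")
        if self.signal_strength < 0:
            raise ConfigError("signal_strength must be >= 0")


@dataclass(frozen=True)
class RaterConfig:
    """A crowd of discrete 0-5 raters with tunable skill."""

    n_raters: int = 42
    records_per_rater: int = 50
    skill: float = 0.1
    dispersion_coupling: float = 1.0
    noise_scale: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.skill <= 1:
            raise ConfigError("skill must lie in [0, 1]")
        if self.dispersion_coupling < 0:
            raise ConfigError("dispersion_coupling must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a synthetic cohort.

    ``membership[h]`` is the smoothed outcome indicator in [0, 1] (0.5 at the
    horizon boundary) and ``hardness[h] = 1 - |2 * membership - 1|`` grows
    toward 1 for records whose transition falls near the horizon.
    """

    patient_risk: np.ndarray
    patient_rate: np.ndarray
    record_patient: np.ndarray
    remaining_days: np.ndarray
    membership: dict[int, np.ndarray] = field(repr=False)
    hardness: dict[int, np.ndarray] = field(repr=False)


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated cohort: visit records, outcome labels and hidden truth."""

    records: pd.DataFrame
    outcomes: pd.DataFrame
    truth: SyntheticTruth
    config: CohortConfig

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.records.columns if c.startswith("feature_")]


def _truncated_geometric(rng, mean, max_value, size):
    draws = rng.geometric(p=min(1.0, 1.0 / mean), size=size)
    return np.clip(draws, 1, max_value)


def simulate_cohort(config: CohortConfig | None = None, **kwargs) -> SyntheticCohort:
    """Simulate a cohort of patients with repeated visits and horizon labels.

    Fully deterministic given ``config.seed``.  Keyword arguments override
    config fields for convenience.
    """
    if config is None:
        config = CohortConfig(**kwargs)
    elif kwargs:
        raise ConfigError("pass either a config or keyword overrides, not both")
    rng = substream(config.seed, "cohort")

    z = rng.standard_normal(config.n_patients)
    rate = np.exp(config.risk_coefficient * z) / config.hazard_scale
    n_visits = _truncated_geometric(rng, config.mean_visits, config.max_visits,
                                    config.n_patients)
    record_patient = np.repeat(np.arange(config.n_patients), n_visits)
    # remaining time to transition at each visit; visits are ordered in time,
    # i.e. by decreasing remaining time, which preserves the Exp(rate) marginal
    remaining = rng.exponential(scale=1.0 / rate[record_patient])
    order = np.lexsort((-remaining, record_patient))
    remaining = remaining[order]
    visit_index = np.concatenate([np.arange(k) for k in n_visits])

    n_records = remaining.size
    record_ids = np.arange(n_records)
    membership, hardness, labels = {}, {}, {}
    for h in config.horizons:
        m = 1.0 / (1.0 + (remaining / h) ** config.membership_sharpness)
        membership[h] = m
        hardness[h] = 1.0 - np.abs(2.0 * m - 1.0)
        labels[f"T_{h}"] = (remaining <= h).astype(np.int8)

    signal = -np.log(remaining / config.hazard_scale)
    loadings = rng.uniform(0.5, 1.5, size=config.n_features)
    noise = rng.standard_normal((n_records, config.n_features))
    if config.signal_strength == 0:  # pure-noise features, unit scale
        features = noise
    else:
        features = (signal[:, None] * loadings[None, :]
                    + noise / config.signal_strength)

    records = pd.DataFrame({"record_id": record_ids,
                            "patient_id": record_patient,
                            "visit_index": visit_index})
    for j in range(config.n_features):
        records[f"feature_{j}"] = features[:, j]
    outcomes = pd.DataFrame(labels, index=pd.Index(record_ids, name="record_id"))

    truth = SyntheticTruth(patient_risk=z, patient_rate=rate,
                           record_patient=record_patient,
                           remaining_days=remaining,
                           membership=membership, hardness=hardness)
    return SyntheticCohort(records=records, outcomes=outcomes, truth=truth,
                           config=config)


def simulate_raters(cohort: SyntheticCohort,
                    config: RaterConfig | None = None, **kwargs) -> pd.DataFrame:
    """Simulate a crowd of raters scoring random record subsets on 0..5.

    Each rater receives ``records_per_rater`` records drawn without
    replacement.  The latent rating is a skill-weighted mixture of the
    smoothed outcome indicator and uniform noise, plus Gaussian scatter
    inflated by ``dispersion_coupling * hardness``; it is clipped to [0, 1]
    and discretised into six equal-width bins.

    Returns a long DataFrame (rater_id, record_id, horizon, score).
    """
    if config is None:
        config = RaterConfig(**kwargs)
    elif kwargs:
        raise ConfigError("pass either a config or keyword overrides, not both")
    n_records = cohort.n_records
    if config.records_per_rater > n_records:
        raise ConfigError(
            f"records_per_rater={config.records_per_rater} exceeds the "
            f"{n_records} available records"
        )
    rng = substream(config.seed, "raters")
    truth = cohort.truth
    rows = []
    for rater in range(config.n_raters):
        rec = rng.choice(n_records, size=config.records_per_rater, replace=False)
        for h in cohort.config.horizons:
            m = truth.membership[h][rec]
            hard = truth.hardness[h][rec]
            u = rng.uniform(size=rec.size)
            g = rng.standard_normal(rec.size)
            latent = (config.skill * m + (1.0 - config.skill) * u
                      + config.dispersion_coupling * config.noise_scale * hard * g)
            score = np.clip(np.floor(np.clip(latent, 0.0, 1.0) * 6.0), 0, 5)
            rows.append(pd.DataFrame({
                "rater_id": rater, "record_id": rec, "horizon": h,
                "score": score.astype(np.int8),
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_ensemble_agent(
    cohort: SyntheticCohort,
    n_unitary: int = 50,
    skill: float = 0.2,
    dispersion_coupling: float = 1.0,
    base_noise: float = 0.05,
    noise_scale: float = 0.25,
    seed: int = 0,
    name: str = "ensemble",
) -> dict[int, ForecastSet]:
    """Simulate a machine-like agent emitting ``n_unitary`` probabilities per record.

    The agent's central estimate is a skill-weighted mixture of the smoothed
    outcome indicator and per-record uniform noise; unitary predictions
    scatter around it with spread ``base_noise + dispersion_coupling *
    noise_scale * hardness``, clipped to [0, 1].  Returns one
    :class:`ForecastSet` per horizon.
    """
    if n_unitary < 2:
        raise ConfigError("n_unitary must be >= 2")
    if not 0 <= skill <= 1:
        raise ConfigError("skill must lie in [0, 1]")
    if dispersion_coupling < 0:
        raise ConfigError("dispersion_coupling must be >= 0")
    rng = substream(seed, "ensemble", name)
    truth = cohort.truth
    n_records = cohort.n_records
    record_ids = cohort.records["record_id"].to_numpy()
    out = {}
    for h in cohort.config.horizons:
        m = truth.membership[h]
        hard = truth.hardness[h]
        center = np.clip(skill * m + (1.0 - skill) * rng.uniform(size=n_records),
                         0.0, 1.0)
        spread = base_noise + dispersion_coupling * noise_scale * hard
        g = rng.standard_normal((n_records, n_unitary))
        unitary = np.clip(center[:, None] + spread[:, None] * g, 0.0, 1.0)
        out[h] = ForecastSet.from_unitary(record_ids, unitary, h)
    return out


def make_fixtures(
    outdir,
    cohort_config: CohortConfig | None = None,
    rater_config: RaterConfig | None = None,
    agent_kwargs: dict | None = None,
) -> dict[str, str]:
    """Write a full synthetic study to ``outdir`` in the canonical CSV layouts.

    Produces ``records.csv`` (features), ``outcomes.csv``, ``ratings.csv``
    and ``scores.csv`` (per-horizon mean probabilities of a simulated
    ensemble agent).  Returns the path of each written file.
    """
    from pathlib import Path

    from . import records_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cohort_config or CohortConfig())
    ratings = simulate_raters(cohort, rater_config or RaterConfig())
    forecasts = simulate_ensemble_agent(cohort, **(agent_kwargs or {}))
    scores = pd.DataFrame(
        {f"Score_{h}": fs.mean for h, fs in forecasts.items()},
        index=cohort.outcomes.index,
    )
    paths = {
        "records": outdir / "records.csv",
        "outcomes": outdir / "outcomes.csv",
        "ratings": outdir / "ratings.csv",
        "scores": outdir / "scores.csv",
    }
    cohort.records.to_csv(paths["records"], index=False)
    records_io.write_outcomes(cohort.outcomes, paths["outcomes"])
    records_io.write_human_predictions(ratings, paths["ratings"])
    records_io.write_ensemble_predictions(scores, paths["scores"])
    return {k: str(v) for k, v in paths.items()}
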