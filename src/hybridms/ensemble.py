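"""Modified leave-one-patient-out ensemble protocol.

Clinical records from the same patient are strongly correlated, so a naive
record-level leave-one-out would let a model recognise the held-out patient
from their other visits and overstate performance.  The protocol here
removes that leakage:

1. exclude *all* visits of one patient;
2. build ``n_sets`` (default 50) training sets, each containing exactly one
   randomly chosen record per remaining patient (83 records for an
   84-patient cohort);
3. train one classifier per training set;
4. score every visit of the excluded patient with each of the trained
   models and average the class-1 probabilities.

Repeating over all patients yields, for every record, ``n_sets`` unitary
probabilities from models that never saw that patient, plus their mean and
dispersion — the machine agent's forecast and its consistency signal.

The base learner is pluggable: any object with ``fit(X, y)`` and
``predict_proba(X)`` (class-1 probability in the second column) works; the
default is a random-forest classifier.  Training sets whose labels collapse
to a single class yield the constant class probability so that every record
always receives exactly ``n_sets`` unitary values.  Missing feature values
are median-imputed using statistics of the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._rand import substream
from .errors import ConfigError
from .forecasts import ForecastSet

__all__ = ["TrainingSetPlan", "build_training_sets", "fit_predict_loo",
           "default_base_learner"]


@dataclass(frozen=True)
class TrainingSetPlan:
    """Training sets for one excluded patient: one record per other patient."""

    excluded_patient: object
    sets: list  # of int arrays of record_ids
    set_size: int

    def __post_init__(self):
        for s in self.sets:
            if len(s) != self.set_size:
                raise ConfigError("every training set must have one record "
                                  "per remaining patient")


def _records_by_patient(records: pd.DataFrame) -> dict:
    # record ids sorted within patient so plans are row-order invariant
    return {pid: np.sort(grp["record_id"].to_numpy())
            for pid, grp in records.groupby("patient_id", sort=True)}


def build_training_sets(records: pd.DataFrame, excluded_patient,
                        n_sets: int = 50, seed: int = 0,
                        rng: np.random.Generator | None = None) -> TrainingSetPlan:
    """Random one-record-per-patient training sets excluding one patient.

    Visit choices are independent across sets and patients and reproducible
    from the seed.  Patients keyed by ``patient_id``; iteration order of the
    input does not matter.
    """
    by_patient = _records_by_patient(records)
    if excluded_patient not in by_patient:
        raise KeyError(f"unknown patient {excluded_patient!r}")
    if len(by_patient) < 2:
        raise ConfigError("need at least 2 patients")
    remaining = [p for p in by_patient if p != excluded_patient]
    if rng is None:
        rng = substream(seed, "loo", excluded_patient)
    sets = []
    for _ in range(n_sets):
        chosen = np.array([by_patient[p][rng.integers(len(by_patient[p]))]
                           for p in remaining])
        sets.append(chosen)
    return TrainingSetPlan(excluded_patient=excluded_patient, sets=sets,
                           set_size=len(remaining))


def default_base_learner(random_state=None):
    """Random-forest classifier used when no learner factory is supplied."""
    return RandomForestClassifier(n_estimators=100, random_state=random_state)


class _ConstantModel:
    """Degenerate-class rule: predict the single observed class's probability."""

    def __init__(self, constant: float):
        self.constant = float(constant)

    def predict_proba_one(self, X):
        return np.full(len(X), self.constant)


def _fit_one(X, y, learner_factory, random_state):
    classes = np.unique(y)
    if classes.size == 1:
        return _ConstantModel(classes[0]), None
    model = learner_factory(random_state=random_state)
    medians = np.nanmedian(X, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    Xf = np.where(np.isnan(X), medians[None, :], X)
    model.fit(Xf, y)
    return model, medians


def _predict_one(model, medians, X):
    if isinstance(model, _ConstantModel):
        return model.predict_proba_one(X)
    Xf = np.where(np.isnan(X), medians[None, :], X)
    proba = model.predict_proba(Xf)
    col = list(model.classes_).index(1)
    return proba[:, col]


def fit_predict_loo(
    records: pd.DataFrame,
    outcomes: pd.DataFrame,
    horizon: int,
    base_learner=None,
    n_sets: int = 50,
    seed: int = 0,
) -> ForecastSet:
    """Run the full leave-one-patient-out protocol at one horizon.

    Parameters
    ----------
    records
        Visit table with ``record_id``, ``patient_id`` and ``feature_*``
        columns.
    outcomes
        Record-indexed label table with a ``T_<horizon>`` column.
    base_learner
        Factory ``f(random_state=...) -> estimator``; defaults to a
        100-tree random forest.

    Returns a :class:`ForecastSet` covering every record, each with exactly
    ``n_sets`` unitary probabilities from models trained without any of that
    record's patient's data.  Randomness is keyed per (excluded patient,
    set index), so results do not depend on patient iteration order.
    """
    if base_learner is None:
        base_learner = default_base_learner
    feat_cols = [c for c in records.columns if c.startswith("feature_")]
    if not feat_cols:
        raise ConfigError("records table has no feature_* columns")
    label_col = f"T_{horizon}"
    if label_col not in outcomes.columns:
        raise ConfigError(f"outcomes lack column {label_col}")

    X_all = records[feat_cols].to_numpy(dtype=float)
    rid_all = records["record_id"].to_numpy()
    pos = {rid: i for i, rid in enumerate(rid_all)}
    y_all = outcomes.loc[rid_all, label_col].to_numpy()

    by_patient = _records_by_patient(records)
    n_records = len(records)
    unitary = np.empty((n_records, n_sets))

    for patient, own_records in by_patient.items():
        plan = build_training_sets(records, patient, n_sets=n_sets,
                                   rng=substream(seed, "loo", patient, "plan"))
        own_idx = np.array([pos[r] for r in own_records])
        X_own = X_all[own_idx]
        for k, train_ids in enumerate(plan.sets):
            tr_idx = np.array([pos[r] for r in train_ids])
            model_seed = int(substream(seed, "loo", patient, "fit", k)
                             .integers(2**31 - 1))
            model, medians = _fit_one(X_all[tr_idx], y_all[tr_idx],
                                      base_learner, model_seed)
            unitary[own_idx, k] = _predict_one(model, medians, X_own)

    return ForecastSet.from_unitary(rid_all, np.clip(unitary, 0.0, 1.0), horizon)
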