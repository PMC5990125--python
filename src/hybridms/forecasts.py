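"""Per-record agent forecasts: unitary predictions, their mean and dispersion.

An *agent* (a crowd of raters, or an ensemble of trained models) produces
several elementary forecasts per clinical record; the agent's forecast is
their mean and its internal (dis)agreement is the sample standard deviation
of the unitary values.  Low dispersion is read as the agent being sure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ForecastSet"]


@dataclass(frozen=True)
class ForecastSet:
    """Forecasts of one agent at one horizon over a set of records.

    ``unitary`` is an (n_records, n_unitary) matrix when every record has the
    same number of elementary forecasts (trained models), and ``None`` for
    ragged sources (human raters with uneven coverage), in which case mean
    and dispersion were computed from the ragged lists at construction.
    Dispersion is the sample SD (ddof=1); records with a single unitary value
    get NaN dispersion.
    """

    record_ids: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray
    horizon: int
    unitary: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        rid = np.asarray(self.record_ids)
        m = np.asarray(self.mean, dtype=float)
        d = np.asarray(self.dispersion, dtype=float)
        if not (rid.size == m.size == d.size):
            raise ValueError("record_ids, mean and dispersion must align")
        if rid.size != np.unique(rid).size:
            raise ValueError("duplicate record_ids in forecast set")
        if np.nanmin(m, initial=0.0) < 0 or np.nanmax(m, initial=0.0) > 1:
            raise ValueError("forecast means must lie in [0, 1]")
        if np.nanmin(d, initial=0.0) < 0:
            raise ValueError("dispersion must be nonnegative")
        object.__setattr__(self, "record_ids", rid)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "dispersion", d)

    def __len__(self) -> int:
        return self.record_ids.size

    @property
    def n_unitary(self) -> int | None:
        return None if self.unitary is None else self.unitary.shape[1]

    @classmethod
    def from_unitary(cls, record_ids, unitary, horizon) -> "ForecastSet":
        """Build from a rectangular matrix of unitary probabilities."""
        u = np.asarray(unitary, dtype=float)
        if u.ndim != 2 or u.shape[1] < 1:
            raise ValueError("unitary must be (n_records, n_unitary)")
        if u.min() < 0 or u.max() > 1:
            raise ValueError("unitary probabilities must lie in [0, 1]")
        if u.shape[1] > 1:
            disp = u.std(axis=1, ddof=1)
            disp[np.ptp(u, axis=1) == 0] = 0.0  # exact zero at full agreement
        else:
            disp = np.full(u.shape[0], np.nan)
        return cls(record_ids=np.asarray(record_ids), mean=u.mean(axis=1),
                   dispersion=disp, horizon=int(horizon), unitary=u)

    @classmethod
    def from_ragged(cls, record_ids, unitary_lists, horizon) -> "ForecastSet":
        """Build from per-record lists of unitary values of varying length."""
        means, disps = [], []
        for vals in unitary_lists:
            v = np.asarray(vals, dtype=float)
            if v.size == 0:
                raise ValueError("every record needs at least one unitary value")
            means.append(v.mean())
            disps.append(v.std(ddof=1) if v.size > 1 else np.nan)
        return cls(record_ids=np.asarray(record_ids), mean=np.array(means),
                   dispersion=np.array(disps), horizon=int(horizon))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; unitary columns ``unitary_0..`` when rectangular."""
        df = pd.DataFrame(
            {"record_id": self.record_ids, "mean": self.mean,
             "dispersion": self.dispersion}
        )
        if self.unitary is not None:
            for j in range(self.unitary.shape[1]):
                df[f"unitary_{j}"] = self.unitary[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, horizon) -> "ForecastSet":
        ucols = sorted(
            (c for c in df.columns if c.startswith("unitary_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if ucols:
            return cls.from_unitary(df["record_id"].to_numpy(),
                                    df[ucols].to_numpy(), horizon)
        return cls(record_ids=df["record_id"].to_numpy(),
                   mean=df["mean"].to_numpy(),
                   dispersion=df["dispersion"].to_numpy(), horizon=int(horizon))
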