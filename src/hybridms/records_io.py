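"""Readers and writers for the three study table layouts.

Three tables drive the analysis:

* **outcomes** — one row per clinical record with binary labels ``T_180``,
  ``T_360``, ``T_720`` (0 = still relapsing-remitting at that horizon,
  1 = transitioned to secondary progressive).  Because the SP phase is
  absorbing, labels must be nondecreasing across horizons within a record.
* **human ratings** — one integer score in 0..5 per (rater, record, horizon).
  The normative interchange layout is a long CSV with columns ``rater_id``,
  ``record_id``, ``horizon``, ``score``; the questionnaire-block spreadsheet
  layout (one block per rater: a "questionnaire" row, a "Clinical report" row
  of record ids, and three "Prediction @ h" rows) is supported best-effort.
* **ensemble scores** — one probability in [0, 1] per record and horizon,
  columns ``Score_180``, ``Score_360``, ``Score_720``.

CSV is the canonical format; ``.xlsx`` files are read through openpyxl.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MonotonicityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

HORIZONS = (180, 360, 720)
OUTCOME_COLS = [f"T_{h}" for h in HORIZONS]
SCORE_COLS = [f"Score_{h}" for h in HORIZONS]
RATING_COLS = ["rater_id", "record_id", "horizon", "score"]

__all__ = [
    "HORIZONS",
    "read_outcomes",
    "write_outcomes",
    "read_human_predictions",
    "write_human_predictions",
    "read_ensemble_predictions",
    "write_ensemble_predictions",
    "write_results_table",
    "read_results_table",
]


def _load_table(path, dialect: str | None, header="infer") -> pd.DataFrame:
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "xlsx":
        return pd.read_excel(path, header=0 if header == "infer" else header)
    if dialect == "csv":
        try:
            return pd.read_csv(path, header=header)
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{path}: file is empty") from None
    raise SchemaError(f"unknown dialect {dialect!r}")


def _index_by_record(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    id_candidates = [c for c in df.columns if c not in required]
    if "record_id" in id_candidates:
        idx = "record_id"
    elif id_candidates:
        idx = id_candidates[0]  # deposited files: record index in first column
    else:
        raise SchemaError(f"{path}: no record-index column found")
    out = df.set_index(df[idx].astype(int)).loc[:, required]
    out.index.name = "record_id"
    if out.index.duplicated().any():
        dupes = out.index[out.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate record_id(s) {dupes[:10]}")
    return out


def read_outcomes(path, dialect: str | None = None,
                  on_violation: str = "warn") -> pd.DataFrame:
    """Read per-record outcome labels, validating range and monotonicity.

    Parameters
    ----------
    on_violation
        What to do when labels decrease across horizons within a record:
        ``"warn"`` (default; the file is authoritative) or ``"raise"``.

    Returns
    -------
    DataFrame indexed by ``record_id`` with integer columns T_180/T_360/T_720.
    """
    df = _index_by_record(_load_table(path, dialect), OUTCOME_COLS, path)
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        offenders = df.index[bad.any(axis=1)].tolist()
        raise ValidationError(
            f"{path}: non-binary outcome label(s) for record_id(s) {offenders[:10]}"
        )
    df = df.astype(np.int8)
    nonmono = (np.diff(df.to_numpy(), axis=1) < 0).any(axis=1)
    if nonmono.any():
        ids = df.index[nonmono].tolist()
        if on_violation == "raise":
            raise MonotonicityError(ids)
        logger.warning(
            "%s: %d record(s) with non-monotone labels: %s",
            path, len(ids), ids[:10],
        )
    logger.info("%s: read %d outcome records", path, len(df))
    return df


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    outcomes.loc[:, OUTCOME_COLS].to_csv(path, index=True, index_label="record_id")


def _parse_questionnaire_blocks(raw: pd.DataFrame) -> pd.DataFrame:
    """Best-effort parser for the questionnaire spreadsheet block layout."""
    rows = raw.reset_index(drop=True)
    first = rows.iloc[:, 0].astype(str)
    ratings = []
    rater, record_ids = None, None
    for i in range(len(rows)):
        label = first.iloc[i].strip().lower()
        if label.startswith("questionnaire"):
            rater = rows.iloc[i, 1]
            record_ids = None
        elif label.startswith("clinical report"):
            record_ids = pd.to_numeric(rows.iloc[i, 1:], errors="coerce").dropna()
        else:
            m = re.match(r"prediction\s*@?\s*(\d+)", label)
            if m and rater is not None and record_ids is not None:
                horizon = int(m.group(1))
                scores = pd.to_numeric(rows.iloc[i, 1:], errors="coerce")
                for col, rid in record_ids.items():
                    s = scores.get(col)
                    if pd.notna(s):
                        ratings.append((rater, int(rid), horizon, s))
    if not ratings:
        raise SchemaError("no questionnaire blocks recognised")
    return pd.DataFrame(ratings, columns=RATING_COLS)


def read_human_predictions(path, dialect: str | None = None) -> pd.DataFrame:
    """Read human ratings into the long layout (rater_id, record_id, horizon, score).

    A long-format file is recognised by its column names; anything else is
    parsed as the questionnaire block layout.  Scores outside 0..5 and
    duplicate (rater, record, horizon) triples are rejected.
    """
    raw = _load_table(path, dialect)
    if set(RATING_COLS).issubset(raw.columns):
        df = raw.loc[:, RATING_COLS].copy()
    else:
        # block layout has no header row; reload raw cells
        df = _parse_questionnaire_blocks(_load_table(path, dialect, header=None))
    df["record_id"] = df["record_id"].astype(int)
    df["horizon"] = df["horizon"].astype(int)
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = score.isna() | (score < 0) | (score > 5) | (score != score.round())
    if bad.any():
        raise ValidationError(
            f"{path}: {int(bad.sum())} score(s) outside the integer range 0..5; "
            f"first offending record_id(s): "
            f"{df.loc[bad, 'record_id'].head(10).tolist()}"
        )
    df["score"] = score.astype(np.int8)
    dup = df.duplicated(subset=["rater_id", "record_id", "horizon"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (rater, record, horizon) rating(s): "
            f"{df.loc[dup, ['rater_id', 'record_id', 'horizon']].head(5).to_dict('records')}"
        )
    logger.info("%s: read %d ratings from %d raters",
                path, len(df), df["rater_id"].nunique())
    return df.reset_index(drop=True)


def write_human_predictions(ratings: pd.DataFrame, path) -> None:
    ratings.loc[:, RATING_COLS].to_csv(path, index=False)


def read_ensemble_predictions(path, dialect: str | None = None) -> pd.DataFrame:
    """Read per-record ensemble probabilities (Score_180/Score_360/Score_720)."""
    df = _index_by_record(_load_table(path, dialect), SCORE_COLS, path)
    df = df.astype(float)
    vals = df.to_numpy()
    bad = (vals < 0) | (vals > 1) | np.isnan(vals)
    if bad.any():
        offenders = df.index[bad.any(axis=1)].tolist()
        raise ValidationError(
            f"{path}: probability outside [0, 1] for record_id(s) {offenders[:10]}"
        )
    logger.info("%s: read %d score records", path, len(df))
    return df


def write_ensemble_predictions(scores: pd.DataFrame, path) -> None:
    scores.loc[:, SCORE_COLS].to_csv(path, index=True, index_label="record_id")


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a per-agent x per-horizon AUC summary as CSV.

    ``results`` is long-form with columns ``agent``, ``horizon``, ``auc`` and
    optionally ``ci_lower``/``ci_upper``; the output has one row per agent
    and one column block per horizon, in first-appearance agent order and
    ascending horizon order.
    """
    required = {"agent", "horizon", "auc"}
    if results is None or len(results) == 0:
        raise ValidationError("results table is empty")
    if not required.issubset(results.columns):
        raise SchemaError(f"results must have columns {sorted(required)}")
    value_cols = ["auc"] + [c for c in ("ci_lower", "ci_upper") if c in results.columns]
    wide = results.pivot_table(index="agent", columns="horizon", values=value_cols,
                               sort=False)
    horizons = sorted(results["horizon"].unique())
    wide = wide.reindex(columns=pd.MultiIndex.from_product([value_cols, horizons]))
    wide.columns = [f"{v}_{h}" for v, h in wide.columns]
    wide = wide.reindex(index=results["agent"].unique())
    wide.to_csv(path, index=True, index_label="agent")


def read_results_table(path) -> pd.DataFrame:
    """Read a results CSV back into the wide per-agent layout."""
    return pd.read_csv(path, index_col="agent")
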