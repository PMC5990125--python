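"""End-to-end experiment orchestration.

One :class:`RunConfig` drives the whole analysis — crowd aggregation
(Singles / Pairs / Group), machine forecasts (leave-one-patient-out
retraining in synthetic mode, or a deposited score table), concordance-rank
hybrid combination, and bootstrap evaluation — and produces a per-agent,
per-horizon AUC table with confidence intervals, a box-plot summary of the
bootstrap distributions, and a manifest sufficient to reproduce every
number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rand import substream
from . import crowd, ensemble, records_io
from .errors import ConfigError, HybridMSError
from .evaluation import auc_difference, bootstrap_auc
from .forecasts import ForecastSet
from .hybrid import combine_forecasts
from .synthetic import CohortConfig, RaterConfig, simulate_cohort, simulate_raters

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExperimentReport", "run_experiment",
           "human_forecasts", "machine_forecasts_from_scores"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experiment run.

    ``mode`` is ``"synthetic"`` (simulate a cohort and retrain the machine
    agent under the leave-one-patient-out protocol) or ``"deposited"`` (read
    the three canonical tables from ``outcomes_path`` / ``ratings_path`` /
    ``scores_path``).  The master ``seed`` feeds every random component
    through named substreams.
    """

    mode: str = "synthetic"
    seed: int = 0
    horizons: tuple[int, ...] = records_io.HORIZONS
    hybrid_mode: str = "weighted"
    pairs_repeats: int = 100
    n_boot: int = 1000
    ci_level: float = 0.95
    bootstrap_unit: str = "record"
    # synthetic mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    raters: RaterConfig = field(default_factory=RaterConfig)
    loo_n_sets: int = 50
    loo_learner_trees: int = 100
    # deposited mode
    outcomes_path: str | None = None
    ratings_path: str | None = None
    scores_path: str | None = None
    records_path: str | None = None
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, sub in (("cohort", CohortConfig), ("raters", RaterConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = sub(**raw[key])
        if "horizons" in raw:
            raw["horizons"] = tuple(raw["horizons"])
        return cls(**raw)


@dataclass(frozen=True)
class ExperimentReport:
    """Results of one run: AUC table, hybrid contrasts, box summary, manifest."""

    results: pd.DataFrame        # agent, horizon, auc, sd, ci_lower, ci_upper
    comparisons: pd.DataFrame    # horizon, baseline, delta, ci, p, excludes_zero
    box_summary: pd.DataFrame    # agent, horizon, q1, median, q3, min, max
    manifest: dict


def human_forecasts(ratings: pd.DataFrame, horizon: int) -> ForecastSet:
    """Per-record crowd forecast: mean and SD of all normalised ratings."""
    sub = ratings.loc[ratings["horizon"] == int(horizon)]
    groups = sub.groupby("record_id")["score"]
    rids, lists = zip(*((rid, crowd.normalize_rating(g.to_numpy()))
                        for rid, g in groups))
    return ForecastSet.from_ragged(np.asarray(rids), lists, horizon)


def machine_forecasts_from_scores(scores: pd.DataFrame, horizon: int) -> ForecastSet:
    """Machine forecast from a deposited score table (no unitary values).

    Without the per-model unitary predictions the machine dispersion is
    unknown; it is left NaN, which the combiner maps to a uniform neutral
    rank of 0.5 — hybrid results in this mode are therefore mode-dependent
    and flagged as such in the manifest.
    """
    return ForecastSet(record_ids=scores.index.to_numpy(),
                       mean=scores[f"Score_{horizon}"].to_numpy(),
                       dispersion=np.full(len(scores), np.nan),
                       horizon=int(horizon))


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
                raise HybridMSError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)

    return _Ctx()


def _evaluate_agent(scores, labels, patient_ids, cfg: RunConfig, seed_key):
    bseed = int(substream(cfg.seed, "bootstrap", *seed_key).integers(2**31 - 1))
    return bootstrap_auc(scores, labels, n_boot=cfg.n_boot, level=cfg.ci_level,
                         unit=cfg.bootstrap_unit, patient_ids=patient_ids,
                         seed=bseed)


def run_experiment(config: RunConfig) -> ExperimentReport:
    """Execute the full pipeline for every horizon in ``config``.

    Deterministic for a fixed config: running twice yields identical
    reports.  When ``config.outdir`` is set, writes ``results.csv``,
    ``eval.json``, ``box_summary.csv`` and ``manifest.json`` there; on a
    stage failure, partially written outputs are removed.
    """
    if config.mode == "synthetic":
        with _stage("simulate"):
            cohort = simulate_cohort(dataclasses.replace(
                config.cohort,
                seed=int(substream(config.seed, "cohort-seed").integers(2**31 - 1))))
            ratings = simulate_raters(cohort, dataclasses.replace(
                config.raters,
                seed=int(substream(config.seed, "rater-seed").integers(2**31 - 1))))
            outcomes = cohort.outcomes
            records = cohort.records
    elif config.mode == "deposited":
        with _stage("read"):
            if not (config.outcomes_path and config.ratings_path
                    and config.scores_path):
                raise ConfigError("deposited mode needs outcomes/ratings/scores paths")
            outcomes = records_io.read_outcomes(config.outcomes_path)
            ratings = records_io.read_human_predictions(config.ratings_path)
            dep_scores = records_io.read_ensemble_predictions(config.scores_path)
            records = None
    else:
        raise ConfigError(f"unknown mode {config.mode!r}")

    rows, comps, box = [], [], []
    pid_lookup = (records.set_index("record_id")["patient_id"]
                  if records is not None else None)

    for h in config.horizons:
        with _stage(f"machine@{h}"):
            if config.mode == "synthetic":
                machine = ensemble.fit_predict_loo(
                    records, outcomes, h,
                    base_learner=lambda random_state=None: ensemble
                    .default_base_learner(random_state=random_state)
                    .set_params(n_estimators=config.loo_learner_trees),
                    n_sets=config.loo_n_sets,
                    seed=int(substream(config.seed, "loo-seed").integers(2**31 - 1)),
                )
            else:
                machine = machine_forecasts_from_scores(dep_scores, h)

        with _stage(f"crowd@{h}"):
            singles = crowd.singles_auc(ratings, outcomes, h)
            pairs = crowd.pairs_auc(
                ratings, outcomes, h,
                seed=int(substream(config.seed, "pairs-seed").integers(2**31 - 1)),
                n_repeats=config.pairs_repeats)
            group = crowd.group_auc(ratings, outcomes, h)
            human = human_forecasts(ratings, h)

        with _stage(f"hybrid@{h}"):
            hyb = combine_forecasts(human, machine, mode=config.hybrid_mode)

        with _stage(f"evaluate@{h}"):
            y_all = outcomes[f"T_{h}"]

            def pids(rids):
                return (pid_lookup.loc[rids].to_numpy()
                        if pid_lookup is not None else None)

            agents = {
                "random_forest": (machine.record_ids, machine.mean),
                "group": (group.record_means.index.to_numpy(),
                          group.record_means.to_numpy()),
                "hybrid": (hyb.record_ids, hyb.scores),
            }
            summaries = {}
            for name, (rids, sc) in agents.items():
                summ = _evaluate_agent(sc, y_all.loc[rids].to_numpy(),
                                       pids(rids), config, (name, h))
                summaries[name] = (rids, sc, summ)
                rows.append((name, h, summ.point_auc, np.nan, *summ.ci))
                box.append((name, h, *summ.quartiles, *summ.full_range))
            rows.append(("singles", h, singles.mean, singles.sd, np.nan, np.nan))
            rows.append(("pairs", h, pairs.auc, float(pairs.per_draw.std(ddof=1))
                         if pairs.per_draw.size > 1 else np.nan, np.nan, np.nan))

            hyb_ids, hyb_sc, _ = summaries["hybrid"]
            for baseline in ("random_forest", "group"):
                b_ids, b_sc, _ = summaries[baseline]
                b_map = pd.Series(b_sc, index=b_ids)
                shared = [r for r in hyb_ids if r in b_map.index]
                diff = auc_difference(
                    pd.Series(hyb_sc, index=hyb_ids).loc[shared].to_numpy(),
                    b_map.loc[shared].to_numpy(),
                    y_all.loc[shared].to_numpy(),
                    n_boot=config.n_boot, level=config.ci_level,
                    unit=config.bootstrap_unit, patient_ids=pids(np.asarray(shared)),
                    seed=int(substream(config.seed, "diff-seed", baseline, h)
                             .integers(2**31 - 1)),
                )
                comps.append((h, baseline, diff.delta, *diff.ci, diff.p_value,
                              diff.excludes_zero))

    order = ["random_forest", "singles", "pairs", "group", "hybrid"]
    results = (pd.DataFrame(rows, columns=["agent", "horizon", "auc", "sd",
                                           "ci_lower", "ci_upper"])
               .assign(_o=lambda d: d["agent"].map(order.index))
               .sort_values(["horizon", "_o"]).drop(columns="_o")
               .reset_index(drop=True))
    comparisons = pd.DataFrame(
        comps, columns=["horizon", "baseline", "delta", "ci_lower", "ci_upper",
                        "p_value", "excludes_zero"])
    box_summary = pd.DataFrame(
        box, columns=["agent", "horizon", "q1", "median", "q3", "min", "max"])

    manifest = {
        "config": _config_dict(config),
        "versions": _versions(),
        "hybrid_machine_rank_fallback": config.mode == "deposited",
        "n_records": int(len(outcomes)),
        "positives": {h: int(outcomes[f"T_{h}"].sum()) for h in config.horizons},
    }
    report = ExperimentReport(results=results, comparisons=comparisons,
                              box_summary=box_summary, manifest=manifest)
    if config.outdir:
        _write_report(report, config)
    return report


def _config_dict(config) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return enc(config)


def _versions() -> dict:
    import sklearn

    from . import __version__

    return {"hybridms": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__}


def _write_report(report: ExperimentReport, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        p = outdir / "results.csv"
        records_io.write_results_table(report.results, p)
        written.append(p)
        p = outdir / "box_summary.csv"
        report.box_summary.to_csv(p, index=False)
        written.append(p)
        p = outdir / "eval.json"
        p.write_text(json.dumps({
            "results": report.results.to_dict("records"),
            "comparisons": report.comparisons.to_dict("records"),
        }, indent=2, default=float))
        written.append(p)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(report.manifest, indent=2, default=str))
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
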