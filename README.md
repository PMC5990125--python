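# hybridms

Human–machine hybrid prognosis of multiple-sclerosis disease course.

Most MS patients start in a relapsing-remitting (RR) phase and eventually
transition to secondary-progressive (SP) disease; predicting *when* is hard,
and better forecasts would let therapy be matched to each patient's
prognosis. `hybridms` implements and evaluates three forecasting agents on
per-visit clinical records, at horizons of 180, 360 and 720 days:

* **Machine** — an ensemble trained under a *modified leave-one-patient-out*
  protocol: for each excluded patient, 50 training sets are drawn with one
  random visit per remaining patient, one random-forest model is trained per
  set, and the patient's visits are scored by the mean of the 50 class
  probabilities. No model ever sees the patient it scores.
* **Crowd** — human ratings on a 0–5 scale aggregated as *Singles*
  (per-rater AUC, mean ± SD), *Pairs* (mean of two random ratings per
  record) and *Group* (mean of all ratings per record).
* **Hybrid** — per record, each agent's forecast is weighted by the squared
  *concordance rank* of its unitary predictions: records are ranked per
  agent by the sample SD of its elementary forecasts (rank 1 = most
  consistent, 0 = most scattered) and combined as

      score = (r_H²·m_H + r_M²·m_M) / (r_H² + r_M²)

  so whichever agent is internally surer about a record dominates it.
  Literal sum-of-squared-ranks, linear-rank and unranked variants are
  provided as documented ablations.

Evaluation is tie-aware Mann–Whitney AUC with percentile-bootstrap
confidence intervals and paired-bootstrap tests for AUC differences.
Because the original clinical feature table is not public, the package
includes a first-class synthetic cohort generator (proportional-hazards
transition times, coupled dispersion–correctness agents) calibrated to the
study cohort's shape: 84 patients, ~527 visits, prevalences ≈ 12.3 / 23.7 /
40.0%. See `docs/methods.md` for the full model description.

## Worked example

Crowd aggregation on a synthetic cohort (`examples/02_crowd_conditions.py`):

```text
horizon 360 d, 42 raters, 480 records
  Singles: AUC 0.555 +/- 0.101 (mean over raters)
  Pairs:   AUC 0.568 (two random ratings averaged per record)
  Group:   AUC 0.580 (all ratings averaged per record)
```

Individual raters barely beat chance (0.5); averaging two ratings per
record already helps, and averaging all of them helps more — the
collective-intelligence effect the crowd conditions measure.

Hybrid combination with bootstrap inference
(`examples/05_bootstrap_evaluation.py`):

```text
machine  AUC 0.690  95% CI [0.634, 0.749]  quartiles [0.668, 0.689, 0.710]
hybrid   AUC 0.755  95% CI [0.697, 0.806]  quartiles [0.737, 0.755, 0.773]
hybrid - machine: delta AUC +0.066, 95% CI [+0.018, +0.116], p = 0.0100
```

The consistency-weighted hybrid outperforms the machine agent alone, and
the paired-bootstrap CI of the difference excludes zero, so the advantage
survives resampling noise. The other scripts in `examples/` cover cohort
simulation, the leave-one-patient-out ensemble, the combination modes and
the full pipeline; each prints what it computes and what the numbers mean.

A thin CLI mirrors the pipeline stages
(`hybridms make-fixtures | run-ensemble | run-crowd | run-hybrid | evaluate |
run-experiment`); run `hybridms --help` for usage.

## Working with the deposited study tables

The readers in `hybridms.records_io` accept the three table layouts of the
original study (outcome labels `T_180/T_360/T_720`, questionnaire-block or
long-format student ratings, machine scores `Score_180/360/720`) in CSV or
XLSX form. Placing those files under `data/deposited/` as `TrueOutcomes`,
`Student_Predictions` and `RF_Predictions` enables the reproduction test in
`tests/test_acceptance.py`, which checks the published label counts and
per-agent AUCs; the tables are not redistributable with this repository.

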