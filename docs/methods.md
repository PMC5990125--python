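# Methods

`hybridms` implements a human–machine hybrid prognosis pipeline for the
relapsing-remitting (RR) → secondary-progressive (SP) transition in multiple
sclerosis, evaluated at fixed horizons of 180, 360 and 720 days after each
clinical visit. This note describes the statistical procedures, the
synthetic data model used to exercise them, the numerical choices, and the
known limitations.

## The prediction problem

The unit of analysis is a *clinical record* (one visit of one patient). For
each record and horizon *h*, the binary outcome `T_h` is 1 if the patient
had entered the SP phase by *h* days after the visit. Because SP is
absorbing, `T_180 ≤ T_360 ≤ T_720` within a record; the readers validate
this and (by default) warn rather than fail on violations, since a deposited
file is authoritative even when inconsistent.

Two kinds of agents score each record with a probability of transition:

* a **crowd of human raters**, each scoring a subset of records on an
  integer 0–5 scale (normalised to [0, 1] by dividing by 5 — any strictly
  monotone map gives identical AUCs, but the fixed choice matters for
  downstream weighting);
* a **machine ensemble**: many classifiers whose class-1 probabilities are
  averaged.

Performance is always the area under the ROC curve (AUC), computed with the
Mann–Whitney rank formulation and half credit for ties, which equals the
trapezoidal area under the tie-aware ROC curve.

## Modified leave-one-patient-out protocol

Records from one patient are highly correlated, so a record-level
leave-one-out would let a model recognise the held-out patient from their
other visits and overstate skill. The protocol instead:

1. excludes all visits of one patient;
2. draws `n_sets` (default 50) training sets, each containing exactly one
   randomly chosen visit per remaining patient (83 records when 84 patients
   are present);
3. trains one base learner per set (default: random forest, 100 trees,
   library defaults otherwise — the learner is a pluggable
   `fit`/`predict_proba` contract);
4. scores all of the excluded patient's visits with each model and averages
   the class-1 probabilities.

Unitary predictions are the 50 model-level probabilities (not individual
trees): the per-record forecast is their mean and the consistency signal is
their sample SD. Numerical details:

* **One-class training sets** (possible at the 180-day horizon, prevalence
  ≈ 12%) yield a constant forecast equal to the observed class, keeping
  exactly `n_sets` unitary values per record.
* **Missing features** are median-imputed with statistics of the training
  set only (no leakage).
* **Seeding**: each (excluded patient, set index) pair has its own named
  substream, so forecasts are invariant to the order patients appear in the
  input table.

## Crowd conditions

* **Singles** — per-rater AUC on exactly the records that rater scored;
  summarised as mean ± SD across raters. Raters whose records carry a
  single label class have no defined AUC and are excluded (logged).
* **Pairs** — for every record with ≥ 2 ratings, the mean of two ratings
  chosen at random when more are available; AUC over those records. The
  selection is stochastic, so the default reports the mean over 100 random
  draws (single-draw variant available).
* **Group** — mean of all normalised ratings per record; deterministic.

## Concordance-ranked hybrid combination

For each agent and horizon, records are ranked by the dispersion (sample
SD, ddof = 1) of the agent's unitary predictions: ascending dispersion, mean
ranks for ties, and the raw rank *R* ∈ {1..N} mapped to
*(N − R)/(N − 1)* so the most consistent record gets rank 1 and the most
scattered rank 0. When every dispersion is equal the map degenerates to 0.5
everywhere (this falls out of the mean-rank rule). Records whose agent has
a single unitary value (undefined SD) also receive the neutral rank 0.5.

The default **weighted** combination is the squared-rank-weighted average of
the two forecast means,

    score = (r_H² · m_H + r_M² · m_M) / (r_H² + r_M²),

with a fall-back to the plain mean when both squared ranks are zero.
Squaring emphasises the momentarily more consistent agent. The package also
exposes:

* `sum_sq_ranks` — the bare `r_H² + r_M²` in [0, 2]. This variant scores
  *consistency only*: a unanimous "will not transition" and a unanimous
  "will transition" both rank 1, so the forecast direction does not enter
  and it cannot by itself order records for a ROC analysis. It is retained,
  documented, for fidelity to the consistency-rank recipe; the weighted
  form is the default precisely because it uses the squared ranks as
  weights on actual forecasts.
* `linear_ranks` — unsquared rank weights (ablation).
* `unranked` — inverse-dispersion weights, no ranking (ablation; NaN
  dispersions are imputed with the agent's mean dispersion so the weights
  stay finite).

Ranks are computed per horizon and per agent over the shared record set.
Human dispersion uses all available ratings for a record, not the Pairs
subsample. When machine unitary values are unavailable (a deposited score
table contains only means), machine dispersion is NaN, every machine rank is
0.5, and the run manifest flags hybrid results as fallback-mode.

## Bootstrap inference

Uncertainty is quantified by a nonparametric bootstrap (default
`n_boot = 1000`, unstated in comparable analyses; percentile intervals by
default, BCa available). The default resampling unit is the record; a
patient-cluster bootstrap is offered as a robustness option because records
within a patient are correlated, but it is not the primary method.
One-class resamples are redrawn rather than dropped, so exactly `n_boot`
replicates are produced (redraw counts are logged). Box-plot summaries
(quartiles + full range of replicates) are emitted for plotting.

Differences between agents use a **paired** bootstrap: the same resample
indices are applied to both score vectors, cancelling shared sampling noise.
Significance is reported both as whether the percentile CI excludes zero and
as a two-sided bootstrap p-value, `2·(min tail + 1)/(n_boot + 1)`.

## Synthetic data model

The real clinical feature table is not public, so the generator emulates the
statistical skeleton the pipeline needs:

* **Cohort shape.** 84 patients; visit counts per patient from a truncated
  geometric with mean 527/84 ≈ 6.3 (max 20), reproducing the unbalanced
  many-visits-per-patient structure.
* **Transition times.** Patient latent risk *z* ~ N(0, 1); time from a
  visit to transition is exponential with rate `exp(β·z)/s` (proportional
  hazards, log-linear in risk). A patient's visit times are placed before
  their single absorbing transition; by memorylessness each record's
  remaining time is marginally Exp(rate). The closed-form prevalence
  `P(T_h = 1) = E_z[1 − exp(−h·e^{βz}/s)]` is the independent oracle used
  in the calibration tests. Defaults `s = 1495` days and `β = 0.531` were
  fitted once so prevalences sit near the study cohort's 12.3 / 23.7 /
  40.0% at 180 / 360 / 720 days (simulated: ≈ 12.7 / 23.3 / 40.0%).
* **Features.** Affine in the record's log remaining time plus independent
  Gaussian noise scaled by `1/signal_strength`. `signal_strength → ∞` makes
  records perfectly separable (used by the leakage/performance tests); the
  default 0.17 was calibrated once so the leave-one-patient-out random
  forest reaches AUC ≈ 0.7, the machine-agent level of the emulated study.
* **Agents.** Raters and simulated ensemble agents observe the *smoothed
  outcome indicator* `m = 1/(1 + (u/h)^κ)` (κ = 4; 0.5 exactly at the
  horizon boundary) blended with uniform noise by a `skill` in [0, 1];
  unitary predictions additionally scatter with SD proportional to
  `dispersion_coupling × hardness`, where `hardness = 1 − |2m − 1|` peaks
  for records whose transition falls near the horizon. This makes
  per-record dispersion rank-correlate with forecast error — the structure
  the hybrid combiner exploits — and is verified by a property test.
  Default rater skill 0.1 and agent skill 0.2 were calibrated once so
  Singles ≈ 0.57, Group ≈ 0.6–0.65 and machine ≈ 0.7, the emulated study's
  levels.
* **Reproducibility.** All draws flow from one master seed through named
  substreams (cohort / raters / ensemble / pairs / bootstrap), so each
  component is individually reproducible and independent of the others.

What the generator does **not** emulate: real MS clinical variables (EDSS
trajectories, relapse counts), informative visit scheduling, rater
interaction, or miscalibrated raters. Passing tests on synthetic cohorts
therefore demonstrate that the *procedures* behave as specified under the
assumed coupling structure, not that the hybrid gain of any particular real
cohort is reproduced.

## Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations for a
single CPU: the hybrid-improvement property uses 200 default-shape cohorts
with two simulated agents (skill 0.2, coupling 1.0, 50 unitary predictions)
and a 10-cohort pooled paired bootstrap for the CI; generator calibration
uses 2000 cohorts; bootstrap null coverage uses 500 null cohorts of 200
records at `n_boot = 1000`; the full synthetic experiment retrains the
leave-one-patient-out forest with 25 trees per model (50 sets × 84 patients
× 3 horizons ≈ 12,600 fits). The protocol default of 100 trees is
unchanged; tree count is a run-config knob.

## Known limitations

* The weighted combination rule is one reading of a consistency-rank
  recipe whose literal sum-of-squared-ranks form carries no forecast
  direction; both are implemented, and results that depend on the choice
  are flagged.
* Under this generator the three direction-carrying weighting variants
  (squared ranks, linear ranks, inverse dispersion) perform within ~0.002
  AUC of one another: a Gaussian, hardness-proportional dispersion signal
  is cleaner than real rater disagreement, so degradation of the unsquared
  variants reported for real cohorts does not emerge here.
* Singles/Pairs/Group values on synthetic crowds depend on the calibrated
  skill defaults; they emulate magnitudes, not patient-level reality.
* The questionnaire-block spreadsheet parser is best-effort (the long CSV
  layout is normative).
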