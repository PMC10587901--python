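# Methods

## The validation problem

A multi-outcome AF risk tool is a set of Cox risk equations, one per
endpoint (all-cause death; ischaemic stroke / systemic embolism; major
bleeding), published as coefficient tables plus baseline survival values at
fixed horizons.  For a covariate vector `x`, reference vector `x̄`,
per-term transforms `f_j` and betas `β_j`, the predicted risk by horizon
`t` is

    lp(x)      = Σ_j β_j (f_j(x_j) − f_j(x̄_j))
    risk(x, t) = 1 − S₀(t) ^ exp(lp(x))

External validation asks two questions on a cohort the tool was not
developed on: discrimination (do patients who go on to have the event get
higher predicted risks?) and calibration (does the size of the predicted
risk match the event rate actually observed?).  The package also carries the
two guideline point scores — CHA₂DS₂-VASc for stroke (weights 1/1/2/1/2/1/1/1
for CHF, hypertension, age ≥ 75, diabetes, prior stroke/TIA, vascular
disease, age 65–74, female sex) and HAS-BLED for bleeding (one point per
component) — as ranking comparators.

## Endpoint and censoring semantics

One outcome record per (patient, endpoint): days from AF diagnosis to the
first occurrence of the endpoint, or to censoring (death registration, end
of practice registration or last data collection, whichever first).  Times
are day counts; the package never parses calendar dates.  Horizons are
specified in months and placed on the day axis at 30.4375 days/month (so 12
months = 365.25 days); the constant is configurable per run.

## Discrimination under censoring

The horizon AUC classifies patients at horizon `t`: cases have the event by
`t`; controls are event-free with follow-up reaching `t`; patients censored
event-free before `t` have unknown status.  Two treatments of the unknowns:

- `exclude` (default): drop them, compute the Mann–Whitney concordance over
  all case–control pairs with ties counted ½.  The per-model tables then
  report exactly N1/P1 (cases and their mean predicted risk) and N0/P0.
- `ipcw`: Uno-style inverse-probability-of-censoring weighting — case `i`
  weighs `1/G(T_i−)` and controls `1/G(t)`, with `G` the Kaplan–Meier
  estimate of the censoring survival.  This removes the selection bias of
  exclusion at the price of an approximate CI (Hanley–McNeil on effective,
  i.e. weight-deflated, sample sizes — documented approximation).

AUC confidence intervals use the DeLong structural-component variance with
the fixed multiplier 1.96; comparisons of two predictors on the *same*
patients (risk equation vs integer point score) use the paired DeLong test.
Comparisons are always restricted to the intersection of patients evaluable
under both predictors — paired tests require shared subjects.  The DeLong
machinery is implemented here (midrank placements; no installed package
offers the paired test) and is cross-checked in the tests against brute-force
pair counting, `sklearn.metrics.roc_auc_score`, scikit-survival's
`cumulative_dynamic_auc` (for IPCW) and a sign-flip permutation test.

## Observed risk and calibration

Observed risk at a horizon is `1 − S(t)` from the Kaplan–Meier
product-limit estimate (lifelines; events before censorings at tied times;
Greenwood 95% band).  Calibration is summarised two ways:

- **Calibration-in-the-large**: logistic regression of horizon status on an
  offset of `logit(predicted risk)` with slope fixed at 1 — the intercept is
  0 under perfect calibration, positive when risks are underpredicted.  A
  second, un-offset logistic fit gives the calibration slope (1 under
  perfect calibration).  Status uses the same exclusion rule as the AUC.
  "Calibration-in-the-large regression" has no single canonical definition;
  this offset-logistic operationalisation is the package's documented
  convention, chosen because it is testable by construction (simulating
  outcomes from the predictions themselves must give intercept ≈ 0, and it
  does, at |intercept| < 0.05 for n = 20000).  A pseudo-observation
  (survival-scale) variant would avoid the status exclusion but is out of
  scope.  Predictions at exactly 0 or 1 are clipped to [1e−6, 1 − 1e−6]
  with a logged count; constant predictions leave the slope undefined (NaN,
  logged).
- **Quantile calibration**: patients are ranked stably by (predicted risk,
  patient id), ranks are cut into `n_quantiles` near-equal bins (default 5,
  sizes differ by ≤ 1), and each bin's mean predicted risk is tabulated
  against its KM observed risk with the Greenwood CI.  The stable tie-break
  makes bins invariant to input row order.

## The pipeline

`run()` assembles: per-(model, horizon) validation cells; the missingness
table (per covariate and per model); AUC comparisons against
CHA₂DS₂-VASc (death, stroke) and HAS-BLED (bleeding); subgroup blocks (OAC
vs no OAC; CHA₂DS₂-VASc strata low = 0 / moderate = 1 / high ≥ 2; HAS-BLED
strata < 2 vs ≥ 2 — the published subgrouping "< 2 or > 2" leaves 2
unassigned, and assigning it to the higher stratum is this package's
documented convention); a complete-case re-analysis (patients evaluable
under every model and both point scores — a pure filter, no imputation);
and adjusted treatment effects (per endpoint, a Cox model of the outcome on
OAC plus that endpoint's full covariate set, Efron ties by default,
statsmodels PHReg underneath).

Missing data policy is hard-coded: a patient missing any covariate of a risk
equation is *not evaluable* for it (no silent defaults, no imputation),
while the point scores are computed for everyone with missing components
scoring 0 and a `complete=False` flag — mirroring how the two kinds of
scores are used in practice.  Cells fail independently: an undefined metric
produces an empty cell and a log line, never an aborted run.  Reports are
CSVs with fixed column order, risks on the percent scale, written to 6
decimals (lossless round-trip at that precision); identical inputs and
config give byte-identical files regardless of input row order.

## The synthetic cohort generator

The simulator emulates a UK-style incident-AF cohort so that every pipeline
stage can be tested against known truth.  Defaults are the study
conditions:

- **Covariates**: age truncated-normal (mean 74.6, SD 12.2, ≥ 18); female
  46.7%; ethnicity 95.2/1.6/3.2% white/Asian/other; vitals normal (pulse
  79.2 ± 18.9, SBP 134.8 ± 19.6, DBP via a positive pulse-pressure draw,
  weight 81.3 ± 21.0, height 1.68 ± 0.10, floors keeping SBP > DBP > 0);
  history flags Bernoulli at incident-AF prevalences (hypertension 70.8%,
  CKD ≥ 3 14.3%, diabetes 13.7%, paroxysmal AF 13.4%, prior stroke/TIA
  10.7%, vascular disease 8.5%, CHF 6.9%, bleeding history 6.8%, smoking
  6.2%, …); alcohol a two-part mixture putting 7.1% above 8 units/week;
  treatment OAC 50.6% with a 43.5% NOAC share.  Age-associated flags get a
  logistic age link (log-odds tilts of 0.01–0.10 per year) whose intercept
  is root-solved per cohort so the realised marginal hits its target — the
  only covariate correlation modelled; richer joint structure (copulas,
  deprivation, practice clustering) is deliberately out of scope.
- **Outcomes**: per endpoint, a Weibull-baseline Cox model (default shape 1)
  with moderate coefficient vectors; baseline scales are set so the 1-year
  baseline risks are 11.89% (death), 8.29% (stroke/SE) and 6.32% (major
  bleeding) — observed incident-AF magnitudes.  Treatment log-hazards for
  OAC default to ln 0.58 (death), ln 0.71 (stroke) and ln 0.90 (bleeding).
  Event times by inverse transform; censoring = min(exponential dropout at
  5e−5/day, administrative horizon at 5 years); death additionally truncates
  stroke and bleeding follow-up (cause-specific censoring, not a
  competing-risks sub-distribution, matching cause-agnostic KM usage).
- **Injectors**: MCAR per-variable deletion at configured rates (outcomes
  never deleted); hazard multipliers that scale the *true* hazards while the
  evaluated model spec is built without them — multiplier 1 is a perfectly
  specified model, multiplier 2 produces controlled underprediction.

All draws flow through one seeded numpy Generator in a fixed order, so a
seed fully determines the cohort across platforms.

What passing tests do and do not show: the simulator has exact Cox-form
truth, MCAR missingness and mostly independent covariates, so self-
consistency results (intercept → 0, quantile gaps → 0, AUC ordering)
validate the *machinery*, not any real tool's transportability.  Two known
gaps between simulation and the idealised model: (i) for stroke and
bleeding, censoring at death is mildly informative (death shares covariates
with the other endpoints), so the generating model is exactly calibrated
only for the death endpoint — calibration self-consistency checks therefore
use death; (ii) real missingness is not MCAR and real covariates are
correlated beyond the age link.

## Numerical choices and edge cases

- Risk transform computed as `−expm1(exp(lp)·ln S₀)` for accuracy at small
  risks; `S₀ = 1` yields exactly 0 (zero-hazard limit).
- Log-transform terms fail loudly (naming patient and term) on non-positive
  inputs rather than propagating NaN.
- Cox fits: non-convergence is flagged on the result; diverging
  coefficients (|β| > 15 or SE > 50) raise a complete-separation diagnostic.
  Zero events, or zero events in a treatment arm, are explicit errors /
  non-estimable flags.
- AUC with zero cases or zero controls is an explicit error object, not NaN.
- 95% CIs use 1.96 throughout.
- Subgroup strata below 50 patients (configurable) are skipped with a log
  line.

## Problem sizes

The test suite validates on simulated cohorts of 1 500–20 000 patients
(20 000 for calibration self-consistency, discrimination ordering and
treatment-effect recovery; 10⁵ for covariate-marginal convergence), sizes at
which Monte-Carlo error is small against the tested tolerances while the
whole suite stays fast.  `scripts/acceptance.py` uses the same 20 000-patient
study.

## Known limitations

- The bundled coefficient files are synthetic stand-ins, not published
  transcriptions; conclusions about any real tool require transcribing its
  supplementary coefficient tables into the JSON schema.
- The exact variance estimator behind published AUC CIs and the exact
  censoring treatment behind published AUCs are typically unstated; this
  package defaults to DeLong and status-based exclusion and offers IPCW as
  sensitivity.
- No competing-risks estimators, no multiple imputation, no recalibration /
  model updating, no ORBIT-AF score.
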