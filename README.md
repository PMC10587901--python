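# afvalidate

External validation of multi-outcome risk equations for patients with
incident atrial fibrillation (AF).

Clinicians weighing anticoagulation for a patient with newly diagnosed AF
balance the risk of ischaemic stroke against the risk of major bleeding —
and, increasingly, all-cause mortality.  Multi-outcome Cox risk equations
(published as coefficient tables with per-horizon baseline survival) predict
all three simultaneously, while the guideline point scores CHA₂DS₂-VASc and
HAS-BLED rank patients with small integers.  Before any such equation is
used in a new population it must be validated externally: does it still
*discriminate* (rank patients with events above those without) and is it
*calibrated* (do predicted risks match observed event rates)?

`afvalidate` is a tested pipeline for exactly that study design, for
biostatisticians and health-data scientists working with incident-AF
cohorts.  It provides:

- **Risk scoring** — CHA₂DS₂-VASc (0–9), HAS-BLED (the modified labile-INR-
  free variant with maximum 8, or the full 0–9 score), and coefficient-driven
  Cox risk equations `risk(x, t) = 1 − S₀(t)^exp(β·(f(x) − f(x̄)))` loaded
  from auditable JSON files (linear, log, indicator and hinge transforms).
- **Survival metrics** — Kaplan–Meier observed risks `1 − S(t)` with
  Greenwood CIs; horizon-specific AUC under censoring (status-based
  exclusion, or inverse-probability-of-censoring weighting as a sensitivity
  option) with DeLong confidence intervals; the paired DeLong test for
  correlated AUCs; Cox proportional-hazards fits (Efron/Breslow ties) for
  adjusted treatment effects.
- **Calibration** — calibration-in-the-large (offset-logistic recalibration
  intercept and slope on the logit of predicted risk) and quantile
  calibration tables (mean predicted vs KM observed per quintile).
- **A validation pipeline** — missingness accounting (no imputation, ever:
  patients missing a model covariate are not evaluable for it), per-model
  validation tables, score comparisons on shared patients, subgroup analyses
  (by treatment, stroke-risk and bleed-risk strata), complete-case
  re-analysis, treatment-effect hazard ratios; deterministic, cell-failure
  tolerant, CSV outputs.
- **A synthetic cohort simulator** — incident-AF-like covariates at
  configurable prevalences, Cox–Weibull event times with known coefficients
  for all three endpoints, dropout/administrative censoring, MCAR
  missingness injection and controlled miscalibration, so the whole pipeline
  is testable with ground truth.

The point scorers and risk equations are scikit-learn compatible estimators
(`CHA2DS2VAScScorer`, `HASBLEDScorer`, `CoxRiskModel`) and compose with
sklearn pipelines; the metrics are plain functions in the style of
`sklearn.metrics`.

The bundled coefficient files under `afvalidate/data/` are **synthetic
stand-ins** (invented coefficients with realistic covariate structure);
validated transcriptions of published equations drop in through the same
JSON schema (`risk_model.schema.json`).

## Worked example

```python
import afvalidate as av

# a 20000-patient synthetic cohort whose outcomes come from known models
cfg = av.default_config(n=20_000, seed=11)
cohort, truth = av.simulate_cohort(cfg)

# validate the generating models themselves (perfectly specified case)
specs = [av.spec_from_true_model(cfg, ep)
         for ep in ("death", "stroke_se", "major_bleed")]
report = av.run(cohort, specs, av.RunConfig(horizons=[12]),
                treatment_specs={s.outcome: s for s in specs})
print(av.render_summary(report))
```

prints (risks in percent, AUC with 95% CI):

```
model  outcome  horizon_m  n  pred%  KM%  AUC (95% CI)
true_death  death  12  20000  15.89  16.08  0.777 (0.768 to 0.786)
true_stroke_se  stroke_se  12  20000  13.26  12.19  0.743 (0.732 to 0.754)
true_major_bleed  major_bleed  12  20000  9.53  9.20  0.695 (0.681 to 0.708)
```

Because the death model generated the death outcomes, its mean predicted
risk (15.89%) matches the KM observed risk (16.08%) and the recalibration
intercept is ≈ 0; the AUCs reflect the true spread of risk in the cohort.
For stroke and bleeding the simulator censors follow-up at death, which
leaves a small gap between predicted and KM risk — see
`docs/methods.md`.  The same run writes the full table set
(`validation.csv`, `comparisons.csv`, `calibration_quantiles.csv`,
`subgroups.csv`, `missingness_*.csv`, `treatment_effect.csv`) via
`av.write_report(report, "out/")`.

From the shell, the same study is:

```sh
afvalidate simulate --config sim.json --out cohort.csv
afvalidate score --cohort cohort.csv --models models/ --horizons 1,12,24 --out pred.csv
afvalidate run --cohort cohort.csv --models models/ --out report/
```

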