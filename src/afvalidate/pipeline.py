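"""Orchestration of a full external-validation run.

Given a cohort, a set of risk-model coefficient files and a run
configuration, this module reproduces the analysis layout of a multi-outcome
external validation: missingness accounting, per-(model, horizon) validation
cells (discrimination + calibration), AUC comparisons against the integer
point scores, subgroup analyses, a complete-case re-analysis and adjusted
treatment-effect Cox models.

Cells fail independently: an undefined metric (say, zero events for one
endpoint at one horizon) yields an explicit empty cell and a log line, never
an aborted run — real validation tables have heterogeneous denominators per
model for exactly this reason.  No value is ever imputed: patients missing a
covariate of a risk equation are simply not evaluable for it.

Determinism: the cohort is canonically sorted on entry, all iteration orders
are fixed, and no metric consumes randomness, so identical inputs and config
produce byte-identical report files regardless of input row order.
"""

from __future__ import annotations

from typing import Dict, List, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .calibration import calibration_in_the_large, quantile_calibration
from .cohort import Cohort
from .errors import AFValidateError, MetricError
from .metrics import compare_auc, cox_fit, horizon_auc, kaplan_meier, observed_risk
from .model_spec import DAYS_PER_MONTH, RiskModelSpec, months_to_days
from .report import (
    SUBGROUP_COLUMNS,
    VALIDATION_COLUMNS,
    ValidationReport,
)
from .risk import evaluable_mask, predict_risks
from .scores import (
    bleed_risk_strata,
    chads_vasc_scores,
    has_bled_scores,
    stroke_risk_strata,
)

__all__ = [
    "RunConfig",
    "assess_missingness",
    "complete_case",
    "run_validation",
    "run_comparisons",
    "run_subgroups",
    "treatment_effect",
    "run",
]


class RunConfig(BaseModel):
    """Knobs of one validation run."""

    model_config = ConfigDict(extra="forbid")

    horizons: List[int] = Field(default_factory=lambda: [1, 12, 24])
    n_quantiles: int = Field(default=5, ge=2)
    auc_censoring_method: Literal["exclude", "ipcw"] = "exclude"
    subgroup_by_oac: bool = True
    subgroup_by_stroke_stratum: bool = True
    subgroup_by_bleed_stratum: bool = True
    min_stratum_size: int = Field(default=50, ge=1)
    min_bin_size: int = Field(default=20, ge=1)
    cox_ties: Literal["efron", "breslow"] = "efron"
    days_per_month: float = Field(default=DAYS_PER_MONTH, gt=0)
    seed: int = 0

    @field_validator("horizons")
    @classmethod
    def _horizons_valid(cls, v):
        if not v:
            raise ValueError("at least one horizon required")
        if any(h <= 0 for h in v) or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("horizons must be positive and strictly increasing")
        return v


def _spec_list(model_specs) -> List[RiskModelSpec]:
    if isinstance(model_specs, Mapping):
        return [model_specs[k] for k in sorted(model_specs)]
    return list(model_specs)


# ---------------------------------------------------------------------------
# missingness


def assess_missingness(cohort: Cohort, model_specs) -> Dict[str, object]:
    """Per-variable and per-model missingness, plus the complete-case count.

    Returns a dict with ``variables`` (fraction missing per covariate any
    model uses), ``models`` (per model, patients not evaluable) and
    ``complete_case_n`` (patients evaluable under every model).
    """
    specs = _spec_list(model_specs)
    patients = cohort.patients
    used = sorted(set().union(*(s.required_covariates for s in specs))) if specs else []
    var_rows = [
        {
            "variable": v,
            "n_missing": int(patients[v].isna().sum()),
            "fraction_missing": float(patients[v].isna().mean()),
        }
        for v in used
    ]
    model_rows = []
    all_eval = pd.Series(True, index=patients.index)
    for spec in specs:
        mask = evaluable_mask(patients, spec)
        all_eval &= mask
        model_rows.append(
            {
                "model": spec.model_id,
                "n_evaluable": int(mask.sum()),
                "n_not_evaluable": int((~mask).sum()),
                "fraction_not_evaluable": float((~mask).mean()),
            }
        )
    return {
        "variables": pd.DataFrame(var_rows, columns=["variable", "n_missing", "fraction_missing"]),
        "models": pd.DataFrame(
            model_rows,
            columns=["model", "n_evaluable", "n_not_evaluable", "fraction_not_evaluable"],
        ),
        "complete_case_n": int(all_eval.sum()),
    }


def complete_case(cohort: Cohort, model_specs, include_point_scores: bool = True) -> Cohort:
    """Patients evaluable under every model (and both point scores).

    A pure filter — nothing is imputed.  Raises when the subset is empty.
    """
    specs = _spec_list(model_specs)
    mask = pd.Series(True, index=cohort.patients.index)
    for spec in specs:
        mask &= evaluable_mask(cohort.patients, spec)
    if include_point_scores:
        mask &= chads_vasc_scores(cohort.patients)["complete"]
        mask &= has_bled_scores(cohort.patients)["complete"]
    if not mask.any():
        raise MetricError(
            "complete-case subset is empty: a complete-case analysis is not "
            "possible on this cohort"
        )
    return cohort.subset(cohort.patients.index[mask])


# ---------------------------------------------------------------------------
# per-model validation cells


def _validation_cells(
    cohort: Cohort,
    specs: Sequence[RiskModelSpec],
    config: RunConfig,
    report: ValidationReport,
    with_calibration: bool = True,
) -> pd.DataFrame:
    rows = []
    for spec in specs:
        outc = cohort.endpoint_outcomes(spec.outcome)
        for horizon in config.horizons:
            if horizon not in spec.baseline_survival:
                report.note(
                    f"{spec.model_id}: no baseline survival at {horizon} months; cell skipped"
                )
                continue
            ps = predict_risks(cohort.patients, spec, horizon)
            ev = ps.evaluable
            risk = ps.risk[ev]
            times = outc.loc[ev, "time_days"].to_numpy(dtype=float)
            events = outc.loc[ev, "event"].to_numpy(dtype=int)
            h_days = months_to_days(horizon, config.days_per_month)
            row = {
                "model": spec.model_id,
                "outcome": spec.outcome,
                "horizon": horizon,
                "n": int(ev.sum()),
                "avg_predicted": 100.0 * float(risk.mean()) if ev.any() else np.nan,
                "km": np.nan,
                "n0": np.nan, "p0": np.nan, "n1": np.nan, "p1": np.nan,
                "auc": np.nan, "auc_lo": np.nan, "auc_hi": np.nan,
            }
            if int(ev.sum()) == 0:
                report.note(f"{spec.model_id}@{horizon}m: no evaluable patients")
                rows.append(row)
                continue
            try:
                km = kaplan_meier(times, events)
                row["km"] = 100.0 * observed_risk(km, h_days)
            except MetricError as exc:
                report.note(f"{spec.model_id}@{horizon}m: KM undefined ({exc})")
            try:
                auc = horizon_auc(
                    risk.to_numpy(), times, events, h_days,
                    method=config.auc_censoring_method,
                )
                row.update(
                    n0=auc.n0, p0=100.0 * auc.p0, n1=auc.n1, p1=100.0 * auc.p1,
                    auc=auc.auc, auc_lo=auc.ci_lo, auc_hi=auc.ci_hi,
                )
                if auc.n_excluded:
                    report.note(
                        f"{spec.model_id}@{horizon}m: {auc.n_excluded} patients "
                        "censored before the horizon excluded from the AUC"
                    )
            except MetricError as exc:
                report.note(f"{spec.model_id}@{horizon}m: AUC undefined ({exc})")
            rows.append(row)
            if not with_calibration:
                continue
            try:
                summ = calibration_in_the_large(risk.to_numpy(), times, events, h_days)
                report.calibration.loc[len(report.calibration)] = {
                    "model": spec.model_id, "outcome": spec.outcome, "horizon": horizon,
                    "n": summ.n_evaluable,
                    "mean_predicted": 100.0 * summ.mean_predicted,
                    "km_observed": 100.0 * summ.km_observed,
                    "intercept": summ.intercept, "slope": summ.slope,
                }
            except MetricError as exc:
                report.note(f"{spec.model_id}@{horizon}m: calibration undefined ({exc})")
            try:
                qt = quantile_calibration(
                    risk, times, events, h_days,
                    n_quantiles=config.n_quantiles, min_bin_size=config.min_bin_size,
                )
                block = qt.table.copy()
                block["mean_predicted"] *= 100.0
                block["km_observed"] *= 100.0
                block["ci_lo"] *= 100.0
                block["ci_hi"] *= 100.0
                block.insert(0, "model", spec.model_id)
                block.insert(1, "outcome", spec.outcome)
                block.insert(2, "horizon", horizon)
                block = block[report.quantiles.columns]
                report.quantiles = (
                    block
                    if report.quantiles.empty
                    else pd.concat([report.quantiles, block], ignore_index=True)
                )
            except MetricError as exc:
                report.note(f"{spec.model_id}@{horizon}m: quantile calibration skipped ({exc})")
    return pd.DataFrame(rows, columns=VALIDATION_COLUMNS)


def run_validation(cohort: Cohort, model_specs, config: Optional[RunConfig] = None) -> ValidationReport:
    """The per-model validation table plus calibration blocks."""
    config = config or RunConfig()
    cohort = cohort.sorted()
    specs = _spec_list(model_specs)
    report = ValidationReport()
    report.validation = _validation_cells(cohort, specs, config, report)
    return report


# ---------------------------------------------------------------------------
# comparisons against the point scores


def run_comparisons(
    cohort: Cohort, model_specs, config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Paired DeLong comparisons: each risk model vs its comparator score.

    Death and stroke models are compared with CHA2DS2-VASc, bleeding models
    with HAS-BLED; the integer score is the comparator's ranking variable,
    and each comparison runs on the intersection of patients evaluable under
    both predictors.
    """
    config = config or RunConfig()
    cohort = cohort.sorted()
    specs = _spec_list(model_specs)
    chads = chads_vasc_scores(cohort.patients)["score"]
    hasb = has_bled_scores(cohort.patients)["score"]
    rows = []
    for spec in specs:
        comp_name, comp_scores = (
            ("has_bled", hasb) if spec.outcome == "major_bleed" else ("cha2ds2_vasc", chads)
        )
        outc = cohort.endpoint_outcomes(spec.outcome)
        for horizon in config.horizons:
            if horizon not in spec.baseline_survival:
                continue
            ps = predict_risks(cohort.patients, spec, horizon)
            shared = ps.evaluable & comp_scores.notna()
            if not shared.any():
                raise MetricError(
                    f"{spec.model_id} vs {comp_name}: no shared evaluable patients"
                )
            pred_a = ps.risk[shared]
            pred_b = comp_scores[shared].astype(float)
            times = outc.loc[shared, "time_days"].to_numpy(dtype=float)
            events = outc.loc[shared, "event"].to_numpy(dtype=int)
            h_days = months_to_days(horizon, config.days_per_month)
            cmp = compare_auc(
                pred_a.to_numpy(), pred_b.to_numpy(), times, events, h_days
            )
            rows.append(
                {
                    "model": spec.model_id,
                    "comparator": comp_name,
                    "outcome": spec.outcome,
                    "horizon": horizon,
                    "n": int(shared.sum()),
                    "auc_model": cmp.auc_a.auc,
                    "auc_model_lo": cmp.auc_a.ci_lo,
                    "auc_model_hi": cmp.auc_a.ci_hi,
                    "auc_comparator": cmp.auc_b.auc,
                    "auc_comparator_lo": cmp.auc_b.ci_lo,
                    "auc_comparator_hi": cmp.auc_b.ci_hi,
                    "delta": cmp.delta,
                    "p_value": cmp.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "comparator", "outcome", "horizon", "n",
            "auc_model", "auc_model_lo", "auc_model_hi",
            "auc_comparator", "auc_comparator_lo", "auc_comparator_hi",
            "delta", "p_value",
        ],
    )


# ---------------------------------------------------------------------------
# subgroups


def _subgroup_definitions(cohort: Cohort, config: RunConfig):
    patients = cohort.patients
    defs = []
    if config.subgroup_by_oac:
        oac = patients["oac"]
        defs.append(("oac", {"oac": oac == True, "no_oac": oac == False}))  # noqa: E712
    if config.subgroup_by_stroke_stratum:
        strata = stroke_risk_strata(chads_vasc_scores(patients)["score"])
        defs.append(
            ("cha2ds2_vasc_stratum", {lvl: strata == lvl for lvl in ("low", "moderate", "high")})
        )
    if config.subgroup_by_bleed_stratum:
        strata = bleed_risk_strata(has_bled_scores(patients)["score"])
        defs.append(("has_bled_stratum", {lvl: strata == lvl for lvl in ("lower", "higher")}))
    return defs


def run_subgroups(
    cohort: Cohort, model_specs, config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Re-run the validation cells inside each configured stratum.

    Strata smaller than ``config.min_stratum_size`` are skipped with a log
    line (recorded on the returned frame's ``attrs['log']``).
    """
    config = config or RunConfig()
    cohort = cohort.sorted()
    specs = _spec_list(model_specs)
    scratch = ValidationReport()
    blocks = []
    for name, levels in _subgroup_definitions(cohort, config):
        for level, mask in levels.items():
            mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
            size = int(mask.sum())
            if size < config.min_stratum_size:
                scratch.note(
                    f"subgroup {name}={level}: {size} patients < "
                    f"{config.min_stratum_size}; skipped"
                )
                continue
            sub = cohort.subset(cohort.patients.index[mask.to_numpy(dtype=bool)])
            cells = _validation_cells(sub, specs, config, scratch, with_calibration=False)
            cells.insert(0, "subgroup", name)
            cells.insert(1, "level", level)
            blocks.append(cells)
    out = (
        pd.concat(blocks, ignore_index=True)
        if blocks
        else pd.DataFrame(columns=SUBGROUP_COLUMNS)
    )
    out.attrs["log"] = list(scratch.log)
    return out


# ---------------------------------------------------------------------------
# treatment effect


def _design_matrix(patients: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix: flags 0/1, sex/ethnicity dummies, vitals raw."""
    cols = {}
    for cov in sorted(covariates):
        s = patients[cov]
        if cov == "sex":
            cols["sex_female"] = (s == "female").astype(float).where(s.notna())
        elif cov == "ethnicity":
            for lvl in ("asian", "black_mixed_other"):
                cols[f"ethnicity_{lvl}"] = (s == lvl).astype(float).where(s.notna())
        elif str(s.dtype) == "boolean":
            cols[cov] = s.map({True: 1.0, False: 0.0}, na_action="ignore").astype("Float64")
        else:
            cols[cov] = pd.to_numeric(s, errors="coerce")
    return pd.DataFrame(cols, index=patients.index).astype(float)


def treatment_effect(
    cohort: Cohort,
    model_specs_2021: Mapping[str, RiskModelSpec],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Adjusted hazard ratio of baseline anticoagulation per endpoint.

    One Cox model per endpoint: exposure ``oac`` plus every covariate of
    that endpoint's risk equation, fitted on patients complete for all of
    them.  Endpoints whose fit is impossible (no events, separation) are
    flagged non-estimable, not dropped silently.
    """
    config = config or RunConfig()
    cohort = cohort.sorted()
    rows = []
    for ep in sorted(model_specs_2021):
        spec = model_specs_2021[ep]
        covs = set(spec.required_covariates) - {"oac"}
        X = _design_matrix(cohort.patients, covs)
        oac = (
            cohort.patients["oac"].map({True: 1.0, False: 0.0}, na_action="ignore")
            .astype("Float64").astype(float)
        )
        X.insert(0, "oac", oac)
        complete = ~X.isna().any(axis=1)
        outc = cohort.endpoint_outcomes(spec.outcome)
        times = outc.loc[complete, "time_days"].to_numpy(dtype=float)
        events = outc.loc[complete, "event"].to_numpy(dtype=int)
        row = {
            "outcome": spec.outcome, "n": int(complete.sum()),
            "n_events": int(events.sum()),
            "ahr": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "converged": False,
        }
        try:
            if events.sum() == 0 or (events[X.loc[complete, "oac"] == 1.0].sum() == 0) or (
                events[X.loc[complete, "oac"] == 0.0].sum() == 0
            ):
                raise MetricError("an exposure arm has zero events; aHR non-estimable")
            fit = cox_fit(X[complete], times, events, ties=config.cox_ties)
            row.update(
                ahr=fit.summary.loc["oac", "hr"],
                ci_lo=fit.summary.loc["oac", "ci_lo"],
                ci_hi=fit.summary.loc["oac", "ci_hi"],
                converged=fit.converged,
            )
        except MetricError as exc:
            row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run


def run(
    cohort: Cohort,
    model_specs,
    config: Optional[RunConfig] = None,
    treatment_specs: Optional[Mapping[str, RiskModelSpec]] = None,
) -> ValidationReport:
    """Assemble the complete validation report.

    ``treatment_specs`` maps endpoint name to the risk model whose covariate
    set adjusts the treatment-effect Cox model for that endpoint; when
    omitted, the treatment block is skipped.
    """
    config = config or RunConfig()
    cohort = cohort.sorted()
    specs = _spec_list(model_specs)
    report = run_validation(cohort, specs, config)

    miss = assess_missingness(cohort, specs)
    report.missingness_variables = miss["variables"]
    report.missingness_models = miss["models"]
    report.complete_case_n = miss["complete_case_n"]

    try:
        report.comparisons = run_comparisons(cohort, specs, config)
    except MetricError as exc:
        report.note(f"comparisons skipped: {exc}")

    sub = run_subgroups(cohort, specs, config)
    report.subgroups = sub
    for line in sub.attrs.get("log", []):
        report.note(line)

    try:
        cc = complete_case(cohort, specs)
        if cc.n < cohort.n:
            scratch = ValidationReport()
            report.complete_case_validation = _validation_cells(
                cc, specs, config, scratch, with_calibration=False
            )
            for line in scratch.log:
                report.note(f"complete-case: {line}")
        else:
            report.complete_case_validation = report.validation.copy()
            report.note("no missing data: complete-case block equals the main analysis")
    except MetricError as exc:
        report.note(f"complete-case analysis skipped: {exc}")

    if treatment_specs:
        report.treatment_effect = treatment_effect(cohort, treatment_specs, config)
    return report
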