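"""Validation-report container and delimited-text writers.

The report mirrors the tables an external-validation paper prints: one row
per (model, outcome, horizon) with the evaluable count, average predicted
risk, KM observed risk, the case/control summaries N0/P0/N1/P1 and the AUC
with its 95% CI; AUC-comparison rows against the point scores; per-quantile
calibration tables; subgroup blocks; the missingness accounting; the
complete-case re-analysis; and the adjusted treatment-effect hazard ratios.

Risks in the report are on the percent scale (a value of 4.51 means 4.51%).
Files are plain CSV with a fixed column order, written to 6 decimals so a
write/read round-trip is lossless at that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import pandas as pd

from .errors import AFValidateError

logger = logging.getLogger(__name__)

VALIDATION_COLUMNS = [
    "model", "outcome", "horizon", "n", "avg_predicted", "km",
    "n0", "p0", "n1", "p1", "auc", "auc_lo", "auc_hi",
]
CALIBRATION_COLUMNS = [
    "model", "outcome", "horizon", "n", "mean_predicted", "km_observed",
    "intercept", "slope",
]
QUANTILE_COLUMNS = [
    "model", "outcome", "horizon", "quantile", "n", "mean_predicted",
    "km_observed", "ci_lo", "ci_hi",
]
COMPARISON_COLUMNS = [
    "model", "comparator", "outcome", "horizon", "n",
    "auc_model", "auc_model_lo", "auc_model_hi",
    "auc_comparator", "auc_comparator_lo", "auc_comparator_hi",
    "delta", "p_value",
]
SUBGROUP_COLUMNS = ["subgroup", "level"] + VALIDATION_COLUMNS
MISSING_VARIABLE_COLUMNS = ["variable", "n_missing", "fraction_missing"]
MISSING_MODEL_COLUMNS = ["model", "n_evaluable", "n_not_evaluable", "fraction_not_evaluable"]
TREATMENT_COLUMNS = ["outcome", "n", "n_events", "ahr", "ci_lo", "ci_hi", "converged"]

_FILES = {
    "validation": ("validation.csv", VALIDATION_COLUMNS),
    "calibration": ("calibration.csv", CALIBRATION_COLUMNS),
    "quantiles": ("calibration_quantiles.csv", QUANTILE_COLUMNS),
    "comparisons": ("comparisons.csv", COMPARISON_COLUMNS),
    "subgroups": ("subgroups.csv", SUBGROUP_COLUMNS),
    "missingness_variables": ("missingness_variables.csv", MISSING_VARIABLE_COLUMNS),
    "missingness_models": ("missingness_models.csv", MISSING_MODEL_COLUMNS),
    "complete_case_validation": ("complete_case.csv", VALIDATION_COLUMNS),
    "treatment_effect": ("treatment_effect.csv", TREATMENT_COLUMNS),
}


def _empty(columns: List[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class ValidationReport:
    """All result tables of one validation run plus the run log."""

    validation: pd.DataFrame = field(default_factory=lambda: _empty(VALIDATION_COLUMNS))
    calibration: pd.DataFrame = field(default_factory=lambda: _empty(CALIBRATION_COLUMNS))
    quantiles: pd.DataFrame = field(default_factory=lambda: _empty(QUANTILE_COLUMNS))
    comparisons: pd.DataFrame = field(default_factory=lambda: _empty(COMPARISON_COLUMNS))
    subgroups: pd.DataFrame = field(default_factory=lambda: _empty(SUBGROUP_COLUMNS))
    missingness_variables: pd.DataFrame = field(
        default_factory=lambda: _empty(MISSING_VARIABLE_COLUMNS)
    )
    missingness_models: pd.DataFrame = field(
        default_factory=lambda: _empty(MISSING_MODEL_COLUMNS)
    )
    complete_case_validation: pd.DataFrame = field(
        default_factory=lambda: _empty(VALIDATION_COLUMNS)
    )
    treatment_effect: pd.DataFrame = field(default_factory=lambda: _empty(TREATMENT_COLUMNS))
    complete_case_n: int = 0
    log: List[str] = field(default_factory=list)

    def note(self, message: str) -> None:
        logger.info(message)
        self.log.append(message)


def write_report(report: ValidationReport, out_dir) -> List[Path]:
    """Write the report tables as CSVs plus ``run_log.txt``.

    Empty blocks (e.g. no subgroups requested) are omitted and logged;
    column order is fixed and values are written to 6 decimals.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise AFValidateError(f"cannot create report directory {out_dir}: {exc}") from exc
    written: List[Path] = []
    for attr, (fname, columns) in _FILES.items():
        frame = getattr(report, attr)
        if frame is None or frame.empty:
            report.note(f"report block {attr!r} empty; {fname} omitted")
            continue
        path = out_dir / fname
        frame[columns].to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    log_path = out_dir / "run_log.txt"
    log_path.write_text(
        "\n".join([*report.log, f"complete_case_n={report.complete_case_n}"]) + "\n",
        encoding="utf-8",
    )
    written.append(log_path)
    return written


def read_report(out_dir) -> Dict[str, pd.DataFrame]:
    """Read back the CSV tables written by :func:`write_report`."""
    out_dir = Path(out_dir)
    tables = {}
    for attr, (fname, _) in _FILES.items():
        path = out_dir / fname
        if path.exists():
            tables[attr] = pd.read_csv(path)
    return tables


def render_summary(report: ValidationReport) -> str:
    """Human-readable summary with percentages to 2 decimals."""
    lines = ["model  outcome  horizon_m  n  pred%  KM%  AUC (95% CI)"]
    for _, r in report.validation.iterrows():
        auc = (
            f"{r['auc']:.3f} ({r['auc_lo']:.3f} to {r['auc_hi']:.3f})"
            if pd.notna(r["auc"])
            else "undefined"
        )
        lines.append(
            f"{r['model']}  {r['outcome']}  {int(r['horizon'])}  {int(r['n'])}  "
            f"{r['avg_predicted']:.2f}  {r['km']:.2f}  {auc}"
        )
    return "\n".join(lines)
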