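"""Coefficient-driven Cox risk equations loaded from JSON files.

A risk model is a set of terms ``beta_j * f_j(x_j)`` over patient covariates
plus a baseline survival probability ``S0(t)`` per prediction horizon; the
predicted risk at horizon ``t`` is ``1 - S0(t) ** exp(lp)`` where ``lp`` is
the centered linear predictor.  Coefficients are transcribed inputs, one JSON
file per (model generation, outcome), so the transcription is auditable; the
machine-checkable schema ships in ``afvalidate/data/risk_model.schema.json``.

Supported covariate transforms:

``linear``
    ``f(x) = x`` (continuous covariates).
``log``
    ``f(x) = ln x``; evaluation fails loudly on non-positive values.
``indicator``
    ``f(x) = 1`` if a tri-state flag is true, else 0.
``equals``
    ``f(x) = 1`` if a categorical covariate equals ``level`` (e.g. sex).
``hinge``
    ``f(x) = max(0, x - knot)``; with ``linear`` terms this spans the
    piecewise-linear splines used by published risk equations.

Centering is either a reference covariate vector (raw values; for
indicator/equals terms a reference prevalence in [0, 1] is permitted) or the
flag ``"precentered"`` meaning the betas already absorb the reference.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .cohort import ENDPOINTS, FLAG_FIELDS, PatientRecord
from .errors import EvaluationError, ModelSpecError

#: days per month used to place a month horizon on the day-scale follow-up
#: axis (12 months = 365.25 days); override via the ``days_per_month``
#: arguments where offered.
DAYS_PER_MONTH = 30.4375

#: covariate set of the reduced ("abridged") 2017 death model
REDUCED_2017_DEATH_COVARIATES = frozenset(
    {"age", "pulse", "sbp", "vascular_disease", "bleeding_history", "chf",
     "ckd_grade3plus", "oac"}
)

_CATEGORICAL = {"sex", "ethnicity"}
_KNOWN_COVARIATES = set(PatientRecord.field_names()) - {"patient_id"}


def months_to_days(months: float, days_per_month: float = DAYS_PER_MONTH) -> float:
    return float(months) * days_per_month


class Transform(BaseModel):
    """Descriptor of the covariate transform applied inside one term."""

    model_config = ConfigDict(extra="forbid")

    type: Literal["linear", "log", "indicator", "equals", "hinge"]
    knot: Optional[float] = None
    level: Optional[str] = None

    @model_validator(mode="after")
    def _check_params(self) -> "Transform":
        if self.type == "hinge" and self.knot is None:
            raise ValueError("hinge transform requires a knot")
        if self.type == "equals" and self.level is None:
            raise ValueError("equals transform requires a level")
        return self

    def apply(self, values: pd.Series, covariate: str, model_id: str) -> np.ndarray:
        """Vectorised f(x); missing inputs propagate as NaN."""
        if self.type in ("indicator",):
            arr = values.astype("boolean")
            out = arr.map({True: 1.0, False: 0.0}, na_action="ignore").astype("Float64")
            return out.to_numpy(dtype=float, na_value=np.nan)
        if self.type == "equals":
            out = np.where(values.isna(), np.nan, (values == self.level).astype(float))
            return out.astype(float)
        x = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float, na_value=np.nan)
        if self.type == "linear":
            return x
        if self.type == "hinge":
            return np.where(np.isnan(x), np.nan, np.maximum(0.0, x - self.knot))
        if self.type == "log":
            bad = ~np.isnan(x) & (x <= 0)
            if bad.any():
                first = values.index[np.flatnonzero(bad)[0]]
                raise EvaluationError(
                    f"model {model_id}: log transform of non-positive "
                    f"{covariate!r} for patient {first!r}"
                )
            return np.where(np.isnan(x), np.nan, np.log(np.where(x > 0, x, np.nan)))
        raise AssertionError(self.type)

    def apply_reference(self, value: float, covariate: str, model_id: str) -> float:
        """f(x̄) for a scalar reference value."""
        if self.type in ("indicator", "equals"):
            v = float(value)
            if not 0.0 <= v <= 1.0:
                raise ModelSpecError(
                    f"model {model_id}: reference for {covariate!r} must be in [0, 1]"
                )
            return v
        v = float(value)
        if self.type == "linear":
            return v
        if self.type == "hinge":
            return max(0.0, v - self.knot)
        if self.type == "log":
            if v <= 0:
                raise ModelSpecError(
                    f"model {model_id}: log reference for {covariate!r} must be positive"
                )
            return math.log(v)
        raise AssertionError(self.type)


class Term(BaseModel):
    model_config = ConfigDict(extra="forbid")

    covariate: str
    transform: Transform = Field(default_factory=lambda: Transform(type="linear"))
    beta: float


class RiskModelSpec(BaseModel):
    """A validated coefficient file: terms, centering and baseline survival."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    model_id: str
    outcome: Literal["death", "stroke_se", "major_bleed"]
    description: Optional[str] = None
    terms: List[Term]
    centering: Union[Literal["precentered"], Dict[str, float]]
    baseline_survival: Dict[int, float] = Field(
        description="map from horizon in months to S0(t) in (0, 1]"
    )

    @field_validator("baseline_survival")
    @classmethod
    def _s0_valid(cls, v: Dict[int, float]) -> Dict[int, float]:
        if not v:
            raise ValueError("baseline_survival must contain at least one horizon")
        for h, s0 in v.items():
            if h <= 0:
                raise ValueError(f"horizon {h} must be a positive month count")
            if not 0.0 < s0 <= 1.0:
                raise ValueError(f"S0({h}) = {s0} outside (0, 1]")
        hs = sorted(v)
        for a, b in zip(hs, hs[1:]):
            if v[b] > v[a]:
                raise ValueError(
                    f"baseline survival must be non-increasing in horizon: "
                    f"S0({b}) = {v[b]} > S0({a}) = {v[a]}"
                )
        return v

    @model_validator(mode="after")
    def _covariates_valid(self) -> "RiskModelSpec":
        for term in self.terms:
            if term.covariate not in _KNOWN_COVARIATES:
                raise ValueError(
                    f"unknown covariate {term.covariate!r} (not a patient-record field)"
                )
            if term.transform.type == "indicator" and term.covariate not in FLAG_FIELDS:
                raise ValueError(
                    f"indicator transform requires a flag covariate, got {term.covariate!r}"
                )
            if term.transform.type == "equals" and term.covariate not in _CATEGORICAL:
                raise ValueError(
                    f"equals transform requires a categorical covariate, got {term.covariate!r}"
                )
        if isinstance(self.centering, dict):
            covs = {t.covariate for t in self.terms}
            extra = set(self.centering) - covs
            if extra:
                raise ValueError(f"centering references covariates with no term: {sorted(extra)}")
            missing = covs - set(self.centering)
            if missing:
                raise ValueError(f"centering missing reference values for: {sorted(missing)}")
        if self.model_id == "garfield2017_death_reduced":
            covs = {t.covariate for t in self.terms}
            if covs != set(REDUCED_2017_DEATH_COVARIATES):
                raise ValueError(
                    "reduced 2017 death model must contain exactly "
                    f"{sorted(REDUCED_2017_DEATH_COVARIATES)}; got {sorted(covs)}"
                )
        return self

    # -- convenience -------------------------------------------------------

    @property
    def horizons(self) -> List[int]:
        return sorted(self.baseline_survival)

    @property
    def required_covariates(self) -> frozenset:
        return frozenset(t.covariate for t in self.terms)

    def s0(self, horizon_months: int) -> float:
        try:
            return self.baseline_survival[int(horizon_months)]
        except KeyError:
            raise ModelSpecError(
                f"model {self.model_id}: no baseline survival for horizon "
                f"{horizon_months} months (have {self.horizons})"
            ) from None


def read_model_spec(path) -> RiskModelSpec:
    """Load and validate a risk-model coefficient JSON file.

    Raises :class:`ModelSpecError` naming the offending field on any schema
    or invariant violation (S0 outside (0, 1], non-monotone S0, unknown
    covariate, missing centering entry, ...).
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelSpecError(f"{path.name}: invalid JSON ({exc})") from exc
    try:
        return RiskModelSpec.model_validate(payload)
    except ValidationError as exc:
        raise ModelSpecError(f"{path.name}: {exc}") from exc


def write_model_spec(spec: RiskModelSpec, path) -> None:
    Path(path).write_text(
        json.dumps(spec.model_dump(mode="json"), indent=2) + "\n", encoding="utf-8"
    )


def model_spec_json_schema() -> dict:
    """The machine-checkable JSON schema for coefficient files."""
    return RiskModelSpec.model_json_schema()


def bundled_model_specs() -> Dict[str, RiskModelSpec]:
    """Load the synthetic stand-in coefficient files shipped with the package.

    These are NOT the published GARFIELD-AF coefficients (which are licensed
    supplementary material); they are synthetic equations with the same
    covariate structure, so the pipeline runs end-to-end.  Real
    transcriptions drop in through the same schema.
    """
    data_dir = Path(__file__).parent / "data"
    specs = {}
    for p in sorted(data_dir.glob("synthetic_garfield*.json")):
        spec = read_model_spec(p)
        specs[spec.model_id] = spec
    return specs
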