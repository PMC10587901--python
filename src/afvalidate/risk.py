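"""Evaluate coefficient-driven Cox risk equations on a cohort.

The predicted risk of an endpoint by horizon ``t`` is

    risk(x, t) = 1 - S0(t) ** exp(lp(x)),
    lp(x) = sum_j beta_j * (f_j(x_j) - f_j(xbar_j)),

with ``S0`` the baseline survival at ``t`` and ``xbar`` the reference
covariate vector of the coefficient file (absent when the file is
pre-centered).  A patient missing any required covariate is *not evaluable*:
the linear predictor is NaN, never an imputed value — the missingness
accounting downstream relies on this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort, PatientRecord
from .errors import ModelSpecError
from .model_spec import RiskModelSpec, read_model_spec

__all__ = [
    "PredictionSet",
    "linear_predictor",
    "evaluable_mask",
    "predicted_risk",
    "predict_risks",
    "CoxRiskModel",
]


@dataclass
class PredictionSet:
    """Per-patient predictions of one model at one horizon.

    ``risk`` and ``linear_predictor`` are NaN exactly where ``evaluable`` is
    False (a required covariate was missing).
    """

    model_id: str
    horizon_months: int
    linear_predictor: pd.Series
    risk: pd.Series
    evaluable: pd.Series

    @property
    def n_evaluable(self) -> int:
        return int(self.evaluable.sum())


def linear_predictor(patients: Union[pd.DataFrame, PatientRecord], spec: RiskModelSpec):
    """Centered linear predictor; NaN where any required covariate is missing.

    Accepts a patients frame (returns a float Series aligned to its index) or
    a single :class:`PatientRecord` (returns float or None when not
    evaluable).
    """
    if isinstance(patients, PatientRecord):
        frame = _one_row_frame(patients)
        lp = _linear_predictor_frame(frame, spec)
        val = lp.iloc[0]
        return None if np.isnan(val) else float(val)
    return _linear_predictor_frame(patients, spec)


def _one_row_frame(record: PatientRecord) -> pd.DataFrame:
    from .cohort import _coerce_patient_dtypes

    frame = pd.DataFrame(
        [{name: getattr(record, name) for name in PatientRecord.field_names()}]
    ).set_index("patient_id")
    return _coerce_patient_dtypes(frame)


def _linear_predictor_frame(patients: pd.DataFrame, spec: RiskModelSpec) -> pd.Series:
    lp = np.zeros(len(patients))
    for term in spec.terms:
        if term.covariate not in patients.columns:
            raise ModelSpecError(
                f"model {spec.model_id}: cohort lacks covariate {term.covariate!r}"
            )
        fx = term.transform.apply(patients[term.covariate], term.covariate, spec.model_id)
        if isinstance(spec.centering, dict):
            fx = fx - term.transform.apply_reference(
                spec.centering[term.covariate], term.covariate, spec.model_id
            )
        lp = lp + term.beta * fx  # NaN propagates: not evaluable
    return pd.Series(lp, index=patients.index, name=f"lp_{spec.model_id}")


def evaluable_mask(patients: pd.DataFrame, spec: RiskModelSpec) -> pd.Series:
    """True where every covariate required by ``spec`` is present."""
    mask = pd.Series(True, index=patients.index)
    for cov in sorted(spec.required_covariates):
        mask &= patients[cov].notna()
    return mask


def predicted_risk(lp, spec: RiskModelSpec, horizon_months: int):
    """Cox-form risk ``1 - S0(t) ** exp(lp)`` at a horizon of the spec.

    Strictly increasing in ``lp`` whenever ``S0 < 1``; equals ``1 - S0`` at
    ``lp = 0``; identically 0 when ``S0 = 1`` (zero-hazard limit).
    """
    s0 = spec.s0(horizon_months)
    arr = np.asarray(lp, dtype=float)
    # 1 - s0**exp(lp) via expm1 for accuracy at small risks; log(1) = 0 gives
    # exactly 0 in the zero-hazard limit
    risk = -np.expm1(np.exp(arr) * np.log(s0))
    if isinstance(lp, pd.Series):
        return pd.Series(risk, index=lp.index, name=f"risk_{spec.model_id}_{horizon_months}m")
    if np.isscalar(lp) or arr.ndim == 0:
        return float(risk)
    return risk


def predict_risks(
    patients: pd.DataFrame, spec: RiskModelSpec, horizon_months: int
) -> PredictionSet:
    """Evaluate one model at one horizon over a patients frame."""
    lp = _linear_predictor_frame(patients, spec)
    risk = predicted_risk(lp, spec, horizon_months)
    return PredictionSet(
        model_id=spec.model_id,
        horizon_months=int(horizon_months),
        linear_predictor=lp,
        risk=risk,
        evaluable=lp.notna(),
    )


class CoxRiskModel(BaseEstimator):
    """sklearn-style wrapper around a fixed-coefficient Cox risk equation.

    The coefficients are inputs, not fitted: ``fit`` only resolves and
    validates the spec (a :class:`RiskModelSpec` or a path to its JSON file)
    so the estimator composes with sklearn pipelines and model selection.

    Parameters
    ----------
    spec : RiskModelSpec or path
    horizon_months : int, default 12
        Horizon whose risk ``predict`` returns; must have a baseline
        survival entry in the spec.
    """

    def __init__(self, spec=None, horizon_months: int = 12):
        self.spec = spec
        self.horizon_months = horizon_months

    def _resolve(self) -> RiskModelSpec:
        if isinstance(self.spec, RiskModelSpec):
            return self.spec
        if self.spec is None:
            raise ModelSpecError("CoxRiskModel requires a spec")
        return read_model_spec(self.spec)

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._resolve()
        spec.s0(self.horizon_months)  # horizon must exist
        missing = spec.required_covariates - set(X.columns)
        if missing:
            raise ModelSpecError(f"cohort lacks covariates {sorted(missing)}")
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Centered linear predictor (NaN = not evaluable)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "spec_")
        return _linear_predictor_frame(X, self.spec_).to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted risk in [0, 1) at ``horizon_months`` (NaN = not evaluable)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "spec_")
        ps = predict_risks(X, self.spec_, self.horizon_months)
        return ps.risk.to_numpy()

    def predict_set(self, X: pd.DataFrame) -> PredictionSet:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "spec_")
        return predict_risks(X, self.spec_, self.horizon_months)
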