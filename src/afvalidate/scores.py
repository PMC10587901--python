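"""CHA2DS2-VASc and HAS-BLED integer point scores.

Both scores use the original published component weights.  Components whose
inputs are missing score 0 and set ``complete=False`` — the score is still
returned (point scores are computable for everyone in primary-care data),
whereas the coefficient-driven risk equations in :mod:`afvalidate.risk`
refuse to evaluate incomplete patients.  Only a missing age (or, for
CHA2DS2-VASc, sex) makes the score itself undefined.

The HAS-BLED labile-INR component is excluded by default: INR stability is
unavailable in most primary-care extracts, capping the attainable score at 8
of the nominal 9 points.  Pass ``include_labile_inr=True`` to score the full
published definition when an INR-stability flag is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import PatientRecord
from .errors import AFValidateError

__all__ = [
    "PointScoreResult",
    "chads_vasc",
    "has_bled",
    "chads_vasc_scores",
    "has_bled_scores",
    "stroke_risk_stratum",
    "bleed_risk_stratum",
    "stroke_risk_strata",
    "bleed_risk_strata",
    "CHA2DS2VAScScorer",
    "HASBLEDScorer",
]

#: SBP above which hypertension counts as "uncontrolled" for HAS-BLED
UNCONTROLLED_SBP_MMHG = 160.0
#: weekly alcohol intake above which the HAS-BLED alcohol point is awarded
ALCOHOL_EXCESS_UNITS_PER_WEEK = 8.0


@dataclass
class PointScoreResult:
    """One patient's integer point score with its component breakdown.

    ``score`` is ``None`` when the score is not computable (missing age/sex).
    ``components`` maps component name to points awarded (missing inputs
    award 0); ``complete`` is False whenever any component input was missing.
    """

    patient_id: str
    score: Optional[int]
    components: Dict[str, int]
    complete: bool


def _flag_points(series: pd.Series, points: int) -> pd.Series:
    """Points for a tri-state flag as Float64 (NaN = input missing)."""
    s = series.astype("boolean")
    return s.map({True: float(points), False: 0.0}, na_action="ignore").astype("Float64")


def _chads_components(patients: pd.DataFrame) -> pd.DataFrame:
    """Per-component CHA2DS2-VASc points; NaN marks a missing input."""
    age = pd.to_numeric(patients["age"], errors="coerce")
    sex = patients["sex"]
    comp = pd.DataFrame(index=patients.index)
    comp["chf"] = _flag_points(patients["chf"], 1)
    comp["hypertension"] = _flag_points(patients["hypertension"], 1)
    comp["age_ge75"] = pd.Series(
        np.where(age.isna(), np.nan, (age >= 75).astype(float) * 2.0), index=patients.index
    ).astype("Float64")
    comp["diabetes"] = _flag_points(patients["diabetes"], 1)
    comp["prior_stroke_tia"] = _flag_points(patients["prior_stroke_tia"], 2)
    comp["vascular_disease"] = _flag_points(patients["vascular_disease"], 1)
    comp["age_65_74"] = pd.Series(
        np.where(age.isna(), np.nan, ((age >= 65) & (age < 75)).astype(float)),
        index=patients.index,
    ).astype("Float64")
    comp["female"] = pd.Series(
        np.where(sex.isna(), np.nan, (sex == "female").astype(float)), index=patients.index
    ).astype("Float64")
    return comp


def _has_bled_components(patients: pd.DataFrame, include_labile_inr: bool) -> pd.DataFrame:
    """Per-component HAS-BLED points; NaN marks a missing input.

    Hypertension is "uncontrolled" (SBP > 160 mmHg) when SBP is recorded,
    falling back to the hypertension-history flag otherwise.
    """
    age = pd.to_numeric(patients["age"], errors="coerce")
    sbp = pd.to_numeric(patients["sbp"], errors="coerce")
    alcohol = pd.to_numeric(patients["alcohol_units_per_week"], errors="coerce")
    comp = pd.DataFrame(index=patients.index)

    htn_flag = _flag_points(patients["hypertension"], 1).to_numpy(dtype=float, na_value=np.nan)
    htn = np.where(sbp.notna(), (sbp > UNCONTROLLED_SBP_MMHG).astype(float), htn_flag)
    comp["hypertension_uncontrolled"] = pd.Series(htn, index=patients.index).astype("Float64")
    comp["abnormal_renal_function"] = _flag_points(patients["abnormal_renal_function"], 1)
    comp["abnormal_liver_function"] = _flag_points(patients["abnormal_liver_function"], 1)
    comp["prior_stroke_tia"] = _flag_points(patients["prior_stroke_tia"], 1)
    comp["bleeding_history"] = _flag_points(patients["bleeding_history"], 1)
    comp["age_gt65"] = pd.Series(
        np.where(age.isna(), np.nan, (age > 65).astype(float)), index=patients.index
    ).astype("Float64")
    comp["antiplatelet_or_nsaid"] = _flag_points(patients["antiplatelet_or_nsaid"], 1)
    comp["alcohol_excess"] = pd.Series(
        np.where(alcohol.isna(), np.nan, (alcohol > ALCOHOL_EXCESS_UNITS_PER_WEEK).astype(float)),
        index=patients.index,
    ).astype("Float64")
    if include_labile_inr:
        comp["labile_inr"] = _flag_points(patients["labile_inr"], 1)
    return comp


def _summarise(comp: pd.DataFrame, undefined: pd.Series) -> pd.DataFrame:
    """Fold a component table into (score, complete); NaN components score 0."""
    score = comp.sum(axis=1, skipna=True).astype("Float64")
    complete = ~comp.isna().any(axis=1)
    score[undefined] = pd.NA
    return pd.DataFrame(
        {"score": score, "complete": complete & ~undefined}, index=comp.index
    )


def chads_vasc_scores(patients: pd.DataFrame) -> pd.DataFrame:
    """Vectorised CHA2DS2-VASc over a patients table.

    Returns a frame with nullable ``score`` (NA when age or sex is missing)
    and boolean ``complete``.
    """
    comp = _chads_components(patients)
    undefined = pd.to_numeric(patients["age"], errors="coerce").isna() | patients["sex"].isna()
    return _summarise(comp, undefined)


def has_bled_scores(patients: pd.DataFrame, include_labile_inr: bool = False) -> pd.DataFrame:
    """Vectorised HAS-BLED (modified: no labile-INR point unless requested)."""
    comp = _has_bled_components(patients, include_labile_inr)
    undefined = pd.to_numeric(patients["age"], errors="coerce").isna()
    return _summarise(comp, undefined)


def _single(record: PatientRecord, comp_fn) -> PointScoreResult:
    frame = pd.DataFrame([{
        name: getattr(record, name) for name in PatientRecord.field_names()
    }]).set_index("patient_id")
    from .cohort import _coerce_patient_dtypes  # local import: avoid cycle at module load

    frame = _coerce_patient_dtypes(frame)
    comp = comp_fn(frame)
    row = comp.iloc[0]
    components = {name: int(v) if pd.notna(v) else 0 for name, v in row.items()}
    complete = not row.isna().any()
    return PointScoreResult(
        patient_id=record.patient_id,
        score=int(row.sum(skipna=True)),
        components=components,
        complete=complete,
    )


def chads_vasc(record: PatientRecord) -> PointScoreResult:
    """CHA2DS2-VASc for one patient (0-9): CHF +1, hypertension +1,
    age >= 75 +2, diabetes +1, prior stroke/TIA +2, vascular disease +1,
    age 65-74 +1, female sex +1."""
    if record.age is None or record.sex is None:
        return PointScoreResult(record.patient_id, None, {}, False)
    return _single(record, _chads_components)


def has_bled(record: PatientRecord, include_labile_inr: bool = False) -> PointScoreResult:
    """HAS-BLED for one patient: one point each for uncontrolled hypertension,
    abnormal renal function, abnormal liver function, prior stroke, bleeding
    history, age > 65, antiplatelet/NSAID use, alcohol excess
    (> 8 units/week) and — only when ``include_labile_inr`` — labile INR.
    Maximum 8 without the INR point, 9 with it."""
    if record.age is None:
        return PointScoreResult(record.patient_id, None, {}, False)
    return _single(record, lambda p: _has_bled_components(p, include_labile_inr))


# ---------------------------------------------------------------------------
# risk strata


def stroke_risk_stratum(score: int) -> str:
    """CHA2DS2-VASc stratum: low = 0, moderate = 1, high >= 2."""
    score = int(score)
    if not 0 <= score <= 9:
        raise AFValidateError(f"CHA2DS2-VASc score {score} outside [0, 9]")
    if score == 0:
        return "low"
    if score == 1:
        return "moderate"
    return "high"


def bleed_risk_stratum(score: int) -> str:
    """HAS-BLED stratum: lower if < 2, higher if >= 2.

    The source subgrouping ("< 2 or > 2") leaves a score of exactly 2
    unassigned; this package assigns 2 to "higher" as a documented
    convention.
    """
    score = int(score)
    if not 0 <= score <= 9:
        raise AFValidateError(f"HAS-BLED score {score} outside [0, 9]")
    return "lower" if score < 2 else "higher"


def stroke_risk_strata(scores: pd.Series) -> pd.Series:
    s = pd.to_numeric(scores, errors="coerce")
    if ((s < 0) | (s > 9)).any():
        raise AFValidateError("CHA2DS2-VASc scores outside [0, 9]")
    out = pd.Series(pd.NA, index=scores.index, dtype="string")
    out[s == 0] = "low"
    out[s == 1] = "moderate"
    out[s >= 2] = "high"
    return out


def bleed_risk_strata(scores: pd.Series) -> pd.Series:
    s = pd.to_numeric(scores, errors="coerce")
    if ((s < 0) | (s > 9)).any():
        raise AFValidateError("HAS-BLED scores outside [0, 9]")
    out = pd.Series(pd.NA, index=scores.index, dtype="string")
    out[s < 2] = "lower"
    out[s >= 2] = "higher"
    return out


# ---------------------------------------------------------------------------
# sklearn-style scorers


class _PointScorer(BaseEstimator, TransformerMixin):
    """Base for stateless point-score transformers over a patients frame."""

    def fit(self, X: pd.DataFrame, y=None):
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    @staticmethod
    def _validate(X) -> None:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a patients DataFrame (see afvalidate.cohort)")

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        self._validate(X)
        scores = self._score_frame(X)["score"]
        return scores.to_numpy(dtype=float, na_value=np.nan).reshape(-1, 1)

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Scores plus completeness flags, index-aligned with ``X``."""
        self._validate(X)
        return self._score_frame(X)


class CHA2DS2VAScScorer(_PointScorer):
    """Transformer mapping a patients frame to CHA2DS2-VASc scores (0-9).

    ``transform`` returns an (n, 1) float array with NaN where the score is
    undefined (missing age or sex); use :meth:`score_frame` for completeness
    flags.
    """

    def _score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        return chads_vasc_scores(X)


class HASBLEDScorer(_PointScorer):
    """Transformer mapping a patients frame to HAS-BLED scores.

    Parameters
    ----------
    include_labile_inr : bool, default False
        Award the labile-INR point (full 0-9 definition) instead of the
        modified 0-8 score used when INR stability is unrecorded.
    """

    def __init__(self, include_labile_inr: bool = False):
        self.include_labile_inr = include_labile_inr

    def _score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        return has_bled_scores(X, include_labile_inr=self.include_labile_inr)
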