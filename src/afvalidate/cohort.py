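"""Cohort data model and delimited-text I/O.

A cohort is one row per patient with covariates measured at AF diagnosis and,
per endpoint, a follow-up time in days and an event indicator.  History and
treatment flags are tri-state (true / false / missing): the missingness
accounting downstream must distinguish "recorded absent" from "not recorded",
so a blank cell is parsed to missing, never to false.

On disk the cohort is a UTF-8 CSV/TSV with a header row; the single missing
sentinel is the empty cell.  Dates are pre-resolved to ``time_*`` day counts
by the data preparer — this package never parses calendar dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

ENDPOINTS = ("death", "stroke_se", "major_bleed")

#: tri-state medical-history flags
HISTORY_FLAGS = (
    "chf",
    "hypertension",
    "diabetes",
    "prior_stroke_tia",
    "vascular_disease",
    "peripheral_vascular_disease",
    "carotid_occlusive_disease",
    "bleeding_history",
    "ckd_grade3plus",
    "cirrhosis",
    "current_smoker",
    "sleep_apnoea",
    "dementia",
    "paroxysmal_af",
    "abnormal_renal_function",
    "abnormal_liver_function",
    "labile_inr",
)

#: tri-state treatment flags at diagnosis
TREATMENT_FLAGS = ("oac", "noac", "vka", "antiplatelet_or_nsaid")

FLAG_FIELDS = HISTORY_FLAGS + TREATMENT_FLAGS

#: optional continuous covariates
NUMERIC_OPTIONAL = ("pulse", "sbp", "dbp", "weight", "height", "alcohol_units_per_week")

SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("white", "asian", "black_mixed_other")

#: mandatory cohort columns
MANDATORY_COLUMNS = ("patient_id", "age", "sex") + tuple(
    f"{prefix}_{ep}" for ep in ENDPOINTS for prefix in ("time", "event")
)

PATIENT_COLUMNS = (
    ("age", "sex", "ethnicity") + NUMERIC_OPTIONAL + FLAG_FIELDS
)

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


@dataclass
class PatientRecord:
    """One patient's covariates at AF diagnosis.

    ``None`` means missing.  Flags are tri-state: ``True`` / ``False`` /
    ``None``.  ``labile_inr`` exists so the full HAS-BLED score is computable
    when INR stability is recorded; in primary-care extracts it is typically
    missing, capping the attainable score at 8.
    """

    patient_id: str
    age: float
    sex: str
    ethnicity: Optional[str] = None
    pulse: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    weight: Optional[float] = None
    height: Optional[float] = None
    alcohol_units_per_week: Optional[float] = None
    chf: Optional[bool] = None
    hypertension: Optional[bool] = None
    diabetes: Optional[bool] = None
    prior_stroke_tia: Optional[bool] = None
    vascular_disease: Optional[bool] = None
    peripheral_vascular_disease: Optional[bool] = None
    carotid_occlusive_disease: Optional[bool] = None
    bleeding_history: Optional[bool] = None
    ckd_grade3plus: Optional[bool] = None
    cirrhosis: Optional[bool] = None
    current_smoker: Optional[bool] = None
    sleep_apnoea: Optional[bool] = None
    dementia: Optional[bool] = None
    paroxysmal_af: Optional[bool] = None
    abnormal_renal_function: Optional[bool] = None
    abnormal_liver_function: Optional[bool] = None
    labile_inr: Optional[bool] = None
    oac: Optional[bool] = None
    noac: Optional[bool] = None
    vka: Optional[bool] = None
    antiplatelet_or_nsaid: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age is None or not np.isfinite(self.age):
            raise CohortValidationError(f"patient {self.patient_id}: age is required")
        if self.age < 18:
            raise CohortValidationError(
                f"patient {self.patient_id}: age {self.age} < 18 (adult cohort)"
            )
        if self.sex not in SEX_LEVELS:
            raise CohortValidationError(
                f"patient {self.patient_id}: sex must be one of {SEX_LEVELS}"
            )
        if self.ethnicity is not None and self.ethnicity not in ETHNICITY_LEVELS:
            raise CohortValidationError(
                f"patient {self.patient_id}: ethnicity must be one of {ETHNICITY_LEVELS}"
            )
        _check_vitals(self.patient_id, self.pulse, self.sbp, self.dbp, self.weight, self.height)
        if None not in (self.oac, self.noac, self.vka) and self.oac != (self.noac or self.vka):
            raise CohortValidationError(
                f"patient {self.patient_id}: oac must equal (noac OR vka)"
            )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))


def _check_vitals(pid, pulse, sbp, dbp, weight, height) -> None:
    if height is not None and not 0 < height < 2.6:
        raise CohortValidationError(f"patient {pid}: height {height} m out of (0, 2.6)")
    if weight is not None and weight <= 0:
        raise CohortValidationError(f"patient {pid}: weight must be positive")
    if pulse is not None and pulse <= 0:
        raise CohortValidationError(f"patient {pid}: pulse must be positive")
    if sbp is not None and dbp is not None and not sbp > dbp > 0:
        raise CohortValidationError(f"patient {pid}: need sbp > dbp > 0")
    elif sbp is not None and sbp <= 0:
        raise CohortValidationError(f"patient {pid}: sbp must be positive")
    elif dbp is not None and dbp <= 0:
        raise CohortValidationError(f"patient {pid}: dbp must be positive")


@dataclass
class OutcomeRecord:
    """Per-endpoint follow-up: days from index date and first-event indicator.

    Follow-up ends at the first occurrence of the endpoint, death, practice
    deregistration or last data collection, whichever is first; ``event=0``
    means censored at ``time_days``.
    """

    patient_id: str
    endpoint: str
    time_days: float
    event: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise CohortValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.time_days < 0 or not np.isfinite(self.time_days):
            raise CohortValidationError(
                f"patient {self.patient_id}: time_days must be finite and >= 0"
            )
        if self.event not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id}: event must be 0 or 1"
            )


@dataclass
class Cohort:
    """In-memory cohort: a patients table and a long outcomes table.

    ``patients`` is indexed by ``patient_id``; flags use pandas' nullable
    boolean dtype so tri-state survives vectorised operations.  ``outcomes``
    has columns ``patient_id, endpoint, time_days, event`` with exactly one
    row per (patient, endpoint).
    """

    patients: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> pd.Index:
        return self.patients.index

    def endpoint_outcomes(self, endpoint: str) -> pd.DataFrame:
        """Times/events for one endpoint, aligned to ``patients.index``."""
        sub = self.outcomes[self.outcomes["endpoint"] == endpoint]
        sub = sub.set_index("patient_id").loc[self.patients.index]
        return sub[["time_days", "event"]]

    def subset(self, patient_ids) -> "Cohort":
        ids = pd.Index(patient_ids)
        patients = self.patients.loc[ids]
        outcomes = self.outcomes[self.outcomes["patient_id"].isin(set(ids))].reset_index(
            drop=True
        )
        return Cohort(patients=patients, outcomes=outcomes)

    def sorted(self) -> "Cohort":
        """Canonical order: patients by id, outcomes by (id, endpoint)."""
        patients = self.patients.sort_index(kind="stable")
        outcomes = self.outcomes.sort_values(
            ["patient_id", "endpoint"], kind="stable"
        ).reset_index(drop=True)
        return Cohort(patients=patients, outcomes=outcomes)

    def patient_records(self) -> Iterator[PatientRecord]:
        for pid, row in self.patients.iterrows():
            yield patient_record_from_row(pid, row)

    def outcome_records(self) -> Iterator[OutcomeRecord]:
        for _, row in self.outcomes.iterrows():
            yield OutcomeRecord(
                patient_id=row["patient_id"],
                endpoint=row["endpoint"],
                time_days=float(row["time_days"]),
                event=int(row["event"]),
            )

    @classmethod
    def from_records(cls, patients, outcomes) -> "Cohort":
        pdf = pd.DataFrame([_record_to_dict(p) for p in patients]).set_index("patient_id")
        pdf = _coerce_patient_dtypes(pdf)
        odf = pd.DataFrame(
            [
                {
                    "patient_id": o.patient_id,
                    "endpoint": o.endpoint,
                    "time_days": float(o.time_days),
                    "event": int(o.event),
                }
                for o in outcomes
            ]
        )
        return cls(patients=pdf, outcomes=odf)


def _record_to_dict(rec: PatientRecord) -> dict:
    return {name: getattr(rec, name) for name in PatientRecord.field_names()}


def patient_record_from_row(pid: str, row: pd.Series) -> PatientRecord:
    kwargs = {"patient_id": str(pid)}
    for name in PatientRecord.field_names():
        if name == "patient_id":
            continue
        val = row.get(name, pd.NA)
        if pd.isna(val):
            kwargs[name] = None
        elif name in FLAG_FIELDS:
            kwargs[name] = bool(val)
        elif name in ("sex", "ethnicity"):
            kwargs[name] = str(val)
        else:
            kwargs[name] = float(val)
    return PatientRecord(**kwargs)


def _coerce_patient_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in FLAG_FIELDS:
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = df[col].astype("boolean")
    for col in ("age",) + NUMERIC_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    for col in ("sex", "ethnicity"):
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = df[col].astype("string")
    # stable canonical column order
    return df[list(PATIENT_COLUMNS)]


# ---------------------------------------------------------------------------
# reading / writing


def read_cohort(
    path, schema: Optional[Mapping[str, str]] = None, delimiter: Optional[str] = None
) -> Cohort:
    """Read a delimited cohort table into a validated :class:`Cohort`.

    Parameters
    ----------
    path : str or Path
        CSV (default) or TSV file with a header row; empty cells are missing.
    schema : mapping, optional
        Map from canonical column name (e.g. ``"age"``) to the actual column
        name in the file.
    delimiter : str, optional
        Inferred from the extension (``.tsv`` → tab) when omitted.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names it).
    CohortValidationError
        If a value violates a data-model invariant; unparseable numerics are
        reported with their 1-based data row number.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    if schema:
        rename = {actual: canonical for canonical, actual in schema.items()}
        raw = raw.rename(columns=rename)

    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path.name}")

    raw = raw.replace("", pd.NA)
    n = len(raw)

    def parse_numeric(col: str, required: bool) -> pd.Series:
        if col not in raw.columns:
            return pd.Series(np.nan, index=raw.index)
        s = raw[col]
        out = pd.to_numeric(s, errors="coerce")
        bad = s.notna() & out.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CohortValidationError(
                f"column {col!r}: unparseable numeric {s[bad].iloc[0]!r} at data row {row}"
            )
        if required and s.isna().any():
            row = int(np.flatnonzero(s.isna().to_numpy())[0]) + 1
            raise SchemaError(f"column {col!r}: missing value at data row {row}")
        return out.astype(float)

    def parse_flag(col: str) -> pd.Series:
        if col not in raw.columns:
            return pd.Series(pd.NA, index=raw.index, dtype="boolean")
        s = raw[col].str.strip().str.lower()
        out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
        out[s.isin(_TRUE_TOKENS)] = True
        out[s.isin(_FALSE_TOKENS)] = False
        bad = s.notna() & ~s.isin(_TRUE_TOKENS | _FALSE_TOKENS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CohortValidationError(
                f"column {col!r}: unparseable flag {raw[col][bad].iloc[0]!r} at data row {row}"
            )
        return out

    if raw["patient_id"].isna().any():
        raise SchemaError("column 'patient_id': missing value")
    ids = raw["patient_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise CohortValidationError(f"duplicate patient_id {dup!r}")

    patients = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    patients["age"] = parse_numeric("age", required=True).to_numpy()
    sex = raw["sex"].str.strip().str.lower()
    bad_sex = sex.isna() | ~sex.isin(SEX_LEVELS)
    if bad_sex.any():
        raise CohortValidationError(
            f"column 'sex': invalid value {raw['sex'][bad_sex].iloc[0]!r}"
            f" at data row {int(np.flatnonzero(bad_sex.to_numpy())[0]) + 1}"
        )
    patients["sex"] = sex.to_numpy()
    if "ethnicity" in raw.columns:
        eth = raw["ethnicity"].str.strip().str.lower()
        bad = eth.notna() & ~eth.isin(ETHNICITY_LEVELS)
        if bad.any():
            raise CohortValidationError(
                f"column 'ethnicity': invalid value {raw['ethnicity'][bad].iloc[0]!r}"
            )
        patients["ethnicity"] = eth.to_numpy()
    else:
        patients["ethnicity"] = pd.NA
    for col in NUMERIC_OPTIONAL:
        patients[col] = parse_numeric(col, required=False).to_numpy()
    for col in FLAG_FIELDS:
        patients[col] = parse_flag(col).to_numpy()
    patients = _coerce_patient_dtypes(patients.reset_index().set_index("patient_id"))

    under_age = patients.index[patients["age"] < 18].tolist()
    if under_age:
        raise CohortValidationError(
            f"age < 18 for patient ids {under_age} (cohort is adults >= 18)"
        )
    _validate_patients_frame(patients)

    frames = []
    for ep in ENDPOINTS:
        t = parse_numeric(f"time_{ep}", required=True)
        e = parse_numeric(f"event_{ep}", required=True)
        if (t < 0).any():
            row = int(np.flatnonzero((t < 0).to_numpy())[0]) + 1
            raise CohortValidationError(f"column 'time_{ep}': negative time at data row {row}")
        if ~e.isin([0.0, 1.0]).all():
            raise CohortValidationError(f"column 'event_{ep}': events must be 0 or 1")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids.to_numpy(),
                    "endpoint": ep,
                    "time_days": t.to_numpy(),
                    "event": e.astype(int).to_numpy(),
                }
            )
        )
    outcomes = pd.concat(frames, ignore_index=True)
    return Cohort(patients=patients, outcomes=outcomes)


def _validate_patients_frame(patients: pd.DataFrame) -> None:
    """Vectorised invariant checks mirroring :class:`PatientRecord`."""

    def offending(mask, msg):
        mask = mask.fillna(False).to_numpy() if hasattr(mask, "fillna") else mask
        if mask.any():
            ids = patients.index[mask].tolist()[:5]
            raise CohortValidationError(f"{msg}; offending ids {ids}")

    h = patients["height"]
    offending((h <= 0) | (h >= 2.6), "height out of (0, 2.6) m")
    offending(patients["weight"] <= 0, "weight must be positive")
    offending(patients["pulse"] <= 0, "pulse must be positive")
    sbp, dbp = patients["sbp"], patients["dbp"]
    offending(sbp.notna() & dbp.notna() & ~(sbp > dbp), "need sbp > dbp")
    offending(dbp <= 0, "dbp must be positive")
    offending(sbp <= 0, "sbp must be positive")
    oac, noac, vka = patients["oac"], patients["noac"], patients["vka"]
    all_present = oac.notna() & noac.notna() & vka.notna()
    offending(all_present & (oac != (noac | vka)), "oac must equal (noac OR vka)")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV/TSV, missing values as empty cells (round-trips)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    wide = cohort.patients.copy()
    for col in FLAG_FIELDS:
        wide[col] = wide[col].map({True: "1", False: "0"}, na_action="ignore")
    for ep in ENDPOINTS:
        sub = cohort.endpoint_outcomes(ep)
        wide[f"time_{ep}"] = sub["time_days"].to_numpy()
        wide[f"event_{ep}"] = sub["event"].to_numpy()
    wide.reset_index().to_csv(path, sep=delimiter, index=False, na_rep="")
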