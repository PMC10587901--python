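"""Synthetic incident-AF cohort generator with known ground truth.

The generator emulates a UK primary-care incident-AF population: covariates
are drawn at configurable prevalences (defaults match a large published
incident-AF validation cohort — mean age 74.6, 46.7% female, 70.8%
hypertensive, 50.6% anticoagulated at diagnosis, ...), event times for
death, ischaemic stroke/systemic embolism and major bleeding come from
Weibull-baseline Cox models with known coefficients, and follow-up is cut by
exponential dropout and an administrative horizon.  Death ends follow-up for
the other two endpoints (cause-specific censoring, not a competing-risks
sub-distribution).

Because the truth is known, every pipeline stage is testable: the evaluated
risk model can be the generating model itself (perfect calibration by
construction), or the true hazards can be inflated relative to it
(:func:`inject_miscalibration`) to produce controlled underprediction, and
MCAR missingness can be injected at per-variable rates to exercise the
missingness accounting.

Joint covariate structure is deliberately simple: flags are Bernoulli with a
logistic age link (intercepts solved so empirical marginals hit their
targets), vitals are truncated normals, and no further correlation is
modelled.

All randomness flows through one ``numpy`` Generator seeded from the config;
the order of draws is fixed, so a seed fully determines the cohort.
"""

from __future__ import annotations

import math
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy import optimize, special, stats

from .cohort import ENDPOINTS, FLAG_FIELDS, Cohort, _coerce_patient_dtypes
from .errors import ConfigError
from .model_spec import DAYS_PER_MONTH, RiskModelSpec, Term, Transform, months_to_days

__all__ = [
    "TrueEndpointModel",
    "SimulationConfig",
    "default_config",
    "generate_covariates",
    "simulate_outcomes",
    "simulate_cohort",
    "true_risk",
    "inject_missingness",
    "inject_miscalibration",
    "spec_from_true_model",
]

#: default flag prevalences of the emulated incident-AF cohort
DEFAULT_PREVALENCES: Dict[str, float] = {
    "chf": 0.069,
    "hypertension": 0.708,
    "diabetes": 0.137,
    "prior_stroke_tia": 0.107,
    "vascular_disease": 0.085,
    "peripheral_vascular_disease": 0.021,
    "carotid_occlusive_disease": 0.004,
    "bleeding_history": 0.068,
    "ckd_grade3plus": 0.143,
    "cirrhosis": 0.003,
    "current_smoker": 0.062,
    "sleep_apnoea": 0.010,
    "dementia": 0.022,
    "paroxysmal_af": 0.134,
    "abnormal_renal_function": 0.016,
    "abnormal_liver_function": 0.010,
    "labile_inr": 0.0,
    "antiplatelet_or_nsaid": 0.395,
    "oac": 0.506,
}

#: log-odds-per-year age tilt of the age-associated flags
DEFAULT_AGE_TILTS: Dict[str, float] = {
    "chf": 0.05,
    "hypertension": 0.05,
    "diabetes": 0.01,
    "prior_stroke_tia": 0.04,
    "vascular_disease": 0.04,
    "peripheral_vascular_disease": 0.03,
    "carotid_occlusive_disease": 0.03,
    "ckd_grade3plus": 0.08,
    "dementia": 0.10,
    "current_smoker": -0.04,
}


class TrueEndpointModel(BaseModel):
    """The data-generating Cox model of one endpoint.

    Hazard: ``h(t | x) = multiplier * h0(t) * exp(lp(x) + loghr_oac * oac)``
    with a Weibull baseline ``h0`` of the given shape and scale (days).
    ``hazard_multiplier`` scales the *true* hazard only — the evaluated risk
    model is built without it, so a multiplier of 1 means the model is
    perfectly specified and anything else is controlled miscalibration.
    """

    model_config = ConfigDict(extra="forbid")

    weibull_shape: float = Field(gt=0)
    weibull_scale_days: float = Field(gt=0)
    terms: List[Term] = Field(default_factory=list)
    centering: Dict[str, float] = Field(default_factory=dict)
    treatment_loghr: float = 0.0
    #: 0 is allowed and yields no events at all (zero-hazard limit)
    hazard_multiplier: float = Field(default=1.0, ge=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = Field(ge=1)
    seed: int
    age_mean: float = 74.6
    age_sd: float = 12.2
    age_min: float = 18.0
    female_fraction: float = Field(default=0.467, ge=0, le=1)
    ethnicity_probs: Tuple[float, float, float] = (0.952, 0.016, 0.032)
    pulse_mean: float = 79.2
    pulse_sd: float = 18.9
    sbp_mean: float = 134.8
    sbp_sd: float = 19.6
    pulse_pressure_mean: float = 57.4
    pulse_pressure_sd: float = 12.0
    weight_mean: float = 81.3
    weight_sd: float = 21.0
    height_mean: float = 1.68
    height_sd: float = 0.10
    alcohol_excess_fraction: float = Field(default=0.071, ge=0, le=1)
    prevalences: Dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_tilts: Dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_AGE_TILTS))
    noac_given_oac: float = Field(default=0.435, ge=0, le=1)
    endpoints: Dict[Literal["death", "stroke_se", "major_bleed"], TrueEndpointModel]
    admin_censor_days: float = Field(default=5 * 365.25, gt=0)
    dropout_rate_per_day: float = Field(default=5e-5, ge=0)
    missingness: Dict[str, float] = Field(default_factory=dict)

    @field_validator("prevalences")
    @classmethod
    def _prev_valid(cls, v):
        for name, p in v.items():
            if name not in FLAG_FIELDS:
                raise ValueError(f"prevalence for unknown flag {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} = {p} outside [0, 1]")
        return v

    @field_validator("missingness")
    @classmethod
    def _miss_valid(cls, v):
        for name, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness rate of {name!r} = {p} outside [0, 1]")
        return v


def _scale_for_one_year_risk(q: float) -> float:
    """Weibull(shape 1) scale whose baseline 1-year risk is ``q``."""
    return 365.25 / -math.log1p(-q)


def default_config(n: int, seed: int, **overrides) -> SimulationConfig:
    """Study-condition defaults: Weibull baselines whose 1-year risks at the
    covariate reference match the observed incident-AF KM risks (death
    11.89%, stroke/SE 8.29%, major bleeding 6.32%), protective anticoagulant
    log-hazards matching the published adjusted HRs (0.58 death, 0.71
    stroke, 0.90 bleeding), and moderate covariate effects."""

    def T(cov, beta, transform=None):
        return Term(covariate=cov, beta=beta, transform=transform or Transform(type="linear"))

    ind = Transform(type="indicator")
    female = Transform(type="equals", level="female")

    death = TrueEndpointModel(
        weibull_shape=1.0,
        weibull_scale_days=_scale_for_one_year_risk(0.1189),
        terms=[
            T("age", 0.07),
            T("pulse", 0.010),
            T("sbp", -0.006),
            T("chf", 0.60, ind),
            T("ckd_grade3plus", 0.40, ind),
            T("vascular_disease", 0.30, ind),
            T("bleeding_history", 0.20, ind),
            T("current_smoker", 0.45, ind),
            T("diabetes", 0.30, ind),
        ],
        centering={
            "age": 74.6, "pulse": 79.2, "sbp": 134.8, "chf": 0.0,
            "ckd_grade3plus": 0.0, "vascular_disease": 0.0,
            "bleeding_history": 0.0, "current_smoker": 0.0, "diabetes": 0.0,
        },
        treatment_loghr=math.log(0.58),
    )
    stroke = TrueEndpointModel(
        weibull_shape=1.0,
        weibull_scale_days=_scale_for_one_year_risk(0.0829),
        terms=[
            T("age", 0.05),
            T("prior_stroke_tia", 0.80, ind),
            T("hypertension", 0.30, ind),
            T("diabetes", 0.30, ind),
            T("vascular_disease", 0.20, ind),
            T("chf", 0.20, ind),
            T("sex", 0.10, female),
        ],
        centering={
            "age": 74.6, "prior_stroke_tia": 0.0, "hypertension": 0.0,
            "diabetes": 0.0, "vascular_disease": 0.0, "chf": 0.0, "sex": 0.0,
        },
        treatment_loghr=math.log(0.71),
    )
    bleed = TrueEndpointModel(
        weibull_shape=1.0,
        weibull_scale_days=_scale_for_one_year_risk(0.0632),
        terms=[
            T("age", 0.04),
            T("bleeding_history", 0.90, ind),
            T("abnormal_renal_function", 0.40, ind),
            T("abnormal_liver_function", 0.40, ind),
            T("antiplatelet_or_nsaid", 0.30, ind),
            T("hypertension", 0.20, ind),
        ],
        centering={
            "age": 74.6, "bleeding_history": 0.0, "abnormal_renal_function": 0.0,
            "abnormal_liver_function": 0.0, "antiplatelet_or_nsaid": 0.0,
            "hypertension": 0.0,
        },
        treatment_loghr=math.log(0.90),
    )
    payload = dict(
        n=n,
        seed=seed,
        endpoints={"death": death, "stroke_se": stroke, "major_bleed": bleed},
    )
    payload.update(overrides)
    return SimulationConfig(**payload)


# ---------------------------------------------------------------------------
# covariates


def _flag_intercept(p: float, tilt: float, age_dev: np.ndarray) -> float:
    """Intercept c with mean(expit(c + tilt * age_dev)) = p (marginal hit)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    if tilt == 0.0:
        return float(special.logit(p))

    def gap(c):
        return float(np.mean(special.expit(c + tilt * age_dev)) - p)

    return float(optimize.brentq(gap, -40.0, 40.0))


def generate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw a patients frame (indexed ``S<number>``) per the config.

    Draw order is fixed (age, sex, ethnicity, vitals, alcohol, flags in
    schema order, treatment split), so a seed fully determines the output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    eth_p = np.asarray(config.ethnicity_probs, dtype=float)
    eth_p = eth_p / eth_p.sum()
    ethnicity = rng.choice(
        np.array(["white", "asian", "black_mixed_other"]), size=n, p=eth_p
    )
    pulse = np.maximum(30.0, rng.normal(config.pulse_mean, config.pulse_sd, n))
    sbp = np.maximum(80.0, rng.normal(config.sbp_mean, config.sbp_sd, n))
    pp = np.maximum(10.0, rng.normal(config.pulse_pressure_mean, config.pulse_pressure_sd, n))
    dbp = np.maximum(30.0, sbp - pp)
    sbp = np.maximum(sbp, dbp + 5.0)  # keep sbp > dbp after flooring
    weight = np.maximum(35.0, rng.normal(config.weight_mean, config.weight_sd, n))
    height = np.clip(rng.normal(config.height_mean, config.height_sd, n), 1.3, 2.1)
    # alcohol: light drinkers uniform on (0, 8], the excess tail uniform (8, 40]
    excess = rng.random(n) < config.alcohol_excess_fraction
    alcohol = np.where(excess, rng.uniform(8.0, 40.0, n), rng.uniform(0.0, 8.0, n))

    frame = pd.DataFrame(
        {
            "age": age, "sex": sex, "ethnicity": ethnicity, "pulse": pulse,
            "sbp": sbp, "dbp": dbp, "weight": weight, "height": height,
            "alcohol_units_per_week": alcohol,
        },
        index=pd.Index([f"S{i:07d}" for i in range(n)], name="patient_id"),
    )

    age_dev = age - config.age_mean
    for flag in FLAG_FIELDS:
        if flag in ("oac", "noac", "vka"):
            continue  # treatment drawn jointly below
        p = config.prevalences.get(flag, 0.0)
        tilt = config.age_tilts.get(flag, 0.0)
        c = _flag_intercept(p, tilt, age_dev)
        prob = special.expit(c + tilt * age_dev) if np.isfinite(c) else np.full(n, float(p > 0))
        frame[flag] = rng.random(n) < prob

    p_oac = config.prevalences.get("oac", 0.0)
    oac = rng.random(n) < p_oac
    noac = oac & (rng.random(n) < config.noac_given_oac)
    frame["oac"] = oac
    frame["noac"] = noac
    frame["vka"] = oac & ~noac
    return _coerce_patient_dtypes(frame)


# ---------------------------------------------------------------------------
# outcomes


def _true_lp(patients: pd.DataFrame, model: TrueEndpointModel) -> np.ndarray:
    """Centered linear predictor of the true model, incl. treatment term."""
    lp = np.zeros(len(patients))
    for term in model.terms:
        fx = term.transform.apply(patients[term.covariate], term.covariate, "true_model")
        ref = model.centering.get(term.covariate)
        if ref is not None:
            fx = fx - term.transform.apply_reference(ref, term.covariate, "true_model")
        lp = lp + term.beta * fx
    if model.treatment_loghr != 0.0:
        oac = (
            patients["oac"].astype("boolean")
            .map({True: 1.0, False: 0.0}, na_action="ignore")
            .to_numpy(dtype=float, na_value=np.nan)
        )
        lp = lp + model.treatment_loghr * oac
    if np.isnan(lp).any():
        raise ConfigError(
            "simulate_outcomes requires complete covariates; inject missingness "
            "after simulating outcomes"
        )
    return lp


def _weibull_event_times(rng, model: TrueEndpointModel, lp: np.ndarray) -> np.ndarray:
    """Inverse-transform sample: T = scale * (-log U / (m * exp(lp)))^(1/shape)."""
    u = rng.random(len(lp))  # always drawn, so the stream position is multiplier-free
    if model.hazard_multiplier == 0:
        return np.full(len(lp), np.inf)
    rate = model.hazard_multiplier * np.exp(lp)
    return model.weibull_scale_days * np.power(-np.log(u) / rate, 1.0 / model.weibull_shape)


def simulate_outcomes(patients: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Long outcomes table (patient_id, endpoint, time_days, event).

    Event times are drawn per endpoint from the true Cox-Weibull models;
    observed time is the minimum of the event time, exponential dropout and
    the administrative horizon, and death additionally truncates stroke and
    bleeding follow-up.  Draws consume the generator in a fixed order
    (dropout, then endpoints in schema order).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(patients)
    if config.dropout_rate_per_day > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate_per_day, n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(dropout, config.admin_censor_days)

    raw_times = {}
    for ep in ENDPOINTS:
        model = config.endpoints[ep]
        lp = _true_lp(patients, model)
        raw_times[ep] = _weibull_event_times(rng, model, lp)

    death_obs = np.minimum(raw_times["death"], censor)
    frames = []
    for ep in ENDPOINTS:
        if ep == "death":
            end = censor
        else:
            end = death_obs  # death or earlier censoring ends follow-up
        obs = np.minimum(raw_times[ep], end)
        event = (raw_times[ep] <= end).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patients.index.to_numpy(),
                    "endpoint": ep,
                    "time_days": obs,
                    "event": event,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def true_risk(
    patients: pd.DataFrame, config: SimulationConfig, endpoint: str, horizon_days: float
) -> pd.Series:
    """Ground-truth event risk by ``horizon_days`` under the true model."""
    model = config.endpoints[endpoint]
    lp = _true_lp(patients, model)
    cum_h0 = (horizon_days / model.weibull_scale_days) ** model.weibull_shape
    risk = 1.0 - np.exp(-cum_h0 * model.hazard_multiplier * np.exp(lp))
    return pd.Series(risk, index=patients.index, name=f"true_risk_{endpoint}")


def simulate_cohort(config: SimulationConfig) -> Tuple[Cohort, pd.DataFrame]:
    """Covariates + outcomes + (optional) missingness, with a truth sidecar.

    The sidecar has, per patient, the true linear predictor and the true
    1-year risk of each endpoint, computed before missingness injection.
    """
    patients = generate_covariates(config)
    outcomes = simulate_outcomes(patients, config)
    truth = pd.DataFrame(index=patients.index)
    for ep in ENDPOINTS:
        truth[f"lp_{ep}"] = _true_lp(patients, config.endpoints[ep])
        truth[f"risk12_{ep}"] = true_risk(patients, config, ep, months_to_days(12))
    if config.missingness:
        patients = inject_missingness(patients, config.missingness, seed=config.seed)
    return Cohort(patients=patients, outcomes=outcomes), truth


# ---------------------------------------------------------------------------
# injectors


def inject_missingness(
    patients: pd.DataFrame, rates: Dict[str, float], seed: int, rng=None
) -> pd.DataFrame:
    """MCAR per-variable deletion at the given rates (outcomes untouched).

    Reproducible: the mask stream is seeded independently of the covariate
    draws, and variables are processed in sorted name order.
    """
    for name, r in rates.items():
        if name not in patients.columns:
            raise ConfigError(f"missingness rate for unknown variable {name!r}")
        if not 0.0 <= r <= 1.0:
            raise ConfigError(f"missingness rate of {name!r} = {r} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out = patients.copy()
    for name in sorted(rates):
        r = rates[name]
        if r == 0.0:
            continue
        mask = rng.random(len(out)) < r
        col = out[name].copy()
        col[mask] = pd.NA if str(out[name].dtype) in ("boolean", "string") else np.nan
        out[name] = col
    return out


def inject_miscalibration(
    config: SimulationConfig, multipliers: Dict[str, float]
) -> SimulationConfig:
    """A copy of the config with true hazards multiplied per endpoint.

    The evaluated risk model (built via :func:`spec_from_true_model`) is left
    unchanged, so a multiplier above 1 makes the model underpredict —
    observed KM risks exceed mean predicted risks, increasingly so in the
    upper quantiles.
    """
    new = config.model_copy(deep=True)
    for ep, m in multipliers.items():
        if ep not in new.endpoints:
            raise ConfigError(f"unknown endpoint {ep!r}")
        if m <= 0:
            raise ConfigError(f"hazard multiplier for {ep!r} must be positive, got {m}")
        new.endpoints[ep].hazard_multiplier *= m
    return new


def spec_from_true_model(
    config: SimulationConfig,
    endpoint: str,
    horizons_months: Optional[List[int]] = None,
    model_id: Optional[str] = None,
    days_per_month: float = DAYS_PER_MONTH,
) -> RiskModelSpec:
    """The risk-model spec a perfectly specified model of ``endpoint`` has.

    Baseline survival is the Weibull baseline *without* the hazard
    multiplier: validating this spec on a cohort simulated with multiplier 1
    is self-consistent by construction, and with multiplier > 1 it exhibits
    controlled underprediction.
    """
    model = config.endpoints[endpoint]
    horizons = horizons_months or [1, 12, 24]
    s0 = {
        int(h): float(
            np.exp(-((months_to_days(h, days_per_month) / model.weibull_scale_days)
                     ** model.weibull_shape))
        )
        for h in horizons
    }
    terms = [t.model_copy(deep=True) for t in model.terms]
    centering = dict(model.centering)
    if model.treatment_loghr != 0.0:
        terms.append(
            Term(covariate="oac", beta=model.treatment_loghr, transform=Transform(type="indicator"))
        )
        centering["oac"] = 0.0
    return RiskModelSpec(
        model_id=model_id or f"true_{endpoint}",
        outcome=endpoint,
        description=f"generating model of the synthetic {endpoint} endpoint",
        terms=terms,
        centering=centering,
        baseline_survival=s0,
    )
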