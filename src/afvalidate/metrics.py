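"""Survival metrics: Kaplan-Meier, horizon-specific AUC, paired AUC tests,
and Cox proportional-hazards fits.

The horizon AUC treats censoring in one of two ways:

``exclude`` (default)
    Cases are patients with the event by the horizon; controls are patients
    event-free with follow-up reaching the horizon; patients censored before
    the horizon without the event are excluded.  The AUC is the concordance
    fraction over all case-control pairs with ties counted 1/2 (the
    Mann-Whitney statistic), with a DeLong asymptotic 95% CI.

``ipcw``
    Inverse-probability-of-censoring weighting (Uno-style): case-control
    pairs are weighted by the inverse Kaplan-Meier estimate of the censoring
    survival, removing the bias of dropping early-censored patients at the
    price of a variance approximation for the CI.

Kaplan-Meier estimation and its Greenwood confidence band are delegated to
lifelines; Cox partial-likelihood maximisation (Efron or Breslow ties) to
statsmodels' ``PHReg``.  The DeLong variance and the paired correlated-AUC
test are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import MetricError

__all__ = [
    "KMCurve",
    "AUCResult",
    "AUCComparison",
    "CoxFit",
    "kaplan_meier",
    "observed_risk",
    "horizon_auc",
    "compare_auc",
    "cox_fit",
]

Z_95 = 1.96  # fixed multiplier for all 95% CIs


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate on the observed event-time grid."""

    times: np.ndarray  # event/censor time grid (days), starts at 0
    survival: np.ndarray  # S(t), right-continuous step function
    at_risk: np.ndarray  # n_i at each grid time
    n_events: np.ndarray  # d_i at each grid time
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def _band_at(self, band: np.ndarray, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(band[max(idx, 0)])


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood 95% CI.

    At tied times events are handled before censorings (the censored patient
    is still at risk for the tied event).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise MetricError("kaplan_meier: empty input")
    if t.shape != e.shape:
        raise MetricError("kaplan_meier: times and events must have equal length")
    if (t < 0).any() or not np.isfinite(t).all():
        raise MetricError("kaplan_meier: times must be finite and >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table  # indexed by time, includes t=0 row
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        n_events=table["observed"].to_numpy(dtype=float),
        ci_lo=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_hi=ci.iloc[:, 1].to_numpy(dtype=float),
    )


def observed_risk(km: KMCurve, horizon_days: float) -> float:
    """Observed event risk by the horizon, ``1 - S(horizon)``."""
    if horizon_days < 0:
        raise MetricError("observed_risk: horizon must be >= 0")
    if horizon_days > km.times[-1]:
        warnings.warn(
            f"horizon {horizon_days} beyond last observed time {km.times[-1]}; "
            "returning 1 - S(last)",
            stacklevel=2,
        )
    return 1.0 - km.survival_at(horizon_days)


def observed_risk_ci(km: KMCurve, horizon_days: float) -> tuple:
    """(lo, hi) 95% CI of the observed risk, from the Greenwood band."""
    if km.ci_lo is None:
        raise MetricError("KM curve carries no confidence band")
    # survival band flips under 1 - S
    return (
        1.0 - km._band_at(km.ci_hi, horizon_days),
        1.0 - km._band_at(km.ci_lo, horizon_days),
    )


# ---------------------------------------------------------------------------
# horizon AUC


@dataclass
class AUCResult:
    """Horizon AUC with its 95% CI and Table-2-style group summaries.

    ``n1``/``p1`` are the count and mean predicted risk of patients with the
    outcome (cases); ``n0``/``p0`` of patients without it (controls).
    """

    auc: float
    ci_lo: float
    ci_hi: float
    se: float
    n0: int
    n1: int
    p0: float
    p1: float
    method: str
    horizon_days: float
    n_excluded: int = 0


def _classify(times, events, horizon_days):
    """Case/control/excluded masks at a horizon (status-based rule)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    case = (e == 1) & (t <= horizon_days)
    control = (t >= horizon_days) & ~case
    excluded = ~case & ~control  # censored before horizon, event-free
    return case, control, excluded


def _midrank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2, via midranks."""
    m, n = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)


def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components (V10 over cases, V01 over controls)."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    ranks_all = stats.rankdata(all_scores)
    ranks_cases = stats.rankdata(cases)
    ranks_controls = stats.rankdata(controls)
    # placement values: fraction of the other group below each score
    v10 = (ranks_all[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_controls) / m
    return v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _censoring_km(times, events):
    """KM estimate of the censoring survival G (events flipped)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), event_observed=1 - np.asarray(events, int))
    return kmf


def _g_left(kmf, t: np.ndarray) -> np.ndarray:
    """G(t-) — censoring survival just before t."""
    eps = 1e-9
    return kmf.survival_function_at_times(np.maximum(t - eps, 0.0)).to_numpy(dtype=float)


def horizon_auc(
    predictions,
    times,
    events,
    horizon_days: float,
    method: str = "exclude",
) -> AUCResult:
    """Discrimination of risk predictions for events by a horizon.

    See the module docstring for the ``exclude``/``ipcw`` censoring rules.
    Raises :class:`MetricError` when there are no cases or no controls, or
    when any prediction is missing (filter to evaluable patients first).
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(p) == len(t) == len(e)):
        raise MetricError("horizon_auc: input vectors must be aligned")
    if np.isnan(p).any():
        raise MetricError("horizon_auc: predictions contain NaN; filter to evaluable patients")
    if method not in ("exclude", "ipcw"):
        raise MetricError(f"horizon_auc: unknown method {method!r}")

    case, control, excluded = _classify(t, e, horizon_days)
    m, n = int(case.sum()), int(control.sum())
    if m == 0 or n == 0:
        raise MetricError(
            f"AUC undefined at horizon {horizon_days}: {m} cases, {n} controls"
        )
    p1, p0 = float(p[case].mean()), float(p[control].mean())

    if method == "exclude":
        auc = _midrank_auc(p[case], p[control])
        v10, v01 = _delong_components(p[case], p[control])
        se = float(np.sqrt(_delong_variance(v10, v01)))
        m_eff, n_eff = m, n
    else:
        kmf = _censoring_km(t, e)
        w_case = 1.0 / _g_left(kmf, t[case])
        g_tau = float(kmf.survival_function_at_times(horizon_days).iloc[0])
        if g_tau <= 0 or not np.isfinite(w_case).all():
            raise MetricError("ipcw AUC: censoring survival reaches 0 before the horizon")
        w_control = np.full(n, 1.0 / g_tau)
        auc = _weighted_auc(p[case], w_case, p[control], w_control)
        # Hanley-McNeil variance on effective (weighted) sample sizes;
        # a documented approximation, not an exact IPCW variance.
        m_eff = float(w_case.sum() ** 2 / (w_case**2).sum())
        n_eff = float(w_control.sum() ** 2 / (w_control**2).sum())
        se = float(np.sqrt(_hanley_mcneil_var(auc, m_eff, n_eff)))

    return AUCResult(
        auc=float(auc),
        ci_lo=float(max(0.0, auc - Z_95 * se)),
        ci_hi=float(min(1.0, auc + Z_95 * se)),
        se=se,
        n0=n,
        n1=m,
        p0=p0,
        p1=p1,
        method=method,
        horizon_days=float(horizon_days),
        n_excluded=int(excluded.sum()),
    )


def _weighted_auc(x, wx, y, wy) -> float:
    """Weighted Mann-Whitney: sum_ij wx_i wy_j psi(x_i, y_j) / (W_x W_y)."""
    order = np.argsort(x, kind="stable")
    xs, wxs = x[order], wx[order]
    cum = np.concatenate([[0.0], np.cumsum(wxs)])
    lo = np.searchsorted(xs, y, side="left")
    hi = np.searchsorted(xs, y, side="right")
    w_below = cum[lo]  # case weight strictly below each control
    w_tied = cum[hi] - cum[lo]
    total = wx.sum() * wy.sum()
    concordant = np.sum(wy * (cum[-1] - cum[hi])) + 0.5 * np.sum(wy * w_tied)
    return float(concordant / total)


def _hanley_mcneil_var(auc: float, m: float, n: float) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
    ) / (m * n)


# ---------------------------------------------------------------------------
# paired AUC comparison (DeLong)


@dataclass
class AUCComparison:
    """Paired comparison of two predictors' horizon AUCs on shared patients."""

    auc_a: AUCResult
    auc_b: AUCResult
    delta: float  # auc_a - auc_b
    se: float
    z: float
    p_value: float


def compare_auc(
    pred_a,
    pred_b,
    times,
    events,
    horizon_days: float,
) -> AUCComparison:
    """DeLong test for the difference of two correlated horizon AUCs.

    Both prediction vectors must cover the identical patients (paired
    comparison); the case/control classification uses the ``exclude`` rule.
    Antisymmetric: swapping the predictors negates ``delta`` and ``z``.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape:
        raise MetricError("compare_auc: predictors must cover identical patients")
    if isinstance(pred_a, pd.Series) and isinstance(pred_b, pd.Series):
        if not pred_a.index.equals(pred_b.index):
            raise MetricError("compare_auc: predictors must cover identical patients")
    res_a = horizon_auc(a, times, events, horizon_days, method="exclude")
    res_b = horizon_auc(b, times, events, horizon_days, method="exclude")

    case, control, _ = _classify(times, events, horizon_days)
    va10, va01 = _delong_components(a[case], a[control])
    vb10, vb01 = _delong_components(b[case], b[control])
    m, n = len(va10), len(va01)
    if m > 1:
        cov10 = np.cov(va10, vb10, ddof=1)[0, 1]
    else:
        cov10 = 0.0
    if n > 1:
        cov01 = np.cov(va01, vb01, ddof=1)[0, 1]
    else:
        cov01 = 0.0
    var_delta = (
        _delong_variance(va10, va01)
        + _delong_variance(vb10, vb01)
        - 2.0 * (cov10 / m + cov01 / n)
    )
    delta = res_a.auc - res_b.auc
    var_delta = max(var_delta, 0.0)
    if var_delta == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = delta / np.sqrt(var_delta)
        p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(
        auc_a=res_a, auc_b=res_b, delta=float(delta),
        se=float(np.sqrt(var_delta)), z=float(z), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """A fitted Cox model: per-covariate effects and fit diagnostics.

    ``summary`` has one row per covariate with columns
    ``beta, hr, se, ci_lo, ci_hi`` (CIs on the hazard-ratio scale,
    ``exp(beta +- 1.96 se)``).
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool
    ties: str
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(X: pd.DataFrame, times, events, ties: str = "efron") -> CoxFit:
    """Maximum partial-likelihood Cox fit via statsmodels ``PHReg``.

    ``X`` must be complete (no missing covariates — the caller filters);
    there must be at least one event.  Non-convergence is flagged on the
    result, never silent; complete separation raises :class:`MetricError`
    with a diagnostic.
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("efron", "breslow"):
        raise MetricError(f"cox_fit: unknown ties method {ties!r}")
    Xd = pd.DataFrame(X).astype(float)
    if Xd.isna().any().any():
        raise MetricError("cox_fit: covariate matrix contains missing values")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise MetricError("cox_fit: no events — partial likelihood undefined")

    model = PHReg(t, Xd.to_numpy(), status=e, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = model.fit(disp=False)
    beta = np.asarray(results.params, dtype=float)
    se = np.asarray(results.bse, dtype=float)

    diverged = ~np.isfinite(beta) | ~np.isfinite(se) | (np.abs(beta) > 15) | (se > 50)
    if diverged.any():
        bad = Xd.columns[diverged].tolist()
        raise MetricError(
            f"cox_fit: apparent complete separation on covariates {bad} "
            "(diverging coefficients)"
        )
    score = model.score(beta)
    converged = bool(np.isfinite(se).all() and np.max(np.abs(score)) < 1e-3 * max(1, e.sum()))

    summary = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_lo": np.exp(beta - Z_95 * se),
            "ci_hi": np.exp(beta + Z_95 * se),
        },
        index=Xd.columns,
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(model.loglike(beta)),
        converged=converged,
        ties=ties,
        n=len(Xd),
        n_events=int(e.sum()),
    )
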