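"""Calibration of predicted risks against Kaplan-Meier observed risks.

Two complementary views:

* **Calibration-in-the-large** — a logistic recalibration of the horizon
  outcome status on ``logit(prediction)``: the intercept of an
  offset-logistic fit (slope fixed at 1) measures systematic over/under-
  prediction on the log-odds scale (0 under perfect calibration; positive
  when risks are underpredicted), and the slope of an un-offset fit measures
  spread (1 under perfect calibration).  The summary also carries the mean
  predicted risk against the KM observed risk at the horizon — the
  whole-cohort comparison a validation table prints.

* **Quantile calibration** — patients are split into equal-frequency bins of
  predicted risk (quintiles by default) and each bin's mean predicted risk
  is set against its KM observed risk with a Greenwood CI; this is the
  plot-ready per-quantile table behind calibration plots.

Outcome status at the horizon uses the same rule as the exclusion-based AUC:
patients censored event-free before the horizon contribute to the KM curve
but not to the logistic status fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MetricError
from .metrics import _classify, kaplan_meier, observed_risk, observed_risk_ci

__all__ = [
    "CalibrationSummary",
    "QuantileCalibrationTable",
    "calibration_in_the_large",
    "quantile_calibration",
    "plot_calibration",
]

logger = logging.getLogger(__name__)

_CLIP = 1e-6


@dataclass
class CalibrationSummary:
    """Whole-cohort calibration at one horizon."""

    mean_predicted: float
    km_observed: float
    intercept: float  # offset-logistic recalibration intercept, logit units
    slope: float  # logistic slope on logit(prediction)
    n_evaluable: int  # patients with horizon status (cases + controls)
    n_clipped: int = 0


@dataclass
class QuantileCalibrationTable:
    """Per-quantile predicted vs KM-observed risks at one horizon.

    ``table`` columns: ``quantile`` (1-based), ``n``, ``mean_predicted``,
    ``km_observed``, ``ci_lo``, ``ci_hi``, ``observed_available``.
    """

    table: pd.DataFrame
    horizon_days: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _clip_predictions(p: np.ndarray) -> tuple:
    clipped = (p <= 0.0) | (p >= 1.0)
    n_clipped = int(clipped.sum())
    if n_clipped:
        logger.warning("clipped %d predictions to [%g, 1-%g]", n_clipped, _CLIP, _CLIP)
    return np.clip(p, _CLIP, 1.0 - _CLIP), n_clipped


def calibration_in_the_large(
    predictions, times, events, horizon_days: float
) -> CalibrationSummary:
    """Offset-logistic recalibration intercept, slope, and mean-vs-KM risks.

    Raises :class:`MetricError` when every status-determined patient shares
    one outcome (logistic fits undefined) or when no patient's status at the
    horizon is determined.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.isnan(p).any():
        raise MetricError("calibration: predictions contain NaN; filter first")
    p, n_clipped = _clip_predictions(p)

    km = kaplan_meier(t, e)
    km_obs = observed_risk(km, horizon_days)

    case, control, _ = _classify(t, e, horizon_days)
    status_known = case | control
    if not status_known.any():
        raise MetricError("calibration: no patient has determined status at the horizon")
    y = case[status_known].astype(float)
    if y.min() == y.max():
        raise MetricError("calibration: all patients share one outcome status")
    lp = _logit(p[status_known])

    offset_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp).fit()
    if np.ptp(lp) > 0:
        slope_fit = sm.GLM(
            y, sm.add_constant(lp, has_constant="add"), family=sm.families.Binomial()
        ).fit()
        slope = float(slope_fit.params[1])
    else:
        slope = np.nan  # constant predictions: spread is undefined
        logger.warning("constant predictions: calibration slope undefined")

    return CalibrationSummary(
        mean_predicted=float(np.mean(p)),
        km_observed=float(km_obs),
        intercept=float(offset_fit.params[0]),
        slope=slope,
        n_evaluable=int(status_known.sum()),
        n_clipped=n_clipped,
    )


def quantile_calibration(
    predictions,
    times,
    events,
    horizon_days: float,
    n_quantiles: int = 5,
    min_bin_size: int = 20,
    patient_ids=None,
) -> QuantileCalibrationTable:
    """Equal-frequency binning of predicted risk vs per-bin KM observed risk.

    Binning is deterministic under permutation of the input order: patients
    are stably ranked by ``(prediction, patient_id)`` and ranks are cut into
    ``n_quantiles`` bins whose sizes differ by at most one.  When
    ``patient_ids`` is omitted and ``predictions`` is a Series, its index is
    the tie-break key.
    """
    if n_quantiles < 1:
        raise MetricError("quantile_calibration: n_quantiles must be >= 1")
    if isinstance(predictions, pd.Series) and patient_ids is None:
        patient_ids = predictions.index.to_numpy()
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.isnan(p).any():
        raise MetricError("calibration: predictions contain NaN; filter first")
    n = len(p)
    if patient_ids is None:
        patient_ids = np.arange(n)
    ids = np.asarray(patient_ids)
    if n < n_quantiles * min_bin_size:
        raise MetricError(
            f"quantile_calibration: {n} patients cannot fill {n_quantiles} bins "
            f"of at least {min_bin_size}"
        )

    order = np.lexsort((ids, p))  # stable: prediction, then patient id
    bins = np.floor(np.arange(n) * n_quantiles / n).astype(int)

    rows = []
    for b in range(n_quantiles):
        sel = order[bins == b]
        pb, tb, eb = p[sel], t[sel], e[sel]
        km = kaplan_meier(tb, eb)
        at_risk_at_h = float(np.sum(tb >= horizon_days))
        events_by_h = float(np.sum((eb == 1) & (tb <= horizon_days)))
        available = not (events_by_h == 0 and at_risk_at_h == 0)
        if available:
            obs = observed_risk(km, horizon_days)
            lo, hi = observed_risk_ci(km, horizon_days)
        else:
            obs, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "quantile": b + 1,
                "n": len(sel),
                "mean_predicted": float(pb.mean()),
                "km_observed": obs,
                "ci_lo": lo,
                "ci_hi": hi,
                "observed_available": available,
            }
        )
    return QuantileCalibrationTable(table=pd.DataFrame(rows), horizon_days=float(horizon_days))


def plot_calibration(table: QuantileCalibrationTable, ax=None, title: Optional[str] = None):
    """Paired-bar predicted-vs-observed plot per quantile (needs matplotlib)."""
    import matplotlib.pyplot as plt  # optional dependency

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = table.table
    x = t["quantile"].to_numpy(dtype=float)
    width = 0.38
    ax.bar(x - width / 2, 100 * t["mean_predicted"], width, label="predicted")
    ax.bar(x + width / 2, 100 * t["km_observed"], width, label="KM observed")
    err_lo = 100 * (t["km_observed"] - t["ci_lo"])
    err_hi = 100 * (t["ci_hi"] - t["km_observed"])
    ax.errorbar(
        x + width / 2, 100 * t["km_observed"], yerr=[err_lo, err_hi],
        fmt="none", ecolor="black", capsize=3,
    )
    ax.set_xlabel("quantile of predicted risk")
    ax.set_ylabel("risk by horizon, %")
    ax.set_xticks(x)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
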