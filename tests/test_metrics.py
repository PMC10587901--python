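"""Survival metrics against hand computations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import afvalidate as av
from afvalidate.metrics import _classify


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        km = av.kaplan_meier([3, 5, 8, 2, 9], [0, 0, 0, 0, 0])
        assert km.survival_at(9) == 1.0
        assert av.observed_risk(km, 9) == 0.0

    def test_hand_product_limit(self):
        """times (2,3,3,5,8), events (1,1,0,1,0):
        S(5) = (4/5)(3/4)(1/2) = 0.30, observed risk 0.70."""
        km = av.kaplan_meier([2, 3, 3, 5, 8], [1, 1, 0, 1, 0])
        assert km.survival_at(5) == pytest.approx(0.30)
        assert av.observed_risk(km, 5) == pytest.approx(0.70)

    def test_all_events_at_t1(self):
        km = av.kaplan_meier([1, 1, 1], [1, 1, 1])
        assert km.survival_at(1) == 0.0

    def test_censoring_after_tied_event_keeps_patient_at_risk(self):
        # the patient censored at t=3 is in the risk set of the t=3 event
        km = av.kaplan_meier([3, 3], [1, 0])
        assert km.survival_at(3) == pytest.approx(0.5)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, 300)
        km = av.kaplan_meier(t, np.ones(300, dtype=int))
        for q in (50.0, 100.0, 250.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_error_paths(self):
        with pytest.raises(av.MetricError):
            av.kaplan_meier([], [])
        with pytest.raises(av.MetricError):
            av.kaplan_meier([-1.0, 2.0], [1, 0])
        km = av.kaplan_meier([2, 3], [1, 0])
        with pytest.raises(av.MetricError):
            av.observed_risk(km, -1.0)

    def test_horizon_beyond_last_time_warns(self):
        km = av.kaplan_meier([2, 3], [1, 0])
        with pytest.warns(UserWarning, match="beyond"):
            assert av.observed_risk(km, 10) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# horizon AUC


def brute_force_auc(pred, case_mask):
    """All-pairs concordance with ties counted 1/2 (double loop)."""
    cases = pred[case_mask]
    controls = pred[~case_mask]
    total = 0.0
    for ci in cases:
        for cj in controls:
            total += 1.0 if ci > cj else (0.5 if ci == cj else 0.0)
    return total / (len(cases) * len(controls))


class TestHorizonAUC:
    def test_perfect_separation(self):
        res = av.horizon_auc([0.9, 0.8, 0.1, 0.2], [1, 2, 10, 10], [1, 1, 0, 0], 5.0)
        assert res.auc == 1.0
        assert (res.n1, res.n0) == (2, 2)

    def test_all_tied_predictions_give_half(self):
        res = av.horizon_auc([0.3] * 6, [1, 2, 3, 9, 9, 9], [1, 1, 1, 0, 0, 0], 5.0)
        assert res.auc == 0.5

    def test_matches_brute_force_on_uncensored_records(self):
        """n=50 uncensored: equals the double-loop pair count exactly and the
        classical Mann-Whitney AUC from sklearn."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        pred = np.round(rng.random(50), 2)  # rounding forces some ties
        t_event = rng.exponential(50, 50)
        events = np.ones(50, dtype=int)
        horizon = float(np.median(t_event))
        case = t_event <= horizon
        res = av.horizon_auc(pred, t_event, events, horizon)
        assert res.auc == pytest.approx(brute_force_auc(pred, case), abs=1e-12)
        assert res.auc == pytest.approx(roc_auc_score(case, pred), abs=1e-12)
        assert res.n1 == case.sum() and res.n0 == (~case).sum()
        assert res.p1 == pytest.approx(pred[case].mean())
        assert res.p0 == pytest.approx(pred[~case].mean())

    def test_exclusion_rule(self):
        """Censored-before-horizon patients are excluded; event-free patients
        reaching the horizon are controls even if they have a later event."""
        pred = np.array([0.9, 0.5, 0.4, 0.2])
        times = np.array([3.0, 2.0, 8.0, 10.0])
        events = np.array([1, 0, 1, 0])  # second censored early, third event late
        res = av.horizon_auc(pred, times, events, 5.0)
        assert res.n_excluded == 1
        assert (res.n1, res.n0) == (1, 2)
        assert res.auc == 1.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        pred = rng.random(80)
        times = rng.exponential(30, 80)
        events = (rng.random(80) < 0.8).astype(int)
        h = float(np.quantile(times, 0.5))
        res = av.horizon_auc(pred, times, events, h)
        flipped = av.horizon_auc(-pred, times, events, h)
        assert res.auc == pytest.approx(1.0 - flipped.auc, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        pred = rng.random(100)
        times = rng.exponential(30, 100)
        events = (rng.random(100) < 0.7).astype(int)
        h = 20.0
        a = av.horizon_auc(pred, times, events, h)
        b = av.horizon_auc(np.exp(3 * pred) + 5, times, events, h)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_zero_cases_is_explicit_error(self):
        with pytest.raises(av.MetricError, match="0 cases"):
            av.horizon_auc([0.1, 0.2], [9, 9], [0, 0], 5.0)

    def test_ci_contains_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(5)

        def one(n):
            risk = rng.random(n)
            t = rng.exponential(10 / (risk + 0.1), n)
            return av.horizon_auc(risk, t, np.ones(n, dtype=int), 5.0)

        small, big = one(100), one(5000)
        for r in (small, big):
            assert r.ci_lo <= r.auc <= r.ci_hi
        assert (big.ci_hi - big.ci_lo) < (small.ci_hi - small.ci_lo)

    def test_ipcw_matches_sksurv_oracle(self):
        """IPCW AUC equals scikit-survival's cumulative_dynamic_auc on
        censored continuous data (independent implementation)."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(9)
        n = 400
        risk = rng.random(n)
        t = rng.exponential(40 / (0.2 + risk), n)
        c = rng.exponential(60, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        horizon = 25.0
        y = Surv.from_arrays(events.astype(bool), times)
        expected, _ = cumulative_dynamic_auc(y, y, risk, [horizon])
        res = av.horizon_auc(risk, times, events, horizon, method="ipcw")
        assert res.auc == pytest.approx(float(expected[0]), abs=1e-10)
        assert res.method == "ipcw"

    def test_ipcw_equals_exclude_without_censoring(self):
        rng = np.random.default_rng(10)
        pred = rng.random(200)
        t = rng.exponential(30, 200)
        ev = np.ones(200, dtype=int)
        a = av.horizon_auc(pred, t, ev, 20.0, method="exclude")
        b = av.horizon_auc(pred, t, ev, 20.0, method="ipcw")
        assert a.auc == pytest.approx(b.auc, abs=1e-12)


# ---------------------------------------------------------------------------
# paired comparison


def paired_permutation_p(pred_a, pred_b, times, events, horizon, n_perm=10_000, seed=0):
    """Sign-flip permutation test on the paired AUC difference."""
    rng = np.random.default_rng(seed)
    case, control, _ = _classify(times, events, horizon)
    keep = case | control

    def auc_delta(a, b):
        ra = av.horizon_auc(a[keep], times[keep], events[keep], horizon)
        rb = av.horizon_auc(b[keep], times[keep], events[keep], horizon)
        return ra.auc - rb.auc

    observed = auc_delta(pred_a, pred_b)
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(len(pred_a)) < 0.5
        a = np.where(swap, pred_b, pred_a)
        b = np.where(swap, pred_a, pred_b)
        if abs(auc_delta(a, b)) >= abs(observed) - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


class TestCompareAUC:
    def test_identical_predictors(self):
        rng = np.random.default_rng(1)
        pred = rng.random(60)
        t = rng.exponential(20, 60)
        e = np.ones(60, dtype=int)
        res = av.compare_auc(pred, pred, t, e, 15.0)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(80), rng.random(80)
        t = rng.exponential(20, 80)
        e = (rng.random(80) < 0.8).astype(int)
        r1 = av.compare_auc(a, b, t, e, 15.0)
        r2 = av.compare_auc(b, a, t, e, 15.0)
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_mismatched_patients_rejected(self):
        with pytest.raises(av.MetricError, match="identical patients"):
            av.compare_auc([0.1, 0.2], [0.1, 0.2, 0.3], [1, 2, 3], [1, 1, 1], 2.0)
        a = pd.Series([0.1, 0.2], index=["x", "y"])
        b = pd.Series([0.1, 0.2], index=["x", "z"])
        with pytest.raises(av.MetricError, match="identical patients"):
            av.compare_auc(a, b, [1, 2], [1, 1], 2.0)

    def test_informative_vs_random_predictor(self):
        """Perfect vs random predictor at n=200: the DeLong p-value is
        significant and agrees in verdict with a 10^4-draw sign-flip
        permutation test."""
        rng = np.random.default_rng(12)
        n = 200
        risk = rng.random(n)
        t = rng.exponential(10 / (0.05 + risk), n)
        e = np.ones(n, dtype=int)
        horizon = float(np.median(t))
        informative = risk
        noise = rng.random(n)
        res = av.compare_auc(informative, noise, t, e, horizon)
        assert res.delta > 0
        assert res.p_value < 0.05
        p_perm = paired_permutation_p(informative, noise, t, e, horizon, n_perm=2000, seed=1)
        assert p_perm < 0.05


# ---------------------------------------------------------------------------
# Cox fits


def breslow_negloglik(beta, X, times, events):
    """Hand-coded Breslow partial likelihood (no ties in the fixtures)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    order = np.argsort(times)
    eta_o = eta[order]
    ev_o = events[order]
    # risk set of the i-th ordered time = patients ordered at or after i
    rev_cumsum = np.cumsum(np.exp(eta_o)[::-1])[::-1]
    ll = np.sum(ev_o * (eta_o - np.log(rev_cumsum)))
    return -ll


class TestCoxFit:
    def test_recovers_true_hazard_ratio(self):
        """Two-group exponential data, true HR 2.0, n=5000: the estimate
        lands within the asymptotic 95% CI band around truth."""
        rng = np.random.default_rng(21)
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * x), n)
        c = rng.exponential(2.0, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        fit = av.cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.converged
        assert 1.85 <= fit.hazard_ratio("x") <= 2.15
        assert fit.summary.loc["x", "ci_lo"] <= 2.0 <= fit.summary.loc["x", "ci_hi"]

    def test_null_covariate_coverage(self):
        """Independent covariate: the 95% CI covers HR=1 in >= 90% of 100
        seeded replicates."""
        cover = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            fit = av.cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
            if fit.summary.loc["x", "ci_lo"] <= 1.0 <= fit.summary.loc["x", "ci_hi"]:
                cover += 1
        assert cover >= 90

    def test_matches_generic_optimizer_on_breslow_likelihood(self):
        """PHReg estimates agree with scipy.optimize on a hand-coded Breslow
        partial likelihood to 1e-4 (dual-route check)."""
        rng = np.random.default_rng(31)
        n = 200
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / np.exp(X @ [0.5, -0.3]), n)
        e = np.ones(n, dtype=int)
        fit = av.cox_fit(pd.DataFrame(X, columns=["a", "b"]), t, e, ties="breslow")
        res = optimize.minimize(
            breslow_negloglik, np.zeros(2), args=(X, t, e), method="BFGS"
        )
        np.testing.assert_allclose(fit.summary["beta"].to_numpy(), res.x, atol=1e-4)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    def test_loglik_improves_over_null(self):
        rng = np.random.default_rng(32)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.8 * x), n)
        e = np.ones(n, dtype=int)
        fit = av.cox_fit(pd.DataFrame({"x": x}), t, e, ties="breslow")
        assert fit.log_likelihood > -breslow_negloglik(np.zeros(1), x[:, None], t, e)

    def test_zero_events_error(self):
        with pytest.raises(av.MetricError, match="no events"):
            av.cox_fit(pd.DataFrame({"x": [0.0, 1.0]}), [1.0, 2.0], [0, 0])

    def test_missing_covariates_rejected(self):
        with pytest.raises(av.MetricError, match="missing"):
            av.cox_fit(pd.DataFrame({"x": [0.0, np.nan]}), [1.0, 2.0], [1, 1])

    def test_complete_separation_diagnosed(self):
        # events only while x=1 patients are at risk, perfectly ordered
        x = np.array([1.0] * 10 + [0.0] * 10)
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)])
        e = np.array([1] * 10 + [0] * 10)
        with pytest.raises(av.MetricError, match="separation"):
            av.cox_fit(pd.DataFrame({"x": x}), t, e)
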