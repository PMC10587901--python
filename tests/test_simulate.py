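"""Synthetic-cohort generator: marginals, determinism, closed-form checks."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import afvalidate as av
from afvalidate.model_spec import Term, Transform, months_to_days
from afvalidate.simulate import DEFAULT_PREVALENCES


class TestCovariates:
    def test_marginal_prevalences_hit_targets(self):
        """n=10^5: empirical female fraction within +-0.01 of 0.467 and the
        age-tilted flags within 3 sigma of their configured marginals."""
        cfg = av.default_config(n=100_000, seed=1)
        patients = av.generate_covariates(cfg)
        assert abs((patients["sex"] == "female").mean() - 0.467) < 0.01
        for flag in ("hypertension", "diabetes", "chf", "ckd_grade3plus", "oac"):
            p = DEFAULT_PREVALENCES[flag]
            se = np.sqrt(p * (1 - p) / len(patients))
            assert abs(patients[flag].mean() - p) < 3 * se + 1e-4, flag
        assert abs(patients["age"].mean() - cfg.age_mean) < 0.2
        assert (patients["age"] >= 18).all()
        assert (patients["sbp"] > patients["dbp"]).all()

    def test_oac_consistency_invariant(self):
        patients = av.generate_covariates(av.default_config(n=5000, seed=2))
        assert (patients["oac"] == (patients["noac"] | patients["vka"])).all()
        assert not (patients["noac"] & patients["vka"]).any()

    def test_zero_prevalences_give_all_false(self):
        cfg = av.default_config(
            n=500, seed=3, prevalences={k: 0.0 for k in DEFAULT_PREVALENCES}
        )
        patients = av.generate_covariates(cfg)
        assert not patients[list(DEFAULT_PREVALENCES)].any().any()

    def test_same_seed_reproduces_identical_cohort(self):
        cfg = av.default_config(n=2000, seed=9)
        a = av.generate_covariates(cfg)
        b = av.generate_covariates(av.default_config(n=2000, seed=9))
        pd.testing.assert_frame_equal(a, b)
        c1, t1 = av.simulate_cohort(cfg)
        c2, t2 = av.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.outcomes, c2.outcomes)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            av.default_config(n=10, seed=0, prevalences={"chf": 1.4})
        with pytest.raises(ValidationError, match="unknown flag"):
            av.default_config(n=10, seed=0, prevalences={"bmi": 0.2})


class TestOutcomes:
    def test_exponential_closed_form_at_zero_coefficients(self):
        """Shape 1, no covariate effects: 1-year event risk matches
        1 - exp(-365.25/scale) within 2 MC standard errors."""
        cfg = av.default_config(n=50_000, seed=4)
        model = cfg.endpoints["death"]
        model.terms = []
        model.centering = {}
        model.treatment_loghr = 0.0
        cfg.dropout_rate_per_day = 0.0
        patients = av.generate_covariates(cfg)
        outcomes = av.simulate_outcomes(patients, cfg)
        death = outcomes[outcomes["endpoint"] == "death"]
        h = months_to_days(12)
        risk_emp = ((death["event"] == 1) & (death["time_days"] <= h)).mean()
        risk_true = 1 - np.exp(-h / model.weibull_scale_days)
        se = np.sqrt(risk_true * (1 - risk_true) / len(death))
        assert abs(risk_emp - risk_true) < 2 * se

    def test_zero_hazard_multiplier_no_events(self):
        cfg = av.default_config(n=300, seed=5)
        for ep in cfg.endpoints.values():
            ep.hazard_multiplier = 0.0
        patients = av.generate_covariates(cfg)
        outcomes = av.simulate_outcomes(patients, cfg)
        assert (outcomes["event"] == 0).all()
        assert (outcomes["time_days"] <= cfg.admin_censor_days).all()

    def test_death_truncates_other_endpoints(self):
        cfg = av.default_config(n=2000, seed=6)
        cohort, _ = av.simulate_cohort(cfg)
        death = cohort.endpoint_outcomes("death")
        for ep in ("stroke_se", "major_bleed"):
            other = cohort.endpoint_outcomes(ep)
            assert (other["time_days"] <= death["time_days"] + 1e-9).all()

    def test_cox_recovers_known_binary_hazard_ratio(self):
        """A binary covariate with true HR 2 is recovered within its CI."""
        cfg = av.default_config(n=20_000, seed=7)
        model = cfg.endpoints["death"]
        model.terms = [
            Term(
                covariate="diabetes", beta=float(np.log(2.0)),
                transform=Transform(type="indicator"),
            )
        ]
        model.centering = {"diabetes": 0.0}
        model.treatment_loghr = 0.0
        patients = av.generate_covariates(cfg)
        outcomes = av.simulate_outcomes(patients, cfg)
        death = outcomes[outcomes["endpoint"] == "death"].set_index("patient_id")
        x = patients["diabetes"].map({True: 1.0, False: 0.0}).astype(float)
        fit = av.cox_fit(
            pd.DataFrame({"diabetes": x}),
            death.loc[x.index, "time_days"], death.loc[x.index, "event"],
        )
        assert fit.summary.loc["diabetes", "ci_lo"] <= 2.0 <= fit.summary.loc["diabetes", "ci_hi"]

    def test_true_risk_matches_empirical_rate(self):
        cfg = av.default_config(n=50_000, seed=8)
        cfg.dropout_rate_per_day = 0.0
        patients = av.generate_covariates(cfg)
        outcomes = av.simulate_outcomes(patients, cfg)
        death = outcomes[outcomes["endpoint"] == "death"].set_index("patient_id")
        h = months_to_days(12)
        expected = av.true_risk(patients, cfg, "death", h).mean()
        observed = ((death["event"] == 1) & (death["time_days"] <= h)).mean()
        assert observed == pytest.approx(expected, abs=3 * np.sqrt(0.25 / 50_000) + 2e-3)


class TestInjectors:
    def test_zero_rate_leaves_cohort_unchanged(self):
        patients = av.generate_covariates(av.default_config(n=500, seed=10))
        out = av.inject_missingness(patients, {"pulse": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, patients)

    def test_rate_one_deletes_everything(self):
        patients = av.generate_covariates(av.default_config(n=500, seed=10))
        out = av.inject_missingness(patients, {"pulse": 1.0}, seed=1)
        assert out["pulse"].isna().all()
        assert out["sbp"].notna().all()

    def test_mcar_rate_hits_target(self):
        """Rate 0.333 on the HAS-BLED alcohol input at n=10^5: the score's
        non-complete fraction lands within +-0.01 of 0.333."""
        patients = av.generate_covariates(av.default_config(n=100_000, seed=12))
        out = av.inject_missingness(patients, {"alcohol_units_per_week": 0.333}, seed=13)
        from afvalidate.scores import has_bled_scores

        incomplete = ~has_bled_scores(out)["complete"]
        assert abs(incomplete.mean() - 0.333) < 0.01

    def test_invalid_rates_rejected(self):
        patients = av.generate_covariates(av.default_config(n=50, seed=10))
        with pytest.raises(av.ConfigError, match="outside"):
            av.inject_missingness(patients, {"pulse": 1.5}, seed=1)
        with pytest.raises(av.ConfigError, match="unknown"):
            av.inject_missingness(patients, {"nope": 0.5}, seed=1)

    def test_miscalibration_scales_hazards_only(self):
        cfg = av.default_config(n=10, seed=0)
        cfg2 = av.inject_miscalibration(cfg, {"death": 2.0})
        assert cfg2.endpoints["death"].hazard_multiplier == 2.0
        assert cfg.endpoints["death"].hazard_multiplier == 1.0  # original untouched
        assert cfg2.endpoints["stroke_se"].hazard_multiplier == 1.0
        with pytest.raises(av.ConfigError, match="positive"):
            av.inject_miscalibration(cfg, {"death": 0.0})
        with pytest.raises(av.ConfigError, match="unknown"):
            av.inject_miscalibration(cfg, {"sepsis": 2.0})

    def test_multiplier_one_is_byte_identical(self):
        cfg = av.default_config(n=1000, seed=14)
        cfg2 = av.inject_miscalibration(cfg, {"death": 1.0})
        a, _ = av.simulate_cohort(cfg)
        b, _ = av.simulate_cohort(cfg2)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)


def test_spec_from_true_model_is_self_consistent(sim_config, sim_cohort):
    """Mean predicted risk of the generating-model spec tracks the mean true
    risk exactly (same formula, same coefficients)."""
    cohort, truth = sim_cohort
    spec = av.spec_from_true_model(sim_config, "death")
    ps = av.predict_risks(cohort.patients, spec, 12)
    np.testing.assert_allclose(
        ps.risk.to_numpy(), truth["risk12_death"].to_numpy(), atol=1e-10
    )
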