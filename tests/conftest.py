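"""Shared fixtures: tiny hand-built cohorts and session-scoped simulations."""

import numpy as np
import pandas as pd
import pytest

import afvalidate as av
from afvalidate.cohort import _coerce_patient_dtypes


def build_patients(rows):
    """Patients frame from a list of dicts (patient_id + any covariates)."""
    df = pd.DataFrame(rows)
    if "patient_id" not in df.columns:
        df["patient_id"] = [f"P{i}" for i in range(len(df))]
    return _coerce_patient_dtypes(df.set_index("patient_id"))


@pytest.fixture
def patients_factory():
    return build_patients


@pytest.fixture(scope="session")
def sim_config():
    """Study-condition simulation config, no missingness, n=20000."""
    return av.default_config(n=20000, seed=11)


@pytest.fixture(scope="session")
def sim_cohort(sim_config):
    """Self-consistent cohort: outcomes generated by the very models later
    validated (hazard multiplier 1)."""
    cohort, truth = av.simulate_cohort(sim_config)
    return cohort, truth


@pytest.fixture(scope="session")
def sim_specs(sim_config):
    """The generating models as risk-model specs (one per endpoint)."""
    return {
        ep: av.spec_from_true_model(sim_config, ep)
        for ep in ("death", "stroke_se", "major_bleed")
    }


@pytest.fixture(scope="session")
def miscal_cohort(sim_config):
    """Cohort with true hazards doubled relative to the evaluated models."""
    cfg = av.inject_miscalibration(
        sim_config, {"death": 2.0, "stroke_se": 2.0, "major_bleed": 2.0}
    )
    cohort, _ = av.simulate_cohort(cfg)
    return cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete cohort for pipeline plumbing tests (n=1500)."""
    cfg = av.default_config(n=1500, seed=5)
    cohort, truth = av.simulate_cohort(cfg)
    return cfg, cohort, truth
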