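import numpy as np
import pytest

import glucast
from glucast.synthetic import CohortConfig, generate_subject_dataset


@pytest.fixture(scope="session")
def default_params():
    return glucast.PatientParameters()


@pytest.fixture(scope="session")
def clean_subject():
    """A 2-day noiseless, mismatch-free virtual subject (self-consistent world:
    the forecaster's model class equals the generating model)."""
    cfg = CohortConfig(
        seed=7, cgm_sigma=0.0, cgm_ar1=0.0, gap_rate_per_day=0.0,
        meal_kabs_frac=0.0, meal_ag_frac=0.0, bolus_tmaxi_frac=0.0,
        carb_err_low=0.0, carb_err_high=0.0,
    )
    params = glucast.PatientParameters()
    rng = np.random.default_rng(8)
    return generate_subject_dataset(params, cfg, 2, rng)


@pytest.fixture(scope="session")
def noisy_subject():
    """A 2-day subject under the default study conditions (noise, gaps,
    per-meal kinetic perturbations, carb-counting error)."""
    cfg = CohortConfig(seed=19)
    params = glucast.sample_cohort(cfg)[0]
    rng = np.random.default_rng(20)
    return generate_subject_dataset(params, cfg, 2, rng)
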