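import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def references():
    from epiage.synthetic import placeholder_references

    return placeholder_references()


@pytest.fixture(scope="session")
def cell_reference():
    from epiage.synthetic import synthetic_cell_reference

    return synthetic_cell_reference()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Small cohort with noise-free clock-CpG betas and its true ages."""
    from epiage import synthetic

    samples = synthetic.generate_cohort(40, (18.0, 74.0), seed=11)
    models = [
        synthetic.CpGAgeModel(m.cpg_id, m.baseline_a, m.slope_b, 0.0)
        for m in synthetic.DEFAULT_CPG_MODELS
    ]
    betas = synthetic.simulate_betas(samples, models, seed=12)
    ages = np.array([s.age for s in samples])
    return samples, models, betas, ages
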