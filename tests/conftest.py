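import numpy as np
import pytest
from hypothesis import settings

from costevidence import synthetic_data as sd

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def implicit_truth():
    return sd.default_true_coefficients("implicit")


@pytest.fixture(scope="session")
def implicit_cohort(implicit_truth):
    """Small noisy implicit-task cohort shared across fitting tests."""
    design = sd.implicit_design()
    noise = sd.NoiseSpec(seed=42)
    return sd.generate_effort_allocation(design, implicit_truth, noise, 4)


@pytest.fixture(scope="session")
def noiseless_subject(implicit_truth):
    design = sd.implicit_design()
    noise = sd.NoiseSpec(duration_sd=0.0, between_subject_sd=0.0, seed=0)
    return sd.generate_effort_allocation(design, implicit_truth, noise, 1)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
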