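import numpy as np
import pytest

from tmgkit.metrics import add_derived_columns
from tmgkit.signals import extract_cohort
from tmgkit.synthetic import SimulationConfig, simulate_cohort

# Short schedule for tests that only need baselines and a couple of
# post-exercise points; keeps simulation cheap.
SHORT_SCHEDULE = ("Pre1", "Pre2", "Set1", "Post1", "Post15")


@pytest.fixture(scope="session")
def default_params():
    """Extracted + derived parameter table of a default 16-subject cohort."""
    cohort = simulate_cohort(SimulationConfig(seed=7))
    return add_derived_columns(extract_cohort(cohort))


@pytest.fixture(scope="session")
def noiseless_params():
    """Cohort with no trial-to-trial or trace noise: retest is exact."""
    cfg = SimulationConfig(
        n_subjects=8, schedule=SHORT_SCHEDULE, within_subject_sd=0.0,
        trace_noise_torque=0.0, trace_noise_displacement=0.0, seed=11)
    return add_derived_columns(extract_cohort(simulate_cohort(cfg)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
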