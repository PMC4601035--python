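import numpy as np
import pytest

from p3net.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast cohort with defaults scaled down for unit tests."""
    spec = CohortSpec(n_subjects=4, rest_duration=40.0, n_trials=20,
                      coupling_rho=0.8, artifact_rate=0.1, seed=11,
                      dtype="float32")
    subjects, truths = simulate_cohort(spec)
    return spec, subjects, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
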