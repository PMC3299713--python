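import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from endosim import ModelParams, SimulationSettings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=15,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def tiny_settings():
    """Small but non-trivial simulation size for fast tests."""
    return SimulationSettings(n_initial=150, n_runs=4, horizon=120.0, seed=7)
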