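import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oculostim import SimConfig, simulate_session

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_null_config():
    """A compact null session: 12 electrodes, two currents, no effects."""
    return SimConfig.no_effect(n_electrodes=12, grid_shape=(2, 6), seed=7)


@pytest.fixture(scope="session")
def small_null_session(small_null_config):
    return simulate_session(small_null_config)
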