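import numpy as np
import pytest
from hypothesis import settings

from fingernet import NetworkConfig, make_toy_state

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_config() -> NetworkConfig:
    """Miniature network + short schedule for fast end-to-end tests."""
    return NetworkConfig(seed=0).scaled(
        40, n_days=8, dosage=(50, 100, 100, 100, 100, 100, 50, 0))


@pytest.fixture()
def toy_state():
    return make_toy_state(20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
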