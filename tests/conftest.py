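import numpy as np
import pytest

from heatscreen import HerdSimConfig, simulate_herd


@pytest.fixture(scope="session")
def default_config() -> HerdSimConfig:
    return HerdSimConfig()


@pytest.fixture(scope="session")
def herd(default_config):
    """One fully simulated study, shared read-only across tests."""
    return simulate_herd(default_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
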