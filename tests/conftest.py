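import numpy as np
import pytest

from insolegait.layout import default_layout
from insolegait.simulator import GaitSimConfig, simulate_trial
from insolegait.transduction import DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def cal():
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def layout16():
    return default_layout()


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless, lag-free 20-stride trial."""
    cfg = GaitSimConfig(n_strides=20, voltage_noise_sd=0.0, sensor_lag_tau=0.0, seed=11)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """30-stride trial with default noise and lag."""
    cfg = GaitSimConfig(n_strides=30, seed=7)
    return simulate_trial(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
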