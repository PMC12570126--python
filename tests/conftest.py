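import numpy as np
import pytest

from giantfiber.circuit import CircuitParams, single_pulse_spec, train_spec


@pytest.fixture(scope="session")
def default_params() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def quiet_pulse():
    """Noise-free single-pulse protocol at the calibrated amplitude."""
    return single_pulse_spec(noise_sd=0.0)


@pytest.fixture(scope="session")
def quiet_train():
    """Noise-free 100 Hz 10-stimulus train protocol."""
    return train_spec(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
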