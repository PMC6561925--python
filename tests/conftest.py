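import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from tacswave import fixtures as fx
from tacswave.recordings import NoiseModel, Protocol, generate_session

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def symmetric_setup():
    """Mirror-symmetric three-electrode montage over a single straight track."""
    return fx.preset("symmetric_line")


@pytest.fixture(scope="session")
def short_protocol():
    """Reduced sweep and epoch lengths to keep simulated sessions small."""
    return Protocol(sweep_deg=(0.0, 45.0, 90.0, 180.0), epoch_s=4.0, ramp_s=0.5)


@pytest.fixture(scope="session")
def noiseless_session(symmetric_setup, short_protocol):
    montage, geometry, medium = symmetric_setup
    return generate_session(montage, geometry, medium, short_protocol, NoiseModel.silent())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
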