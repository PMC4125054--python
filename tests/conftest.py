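import numpy as np
import pytest

from tcellsim import geometry
from tcellsim.circulation import BodyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_ln():
    return geometry.default_ln_sphere()


@pytest.fixture(scope="session")
def default_spleen():
    return geometry.default_spleen_section()


@pytest.fixture(scope="session")
def body():
    return BodyConfig()


@pytest.fixture(scope="session")
def spleen_transits_fresh():
    """10^4 explicit spleen transits with a seed independent of calibration."""
    geom = geometry.default_spleen_section()
    return geometry.simulate_spleen_transits(geom, 10000, np.random.default_rng(5), dt=0.1)


@pytest.fixture(scope="session")
def ln_brownian_transits():
    """Explicit discretized-Brownian LN first-passage times (oracle)."""
    geom = geometry.default_ln_sphere()
    return geometry.sample_ln_transit_brownian(geom, np.random.default_rng(9), n=10000, dt=0.1)
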