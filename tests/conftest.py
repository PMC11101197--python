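import numpy as np
import pytest

from demist.channels import build_rotational_channels
from demist.phantom import LVPhantomSpec, SystemModel, generate_lv_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Zero-jitter LV phantom with mask and centroid (48^3)."""
    return generate_lv_phantom(LVPhantomSpec(seed=0))


@pytest.fixture(scope="session")
def system():
    return SystemModel()


@pytest.fixture(scope="session")
def channels32():
    return build_rotational_channels(4, 32, 0.442)


@pytest.fixture(scope="session")
def channels48():
    return build_rotational_channels(4, 48, 0.442)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
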