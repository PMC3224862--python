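import numpy as np
import pytest

from megfc.forward import ConductorModel
from megfc.synthetic import make_grid, make_sensor_array


@pytest.fixture(scope="session")
def conductor():
    return ConductorModel(np.zeros(3))


@pytest.fixture(scope="session")
def array32():
    return make_sensor_array(32, helmet_radius=0.12)


@pytest.fixture(scope="session")
def array64():
    return make_sensor_array(64, helmet_radius=0.12)


@pytest.fixture(scope="session")
def grid20(conductor):
    """Coarse 20 mm grid, ~250 voxels."""
    return make_grid(20.0, conductor)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
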