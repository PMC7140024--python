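import numpy as np
import pytest

from crcscaffold import DeviceGeometry, FluidProperties


@pytest.fixture(scope="session")
def geom():
    """The bench device: 3 mm x 2 mm specimen, 6 mm pipette, 210 mm start."""
    return DeviceGeometry()


@pytest.fixture(scope="session")
def fluid():
    """Water at lab temperature, gamma = 9.81 kN/m^3."""
    return FluidProperties()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
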