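import numpy as np
import pytest

from gmrcyto import (
    AcquisitionConfig,
    BeadMagnetics,
    ChannelGeometry,
    SensorGeometry,
    field_to_voltage,
)


@pytest.fixture(scope="session")
def sensor():
    return SensorGeometry()


@pytest.fixture(scope="session")
def bead():
    return BeadMagnetics()


@pytest.fixture(scope="session")
def channel():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def vthr(sensor, acq):
    """Voltage threshold equivalent to the 2.2 μT pooled detectivity."""
    return float(field_to_voltage(sensor.detectivity, acq))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
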