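import dataclasses

import numpy as np
import pytest

from afplab import presets
from afplab.control_volume import BoxGeometry, FluidProperties
from afplab.instrument import ModalMode, ModalModel, SensorSpec


@pytest.fixture
def geom() -> BoxGeometry:
    return presets.AFP_BOX


@pytest.fixture
def air() -> FluidProperties:
    return presets.AIR


@pytest.fixture
def platform_modes() -> ModalModel:
    return presets.PLATFORM_MODES


@pytest.fixture
def single_mode() -> ModalModel:
    return ModalModel(
        modes=(ModalMode(natural_frequency=132.0, damping_ratio=0.03, participation=1.0),)
    )


@pytest.fixture
def quiet_sensor() -> SensorSpec:
    """Platform sensors with noise switched off (quantization kept)."""
    return dataclasses.replace(presets.PLATFORM_SENSORS, noise_rms=0.0)


@pytest.fixture
def ideal_sensor() -> SensorSpec:
    """No noise, negligible quantization, unity calibration."""
    return dataclasses.replace(
        presets.PLATFORM_SENSORS,
        noise_rms=0.0,
        resolution=1e-12,
        calibration_coefficient=1.0,
        preload_total=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
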