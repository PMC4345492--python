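"""Published parameter sets for the first-generation platform.

These constants collect the printed properties of the original instrument
and its validation setup: inner box dimensions 0.420 x 0.525 x 0.452 m
(height x width x depth), a 1.79 kg platform on three load cells sampling
at 1 ms with 2 mN resolution (linear calibration coefficient 0.989), a
dominant 132 Hz vertical structural mode weakly coupled to a small 105 Hz
mode, a 138 Hz reference beam with two load cells (coefficient 0.997), and
a 28 g parrotlet flying at a 20 Hz wingbeat between perches 0.28 m apart.

Damping ratios are not published for the structure; 0.03 per mode is a
typical value for stiff balsa sandwich construction and is configurable
wherever it matters.
"""

from __future__ import annotations

from .control_volume import BoxGeometry, FluidProperties
from .instrument import ModalMode, ModalModel, SensorSpec
from .signals import FilterSpec
from .synthetic import BirdFlightSpec, ThrustProfileSpec

#: Air with the kinematic viscosity consistent with the instrument's
#: Re ~ 27 000 screening check (nu = 1.48e-5 m^2/s), c = 340 m/s.
AIR = FluidProperties(rho=1.204, nu=1.48e-5, c=340.0)

#: Air at 25 degrees C (used for boundary-layer shear estimates).
AIR_25C = FluidProperties(rho=1.184, nu=1.562e-5, c=346.1)

#: Inner control volume: width (x) 0.525 m, depth (y) 0.452 m,
#: height (z, vertical) 0.420 m.
AFP_BOX = BoxGeometry(Lx=0.525, Ly=0.452, Lz=0.420)

#: Platform structural model: dominant 132 Hz vertical mode with a weakly
#: coupled small-amplitude 105 Hz mode (5% participation).
PLATFORM_MODES = ModalModel(
    modes=(
        ModalMode(natural_frequency=132.0, damping_ratio=0.03, participation=0.95),
        ModalMode(natural_frequency=105.0, damping_ratio=0.03, participation=0.05),
    )
)

#: Reference beam + suspended quadcopter: single 138 Hz mode.
BEAM_MODES = ModalModel(
    modes=(ModalMode(natural_frequency=138.0, damping_ratio=0.03, participation=1.0),)
)

PLATFORM_MASS = 1.79  # kg, sets the load-cell preload

PLATFORM_SENSORS = SensorSpec(
    n_channels=3,
    resolution=2e-3,
    sampling_interval=1e-3,
    calibration_coefficient=0.989,
    noise_rms=2e-3,
    preload_total=PLATFORM_MASS * 9.81,
)

BEAM_SENSORS = SensorSpec(
    n_channels=2,
    resolution=2e-3,
    sampling_interval=1e-3,
    calibration_coefficient=0.997,
    noise_rms=2e-3,
    preload_total=0.0,
)

#: Validation filter (quadcopter runs) and flight filter (bird runs).
VALIDATION_FILTER = FilterSpec(order=4, cutoff=30.0, application="zero-phase")
FLIGHT_FILTER = FilterSpec(order=4, cutoff=60.0, application="zero-phase")

#: Thrust-profile presets used in systematic validation: constant thrust
#: and semi-sinusoids at 0.125, 0.25 and 0.5 Hz (84 periods each).
VALIDATION_PROFILES = (
    ThrustProfileSpec(kind="constant", n_periods=84, mean_thrust=1.0),
    ThrustProfileSpec(kind="semi_sinusoid", frequency=0.125, n_periods=84,
                      mean_thrust=1.0, modulation_amplitude=0.5),
    ThrustProfileSpec(kind="semi_sinusoid", frequency=0.25, n_periods=84,
                      mean_thrust=1.0, modulation_amplitude=0.5),
    ThrustProfileSpec(kind="semi_sinusoid", frequency=0.5, n_periods=84,
                      mean_thrust=1.0, modulation_amplitude=0.5),
)

#: A 28 g parrotlet hopping between perches 0.28 m apart at 20 Hz,
#: downstroke peaks up to twice body weight, negligible upstroke support.
PARROTLET = BirdFlightSpec()

#: Near-wall flow speed measured along the walls during validation runs.
NEAR_WALL_SPEED = 0.95  # m/s

#: Largest force-fluctuation frequency of interest for a 20 Hz wingbeat.
MAX_FORCE_FREQUENCY = 18.0  # Hz

#: Characteristic enclosure length scale used for compactness screening
#: (of the order of the inner box height).
AFP_LENGTH = 0.41  # m
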