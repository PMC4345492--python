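"""Generators for every input the pipeline needs.

Nothing here requires a download: quadcopter-like thrust profiles
(constant, semi-sinusoidal or hand-controlled-like), small-parrot flight
force traces with matching stroke segmentations, and balloon-pop impulse
trains are all produced from explicit parameter specs with seeded
randomness, and every trace carries its generating spec in ``meta`` so
downstream parameter-recovery tests can compare against stated truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np

from .core import ForceTrace
from .signals import BodyProperties, Stroke, StrokeSegmentation


@dataclass(frozen=True)
class ThrustProfileSpec:
    """Quadcopter-style thrust profile.

    ``kind``: ``constant`` (steady mean thrust), ``semi_sinusoid`` (mean
    thrust plus a sinusoidal modulation, clipped at zero because rotors
    cannot pull) or ``manual_random`` (a smoothed seeded random walk below
    2 Hz, emulating a hand-controlled throttle).  Frequency presets used in
    validation runs are 0.125, 0.25 and 0.5 Hz over 84 periods.
    """

    kind: Literal["constant", "semi_sinusoid", "manual_random"] = "semi_sinusoid"
    frequency: float = 0.5
    n_periods: float = 84
    mean_thrust: float = 1.0
    modulation_amplitude: float = 0.5
    sample_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "semi_sinusoid", "manual_random"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind != "constant" and self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.modulation_amplitude > self.mean_thrust:
            raise ValueError(
                "modulation_amplitude must not exceed mean_thrust (thrust >= 0)"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        f = self.frequency if self.kind != "constant" else 0.5
        return self.n_periods / f


@dataclass(frozen=True)
class BirdFlightSpec:
    """Perch-to-perch flight of a small parrot.

    Defaults emulate a 28 g bird at 20 Hz wingbeat frequency hopping
    between perches 0.28 m apart: downstroke vertical force is a half-sine
    peaking at ``downstroke_peak_multiple`` body weights (up to 2), the
    upstroke supports ``upstroke_support_multiple`` body weights (near
    zero), and brief leg-push / landing-deceleration impulses bracket the
    aerial phase.  Cycle-to-cycle amplitude jitter is +-5% (seeded).
    """

    mass: float = 0.028
    wingbeat_frequency: float = 20.0
    downstroke_peak_multiple: float = 2.0
    upstroke_support_multiple: float = 0.05
    downstroke_fraction: float = 0.5
    n_wingbeats: int = 8
    perch_distance: float = 0.28
    takeoff_push_multiple: float = 1.5
    push_width: float = 0.04
    amplitude_jitter: float = 0.05
    sample_rate: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.wingbeat_frequency <= 0:
            raise ValueError("wingbeat_frequency must be positive")
        if self.downstroke_peak_multiple < 0 or self.upstroke_support_multiple < 0:
            raise ValueError("support multiples must be non-negative")
        if not 0.0 < self.downstroke_fraction < 1.0:
            raise ValueError("downstroke_fraction must be in (0, 1)")
        if self.n_wingbeats < 1:
            raise ValueError("n_wingbeats must be >= 1")
        if not 0.0 <= self.amplitude_jitter < 1.0:
            raise ValueError("amplitude_jitter must be in [0, 1)")


def gen_thrust_profile(spec: ThrustProfileSpec) -> ForceTrace:
    """Generate a thrust trace according to the spec; see
    :class:`ThrustProfileSpec` for waveform definitions."""
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.duration / dt)) + 1
    t = dt * np.arange(n)
    if spec.kind == "constant":
        f = np.full(n, spec.mean_thrust)
    elif spec.kind == "semi_sinusoid":
        f = spec.mean_thrust + spec.modulation_amplitude * np.sin(
            2.0 * math.pi * spec.frequency * t
        )
        f = np.clip(f, 0.0, None)
    else:  # manual_random: band-limited (<= 2 Hz) seeded wander about the mean
        from scipy import signal as sps

        rng = np.random.default_rng(spec.seed)
        white = rng.normal(0.0, 1.0, n)
        sos = sps.butter(4, 2.0, btype="low", fs=spec.sample_rate, output="sos")
        slow = sps.sosfiltfilt(sos, white)
        rms = np.sqrt(np.mean(slow**2))
        if rms > 0:
            slow = slow / rms * spec.modulation_amplitude
        f = np.clip(spec.mean_thrust + slow, 0.0, None)
    return ForceTrace(t, f, {"spec": asdict(spec), "generator": "gen_thrust_profile"})


def gen_bird_flight(
    spec: BirdFlightSpec,
) -> tuple[ForceTrace, StrokeSegmentation, BodyProperties]:
    """Generate a synthetic perch-to-perch flight.

    Returns the vertical force trace, the matching stroke segmentation
    (alternating downstrokes and upstrokes tiling the aerial phase, with
    take-off/landing bounds), and the body properties.  Within each
    wingbeat the downstroke force is a half-sine of peak
    ``W * downstroke_peak_multiple * jitter`` and the upstroke a constant
    ``W * upstroke_support_multiple``; leg-push and landing
    impulses sit just outside the flight bounds.
    """
    body = BodyProperties(mass=spec.mass)
    W = body.weight
    T = 1.0 / spec.wingbeat_frequency
    T_down = spec.downstroke_fraction * T
    dt = 1.0 / spec.sample_rate
    rng = np.random.default_rng(spec.seed)

    lead = 2.0 * spec.push_width  # perch time before take-off / after landing
    takeoff = lead
    landing = takeoff + spec.n_wingbeats * T
    total = landing + lead
    n = int(round(total / dt)) + 1
    t = dt * np.arange(n)
    f = np.zeros(n)

    strokes: list[Stroke] = []
    for j in range(spec.n_wingbeats):
        t0 = takeoff + j * T
        jit = 1.0 + rng.uniform(-spec.amplitude_jitter, spec.amplitude_jitter)
        # downstroke: half-sine hump
        m_down = (t >= t0) & (t < t0 + T_down)
        tau = (t[m_down] - t0) / T_down
        f[m_down] += W * spec.downstroke_peak_multiple * jit * np.sin(math.pi * tau)
        # upstroke: low constant support (half-sine mean is 2/pi of its peak,
        # so the analytic wingbeat mean is d*peak*2/pi + (1-d)*upstroke)
        m_up = (t >= t0 + T_down) & (t < t0 + T)
        f[m_up] += W * spec.upstroke_support_multiple
        strokes.append(Stroke(t0, t0 + T_down, "downstroke"))
        strokes.append(Stroke(t0 + T_down, t0 + T, "upstroke"))

    # leg push-off before take-off, landing deceleration after touchdown
    for center, mult in (
        (takeoff - 0.5 * spec.push_width, spec.takeoff_push_multiple),
        (landing + 0.5 * spec.push_width, spec.takeoff_push_multiple),
    ):
        m = np.abs(t - center) < 0.5 * spec.push_width
        f[m] += W * mult * 0.5 * (
            1.0 + np.cos(2.0 * math.pi * (t[m] - center) / spec.push_width)
        )

    seg = StrokeSegmentation(strokes=tuple(strokes), flight_bounds=(takeoff, landing))
    trace = ForceTrace(t, f, {"spec": asdict(spec), "generator": "gen_bird_flight"})
    return trace, seg, body


def gen_pop_impulse(
    amplitude: float,
    width: float,
    n_pops: int,
    spacing: float,
    seed: int = 0,
    sample_rate: float = 10000.0,
    timing_jitter: float = 0.1,
) -> ForceTrace:
    """Train of raised-cosine impulses with seeded timing jitter.

    Each pulse is ``amplitude/2 * (1 - cos(2 pi tau / width))`` over its
    width, so a single pulse integrates to ``amplitude * width / 2``.
    """
    if width >= spacing:
        raise ValueError("width must be smaller than spacing")
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    total = spacing * (n_pops + 1)
    n = int(round(total / dt)) + 1
    t = dt * np.arange(n)
    f = np.zeros(n)
    for k in range(n_pops):
        center = spacing * (k + 1) + rng.uniform(-timing_jitter, timing_jitter) * spacing
        m = np.abs(t - center) < 0.5 * width
        f[m] += amplitude * 0.5 * (1.0 - np.cos(2.0 * math.pi * ((t[m] - center) / width + 0.5)))
    return ForceTrace(
        t,
        f,
        {
            "generator": "gen_pop_impulse",
            "amplitude": amplitude,
            "width": width,
            "n_pops": n_pops,
            "spacing": spacing,
            "seed": seed,
        },
    )
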