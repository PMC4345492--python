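"""Simulator of the instrumented platform.

The physical platform is a stiff, lightweight box resting on three six-axis
load cells, statically determinate and equally preloaded by the platform's
own weight.  Its vertical structural response is dominated by a 132 Hz mode
weakly coupled to a small-amplitude 105 Hz mode; the reference beam used for
validation rings at 138 Hz.  This module turns a true vertical force trace
into the multichannel recording such an instrument would produce: modal
filtering, equal channel split plus preload, additive sensor noise,
mid-tread quantization at the load-cell resolution, sampling at the
acquisition interval, and a separate linear calibration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import ForceTrace


@dataclass(frozen=True)
class ModalMode:
    """One structural resonance: natural frequency [Hz], damping ratio,
    and its participation in the force path (participations sum to 1)."""

    natural_frequency: float
    damping_ratio: float
    participation: float

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be positive")
        if not 0.0 < self.damping_ratio < 1.0:
            raise ValueError("damping_ratio must be in (0, 1)")
        if self.participation < 0:
            raise ValueError("participation must be non-negative")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.natural_frequency

    @property
    def damped_frequency(self) -> float:
        """Ringdown frequency [Hz] of the underdamped mode."""
        return self.natural_frequency * float(np.sqrt(1.0 - self.damping_ratio**2))


@dataclass(frozen=True)
class ModalModel:
    """Force transfer of the structure: a participation-weighted sum of
    second-order resonators, with unity DC gain."""

    modes: tuple[ModalMode, ...]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one mode required")
        total = sum(m.participation for m in self.modes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"participations must sum to 1, got {total}")

    @property
    def primary(self) -> ModalMode:
        return max(self.modes, key=lambda m: m.participation)

    @property
    def natural_period(self) -> float:
        """Vibration period of the primary mode, seconds: the intrinsic
        response-delay scale of the instrument."""
        return 1.0 / self.primary.natural_frequency

    def frequency_response(self, f: np.ndarray) -> np.ndarray:
        """Complex transfer H(f) from applied to sensed force."""
        f = np.asarray(f, dtype=float)
        s = 2j * np.pi * f
        H = np.zeros_like(s, dtype=complex)
        for m in self.modes:
            w = m.omega
            H += m.participation * w**2 / (s**2 + 2.0 * m.damping_ratio * w * s + w**2)
        return H

    def apply(self, t: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Filter a uniformly sampled signal through the modal transfer."""
        y = np.zeros_like(x, dtype=float)
        for m in self.modes:
            w = m.omega
            sys = sps.TransferFunction([w**2], [1.0, 2.0 * m.damping_ratio * w, w**2])
            _, yi, _ = sps.lsim(sys, x, t)
            y += m.participation * yi
        return y


@dataclass(frozen=True)
class SensorSpec:
    """Load-cell array parameters.

    ``resolution`` is the force quantization step per channel [N],
    ``sampling_interval`` the acquisition period [s],
    ``calibration_coefficient`` the linear factor mapping raw readings to
    newtons, ``noise_rms`` additive Gaussian noise per channel [N] and
    ``preload_total`` the static weight shared equally by the channels [N].
    """

    n_channels: int = 3
    resolution: float = 2e-3
    sampling_interval: float = 1e-3
    calibration_coefficient: float = 0.989
    noise_rms: float = 2e-3
    preload_total: float = 1.79 * 9.81

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not 0.9 < self.calibration_coefficient <= 1.1:
            raise ValueError("calibration_coefficient must be in (0.9, 1.1]")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")


class CalibrationStateError(RuntimeError):
    """Calibration applied twice."""


@dataclass
class Recording:
    """Multichannel load-cell output.

    ``channels`` has shape (n_channels, n_samples); raw (uncalibrated)
    channel values are integer multiples of the sensor resolution.
    """

    time: np.ndarray
    channels: np.ndarray
    sensor: SensorSpec
    seed: Optional[int] = None
    calibration_applied: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape != (self.sensor.n_channels, self.time.size):
            raise ValueError("channels must have shape (n_channels, n_samples)")

    @property
    def dt(self) -> float:
        return self.sensor.sampling_interval

    def channel_sum(self) -> np.ndarray:
        return self.channels.sum(axis=0)

    def net_force(self) -> ForceTrace:
        """Channel sum minus the static preload: the measured fluid force.

        The preload is defined in true newtons; raw (uncalibrated) channels
        carry it divided by the calibration coefficient.
        """
        preload = self.sensor.preload_total
        if not self.calibration_applied:
            preload = preload / self.sensor.calibration_coefficient
        return ForceTrace(
            self.time,
            self.channel_sum() - preload,
            {"calibration_applied": self.calibration_applied, **self.meta},
        )


def simulate_recording(
    true_force: ForceTrace,
    modal: ModalModel,
    sensor: SensorSpec,
    seed: int = 0,
    internal_rate: Optional[float] = None,
) -> Recording:
    """Simulate the raw multichannel recording of a true vertical force.

    Pipeline: resample the input onto an internal grid fine enough to
    resolve the structural modes (default: at least 10x the highest natural
    frequency and at least the input rate), filter through the modal
    transfer function, divide equally across channels plus per-channel
    preload, apply the inverse calibration gain (raw sensor units), add
    seeded Gaussian noise, quantize mid-tread at the resolution, and sample
    at the acquisition interval.  Calibration is *not* applied; see
    :func:`apply_calibration`.
    """
    if len(true_force) < 10:
        raise ValueError("true_force must cover at least 10 sampling intervals")
    if true_force.dt > sensor.sampling_interval * (1 + 1e-9):
        raise ValueError("true_force must be sampled at least at the sensor rate")

    f_max = max(m.natural_frequency for m in modal.modes)
    if internal_rate is None:
        internal_rate = max(10.0 * f_max, true_force.sample_rate)
    fine = true_force.resample(1.0 / internal_rate)
    sensed = modal.apply(fine.time, fine.force)

    # sample at the acquisition interval
    n_out = int(np.floor(fine.duration / sensor.sampling_interval)) + 1
    t_out = fine.time[0] + sensor.sampling_interval * np.arange(n_out)
    sensed_out = np.interp(t_out, fine.time, sensed)

    rng = np.random.default_rng(seed)
    n_ch = sensor.n_channels
    per_channel = (sensed_out + sensor.preload_total) / n_ch
    raw = per_channel[None, :] / sensor.calibration_coefficient
    raw = raw + rng.normal(0.0, sensor.noise_rms, size=(n_ch, n_out))
    raw = sensor.resolution * np.round(raw / sensor.resolution)

    return Recording(
        time=t_out,
        channels=raw,
        sensor=sensor,
        seed=seed,
        calibration_applied=False,
        meta={"true_force_meta": dict(true_force.meta)},
    )


def pop_test(
    modal: ModalModel,
    sensor: SensorSpec,
    n_pops: int = 5,
    seed: int = 0,
    amplitude: float = 5.0,
    width: float = 2e-3,
    spacing: float = 1.0,
) -> Recording:
    """Impulse-excitation recording for natural-frequency identification.

    Emulates the standard protocol of exciting the platform a handful of
    times with a short broadband impulse (a balloon pop) and recording the
    ringdown.  Pops are raised-cosine impulses of the given amplitude and
    width, spaced ``spacing`` seconds apart with seeded +-10% timing jitter.
    """
    from .synthetic import gen_pop_impulse

    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    trace = gen_pop_impulse(
        amplitude=amplitude,
        width=width,
        n_pops=n_pops,
        spacing=spacing,
        seed=seed,
        sample_rate=max(4.0 / width, 1.0 / sensor.sampling_interval),
    )
    return simulate_recording(trace, modal, sensor, seed=seed)


def apply_calibration(rec: Recording) -> Recording:
    """Multiply raw channels by the linear calibration coefficient.

    Returns a new Recording; refuses to calibrate twice.
    """
    if rec.calibration_applied:
        raise CalibrationStateError("calibration already applied")
    return Recording(
        time=rec.time.copy(),
        channels=rec.channels * rec.sensor.calibration_coefficient,
        sensor=rec.sensor,
        seed=rec.seed,
        calibration_applied=True,
        meta=dict(rec.meta),
    )
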