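"""Measurement analysis: filtering, validation metrics, natural-frequency
estimation, net acceleration and wingbeat-resolved weight support.

The analysis chain mirrors how force-platform recordings are processed:
both the platform and the reference signal receive an identical low-pass
Butterworth filter, agreement is summarized by impulse and mean-force
ratios plus a cross-correlation delay, structural resonances are read off
pop-test spectra, and flight recordings are reduced to per-stroke and
per-wingbeat weight support (vertical force over body weight).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import ForceTrace
from .instrument import Recording

G = 9.81  # m s^-2


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter: order, cut-off [Hz], and whether it is
    applied forward-backward (zero-phase, the default) or single-pass."""

    order: int = 4
    cutoff: float = 30.0
    application: Literal["zero-phase", "single-pass"] = "zero-phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.application not in ("zero-phase", "single-pass"):
            raise ValueError("application must be 'zero-phase' or 'single-pass'")


@dataclass(frozen=True)
class ValidationMetrics:
    """Agreement between a platform trace and a reference trace:
    ratio of total impulses (trapezoidal), ratio of mean forces, and the
    cross-correlation delay in seconds (positive = platform lags; NaN when
    the reference carries no fluctuation to correlate against, as for a
    constant thrust profile)."""

    total_impulse_ratio: float
    average_force_ratio: float
    delay: float

    def as_dict(self) -> dict:
        return {
            "total_impulse_ratio": self.total_impulse_ratio,
            "average_force_ratio": self.average_force_ratio,
            "delay_ms": self.delay * 1e3,
        }


@dataclass(frozen=True)
class BodyProperties:
    """Mass [kg] and weight [N] of the flying body."""

    mass: float
    g: float = G

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def weight(self) -> float:
        return self.mass * self.g


@dataclass(frozen=True)
class Stroke:
    start: float
    end: float
    phase: Literal["downstroke", "upstroke"]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("stroke end must follow start")
        if self.phase not in ("downstroke", "upstroke"):
            raise ValueError("phase must be 'downstroke' or 'upstroke'")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StrokeSegmentation:
    """Time-ordered, non-overlapping strokes with alternating phase, plus
    take-off and landing markers bounding the aerial phase.

    Stroke boundaries follow the kinematic convention: a downstroke starts
    when the wing is at its highest position, an upstroke when it is at its
    lowest.  Markers come from synchronized video (or a generator); no
    force-based flight detection is attempted.
    """

    strokes: tuple[Stroke, ...]
    flight_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        for a, b in zip(self.strokes, self.strokes[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError("strokes must be time-ordered and non-overlapping")
            if b.phase == a.phase:
                raise ValueError("stroke phases must alternate")
        t0, t1 = self.flight_bounds
        if t1 <= t0:
            raise ValueError("landing must follow take-off")

    def __len__(self) -> int:
        return len(self.strokes)


@dataclass
class WeightSupportSummary:
    """Per-stroke and per-wingbeat weight support.

    ``strokes`` columns: start, end, phase, duration, mean_support.
    ``wingbeats`` columns: start, end, mean_support (duration-weighted over
    the downstroke and its following upstroke), complete (False for a
    trailing unpaired stroke).  ``peak_support`` is the maximum of the
    filtered force over weight within the flight bounds.
    """

    strokes: pd.DataFrame
    wingbeats: pd.DataFrame
    peak_support: float
    mean_support: float
    body: BodyProperties


def _as_force_trace(x: Union[ForceTrace, Recording]) -> ForceTrace:
    if isinstance(x, Recording):
        return x.net_force()
    return x


def lowpass(trace: Union[ForceTrace, Recording], spec: FilterSpec) -> ForceTrace:
    """Low-pass Butterworth filter of a force trace (or a recording's
    channel-sum net force), preserving length and time base.

    Zero-phase application filters forward and backward (squaring the
    magnitude response, doubling the effective order, adding no delay);
    single-pass applies the causal filter once.
    """
    tr = _as_force_trace(trace)
    nyq = 0.5 * tr.sample_rate
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=tr.sample_rate, output="sos")
    if spec.application == "zero-phase":
        y = sps.sosfiltfilt(sos, tr.force)
    else:
        y = sps.sosfilt(sos, tr.force)
    return tr.with_force(y, filter=f"butter{spec.order}@{spec.cutoff}Hz/{spec.application}")


def _xcorr_delay(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Delay of ``a`` behind ``b`` in seconds: argmax of the cross-correlation
    of the mean-removed signals, with parabolic sub-sample interpolation."""
    x = a - a.mean()
    y = b - b.mean()
    scale = max(abs(a.mean()), abs(b.mean()), 1.0)
    if x.std() < 1e-8 * scale or y.std() < 1e-8 * scale:
        return float("nan")  # nothing to correlate against (constant signal)
    cc = sps.correlate(x, y, mode="full")
    lags = sps.correlation_lags(len(x), len(y), mode="full")
    i = int(np.argmax(cc))
    shift = float(lags[i])
    if 0 < i < len(cc) - 1:
        d2 = cc[i - 1] - 2.0 * cc[i] + cc[i + 1]
        if d2 != 0.0:
            shift += 0.5 * (cc[i - 1] - cc[i + 1]) / d2
    return shift * dt


def validation_metrics(
    afp: Union[ForceTrace, Recording],
    reference: Union[ForceTrace, Recording],
) -> ValidationMetrics:
    """Compare a platform measurement against an independent reference.

    Both traces must share the sampling grid and have received identical
    filtering.  Ratios are platform over reference; the delay is positive
    when the platform lags the reference.
    """
    a = _as_force_trace(afp)
    r = _as_force_trace(reference)
    if len(a) != len(r):
        raise ValueError("traces must have equal length")
    if abs(a.dt - r.dt) > 1e-12:
        raise ValueError("traces must share the sampling interval")
    imp_ref = float(np.trapezoid(r.force, r.time))
    mean_ref = float(np.mean(r.force))
    if imp_ref == 0.0 or mean_ref == 0.0:
        raise ZeroDivisionError("reference impulse/mean force is zero; ratios undefined")
    imp_afp = float(np.trapezoid(a.force, a.time))
    return ValidationMetrics(
        total_impulse_ratio=imp_afp / imp_ref,
        average_force_ratio=float(np.mean(a.force)) / mean_ref,
        delay=_xcorr_delay(a.force, r.force, a.dt),
    )


class PeakNotFoundError(ValueError):
    """No spectral peak above the noise floor in the requested band."""


def natural_frequency(
    rec: Union[Recording, ForceTrace],
    band: tuple[float, float] = (50.0, 300.0),
    nperseg: Optional[int] = None,
) -> float:
    """Dominant structural resonance frequency from an impulse recording.

    Welch periodogram of the net force (segments average over the separate
    impulse ringdowns), restricted to ``band``; the peak bin is refined by
    parabolic interpolation on log power.
    """
    tr = _as_force_trace(rec)
    fs = tr.sample_rate
    lo, hi = band
    if not 0 <= lo < hi <= 0.5 * fs:
        raise ValueError("band must lie within (0, Nyquist)")
    if nperseg is None:
        nperseg = min(len(tr), max(256, int(fs)))  # ~1 Hz resolution at 1 kHz
    f, pxx = sps.welch(tr.force - np.mean(tr.force), fs=fs, nperseg=nperseg)
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise PeakNotFoundError("requested band contains no spectral bins")
    fb, pb = f[sel], pxx[sel]
    noise_floor = np.median(pb)
    i = int(np.argmax(pb))
    if pb[i] < 10.0 * noise_floor:
        raise PeakNotFoundError("no peak above the noise floor in band")
    # parabolic refinement on log power
    if 0 < i < len(pb) - 1:
        lp = np.log(pb[i - 1 : i + 2])
        d2 = lp[0] - 2.0 * lp[1] + lp[2]
        if d2 != 0.0:
            return float(fb[i] + 0.5 * (lp[0] - lp[2]) / d2 * (fb[1] - fb[0]))
    return float(fb[i])


def net_acceleration(f_net: ForceTrace, body: BodyProperties) -> ForceTrace:
    """Net vertical acceleration a(t) = (F(t) - W) / m of the flying body."""
    a = (f_net.force - body.weight) / body.mass
    return f_net.with_force(a, quantity="acceleration_m_per_s2")


def weight_support(
    filtered: ForceTrace,
    body: BodyProperties,
    seg: StrokeSegmentation,
    last_stroke: Literal["separate", "drop"] = "separate",
) -> WeightSupportSummary:
    """Wingbeat-resolved weight support from a filtered force trace.

    Each stroke's support is the time-averaged vertical force over body
    weight within the stroke window (trapezoidal mean).  A wingbeat pairs a
    downstroke with its following upstroke, weighting by stroke durations.
    ``last_stroke`` controls a trailing unpaired stroke: ``"separate"``
    reports it as an incomplete wingbeat, ``"drop"`` omits it.  Peak and
    whole-flight mean support are evaluated within the flight bounds only.
    """
    W = body.weight
    rows = []
    for s in seg.strokes:
        rows.append(
            {
                "start": s.start,
                "end": s.end,
                "phase": s.phase,
                "duration": s.duration,
                "mean_support": _window_mean(filtered, s.start, s.end) / W,
            }
        )
    strokes = pd.DataFrame(
        rows, columns=["start", "end", "phase", "duration", "mean_support"]
    )

    beats = []
    i = 0
    while i < len(seg.strokes):
        s = seg.strokes[i]
        if s.phase == "downstroke" and i + 1 < len(seg.strokes):
            u = seg.strokes[i + 1]
            wsum = rows[i]["mean_support"] * s.duration + rows[i + 1]["mean_support"] * u.duration
            beats.append(
                {
                    "start": s.start,
                    "end": u.end,
                    "mean_support": wsum / (s.duration + u.duration),
                    "complete": True,
                }
            )
            i += 2
        else:
            if last_stroke == "separate":
                beats.append(
                    {
                        "start": s.start,
                        "end": s.end,
                        "mean_support": rows[i]["mean_support"],
                        "complete": False,
                    }
                )
            i += 1
    wingbeats = pd.DataFrame(beats, columns=["start", "end", "mean_support", "complete"])

    t0, t1 = seg.flight_bounds
    mask = (filtered.time >= t0) & (filtered.time <= t1)
    if np.any(mask):
        peak = float(np.max(filtered.force[mask]) / W)
        mean = float(np.trapezoid(filtered.force[mask], filtered.time[mask])
                     / max(t1 - t0, 1e-300) / W) if mask.sum() > 1 else 0.0
    else:
        peak = 0.0
        mean = 0.0
    return WeightSupportSummary(
        strokes=strokes, wingbeats=wingbeats, peak_support=peak, mean_support=mean, body=body
    )


def _window_mean(trace: ForceTrace, t0: float, t1: float) -> float:
    """Time-averaged force over [t0, t1], trapezoidal with edge interpolation."""
    if t1 <= t0:
        raise ValueError("empty window")
    tt = trace.time
    lo = np.searchsorted(tt, t0, side="left")
    hi = np.searchsorted(tt, t1, side="right")
    t = np.concatenate([[t0], tt[lo:hi], [t1]])
    ff = np.interp(t, tt, trace.force)
    # drop duplicate endpoints if t0/t1 coincide with samples
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, ff = t[keep], ff[keep]
    if len(t) < 2:
        return float(np.interp(0.5 * (t0 + t1), tt, trace.force))
    return float(np.trapezoid(ff, t) / (t[-1] - t[0]))
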