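"""Signal pipeline: filtering, validation metrics, frequency estimation,
net acceleration and weight support."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afplab.core import ForceTrace
from afplab.signals import (
    BodyProperties,
    FilterSpec,
    PeakNotFoundError,
    Stroke,
    StrokeSegmentation,
    lowpass,
    natural_frequency,
    net_acceleration,
    validation_metrics,
    weight_support,
)
from afplab.synthetic import BirdFlightSpec, gen_bird_flight

from oracles import butterworth_gain


def _sine_trace(f0: float, fs: float = 1000.0, duration: float = 10.0,
                amp: float = 1.0, offset: float = 0.0) -> ForceTrace:
    t = np.arange(0.0, duration, 1.0 / fs)
    return ForceTrace(t, offset + amp * np.sin(2 * np.pi * f0 * t))


class TestLowpass:
    def test_constant_unchanged(self):
        t = np.arange(0.0, 1.0, 1e-3)
        tr = ForceTrace(t, np.full_like(t, 2.5))
        out = lowpass(tr, FilterSpec(order=4, cutoff=30.0))
        np.testing.assert_allclose(out.force, 2.5, rtol=1e-9)

    @pytest.mark.parametrize("f0,cutoff,zero_phase", [
        (300.0, 30.0, True),   # 10x cutoff
        (0.5, 30.0, True),     # well inside passband
        (300.0, 30.0, False),
    ])
    def test_attenuation_matches_butterworth_magnitude(self, f0, cutoff, zero_phase):
        tr = _sine_trace(f0, fs=2000.0, duration=20.0)
        spec = FilterSpec(order=4, cutoff=cutoff,
                          application="zero-phase" if zero_phase else "single-pass")
        out = lowpass(tr, spec)
        mid = out.force[len(out) // 4 : -len(out) // 4]
        measured = (mid.max() - mid.min()) / 2.0
        expected = butterworth_gain(np.array([f0]), cutoff, 4, zero_phase)[0]
        if expected < 1e-4:
            assert measured < 1e-4  # >= 40 dB down at 10x cutoff, squared
        else:
            assert measured == pytest.approx(expected, rel=2e-3)

    def test_cutoff_above_nyquist_rejected(self):
        tr = _sine_trace(1.0, fs=100.0)
        with pytest.raises(ValueError):
            lowpass(tr, FilterSpec(cutoff=60.0))


class TestValidationMetrics:
    def test_identical_traces(self):
        tr = _sine_trace(0.5, offset=1.0)
        m = validation_metrics(tr, tr)
        assert m.total_impulse_ratio == pytest.approx(1.0)
        assert m.average_force_ratio == pytest.approx(1.0)
        assert m.delay == pytest.approx(0.0, abs=1e-9)

    def test_scaled_trace_scales_both_ratios(self):
        tr = _sine_trace(0.5, offset=1.0)
        scaled = tr.with_force(tr.force * 1.017)
        m = validation_metrics(scaled, tr)
        assert m.total_impulse_ratio == pytest.approx(1.017)
        assert m.average_force_ratio == pytest.approx(1.017)
        assert m.delay == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, k):
        tr = _sine_trace(0.5, duration=4.0, offset=1.0)
        m = validation_metrics(tr.with_force(k * tr.force), tr)
        assert m.total_impulse_ratio == pytest.approx(k, rel=1e-9)
        assert m.average_force_ratio == pytest.approx(k, rel=1e-9)

    @pytest.mark.parametrize("shift_ms", list(range(1, 11)))
    def test_integer_sample_delay_recovery(self, shift_ms, rng):
        # band-limited signal shifted by whole samples at 1 kHz: the
        # cross-correlation delay must land within half a sample
        from scipy import signal as sps

        fs = 1000.0
        t = np.arange(0.0, 8.0, 1.0 / fs)
        sos = sps.butter(4, 20.0, fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.normal(0, 1, len(t)))
        ref = ForceTrace(t, x + 2.0)
        lagged = ForceTrace(t, np.roll(ref.force, shift_ms))
        m = validation_metrics(lagged, ref)
        assert m.delay * 1e3 == pytest.approx(shift_ms, abs=0.5)

    def test_zero_reference_rejected(self):
        t = np.arange(0.0, 1.0, 1e-3)
        z = ForceTrace(t, np.zeros_like(t))
        with pytest.raises(ZeroDivisionError):
            validation_metrics(z, z)

    def test_constant_reference_delay_is_nan(self):
        t = np.arange(0.0, 1.0, 1e-3)
        c = ForceTrace(t, np.full_like(t, 1.0))
        m = validation_metrics(c, c)
        assert np.isnan(m.delay)
        assert m.total_impulse_ratio == pytest.approx(1.0)

    def test_filtering_neutrality_for_slow_profiles(self):
        # identical zero-phase filtering of both signals leaves the ratios
        # essentially unchanged for sub-hertz thrust profiles
        tr = _sine_trace(0.5, duration=20.0, offset=1.0, amp=0.5)
        meas = tr.with_force(1.01 * tr.force)
        m_raw = validation_metrics(meas, tr)
        spec = FilterSpec(order=4, cutoff=30.0)
        m_filt = validation_metrics(lowpass(meas, spec), lowpass(tr, spec))
        assert m_filt.total_impulse_ratio == pytest.approx(
            m_raw.total_impulse_ratio, rel=2e-3
        )


class TestNaturalFrequency:
    @pytest.mark.parametrize("f0", [132.0, 105.0])
    def test_recovers_synthesized_ringdown_frequency(self, f0):
        fs = 1000.0
        t = np.arange(0.0, 6.0, 1.0 / fs)
        y = np.zeros_like(t)
        for t0 in (1.0, 2.0, 3.0, 4.0, 5.0):
            m = t >= t0
            tau = t[m] - t0
            y[m] += np.exp(-0.03 * 2 * np.pi * f0 * tau) * np.sin(2 * np.pi * f0 * tau)
        est = natural_frequency(ForceTrace(t, y), band=(50.0, 300.0))
        assert est == pytest.approx(f0, abs=2.0)

    def test_no_peak_raises(self, rng):
        t = np.arange(0.0, 2.0, 1e-3)
        flat = ForceTrace(t, rng.normal(0, 1e-3, len(t)))
        with pytest.raises(PeakNotFoundError):
            natural_frequency(flat, band=(50.0, 300.0))


class TestNetAcceleration:
    def test_weight_support_levels(self):
        body = BodyProperties(mass=0.028)
        t = np.arange(0.0, 0.1, 1e-3)
        for mult, expect in [(1.0, 0.0), (2.0, 9.81), (0.0, -9.81)]:
            tr = ForceTrace(t, np.full_like(t, mult * body.weight))
            a = net_acceleration(tr, body)
            np.testing.assert_allclose(a.force, expect, atol=1e-12)


class TestWeightSupport:
    def _segmentation(self, n_beats=4, T=0.05):
        strokes = []
        for j in range(n_beats):
            strokes.append(Stroke(j * T, j * T + T / 2, "downstroke"))
            strokes.append(Stroke(j * T + T / 2, (j + 1) * T, "upstroke"))
        return StrokeSegmentation(tuple(strokes), (0.0, n_beats * T))

    def test_constant_weight_gives_unit_support_everywhere(self):
        body = BodyProperties(mass=0.028)
        seg = self._segmentation()
        t = np.arange(0.0, 0.25, 1e-4)
        tr = ForceTrace(t, np.full_like(t, body.weight))
        s = weight_support(tr, body, seg)
        np.testing.assert_allclose(s.strokes["mean_support"], 1.0, rtol=1e-6)
        np.testing.assert_allclose(s.wingbeats["mean_support"], 1.0, rtol=1e-6)
        assert s.peak_support == pytest.approx(1.0)

    def test_zero_force_gives_zero_support(self):
        body = BodyProperties(mass=0.028)
        seg = self._segmentation()
        t = np.arange(0.0, 0.25, 1e-4)
        s = weight_support(ForceTrace(t, np.zeros_like(t)), body, seg)
        np.testing.assert_allclose(s.strokes["mean_support"], 0.0, atol=1e-12)

    def test_downstroke_dominates_for_bird_like_trace(self):
        spec = BirdFlightSpec(upstroke_support_multiple=0.0, amplitude_jitter=0.0)
        trace, seg, body = gen_bird_flight(spec)
        s = weight_support(trace, body, seg)
        down = s.strokes.loc[s.strokes.phase == "downstroke", "mean_support"]
        up = s.strokes.loc[s.strokes.phase == "upstroke", "mean_support"]
        assert down.min() > 10 * max(up.max(), 1e-9)
        # half-sine of peak 2 averages 2 * 2/pi over the downstroke
        np.testing.assert_allclose(down, 2 * 2 / np.pi, rtol=0.02)
        assert s.peak_support == pytest.approx(2.0, rel=0.01)

    def test_trailing_unpaired_stroke_reported_incomplete(self):
        strokes = (
            Stroke(0.0, 0.025, "downstroke"),
            Stroke(0.025, 0.05, "upstroke"),
            Stroke(0.05, 0.075, "downstroke"),
        )
        seg = StrokeSegmentation(strokes, (0.0, 0.075))
        body = BodyProperties(mass=0.028)
        t = np.arange(0.0, 0.08, 1e-4)
        tr = ForceTrace(t, np.full_like(t, body.weight))
        s = weight_support(tr, body, seg, last_stroke="separate")
        assert list(s.wingbeats["complete"]) == [True, False]
        s2 = weight_support(tr, body, seg, last_stroke="drop")
        assert list(s2.wingbeats["complete"]) == [True]

    def test_alternation_enforced(self):
        with pytest.raises(ValueError):
            StrokeSegmentation(
                (Stroke(0.0, 0.1, "downstroke"), Stroke(0.1, 0.2, "downstroke")),
                (0.0, 0.2),
            )
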