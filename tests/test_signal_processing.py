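"""Spectrum, adaptive cutoff, zero-phase filtering, peaks, envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bradykinet.signal_processing import (
    SignalConfig,
    butterworth_lowpass,
    detect_peaks,
    local_maxima,
    magnitude_spectrum,
    select_cutoff,
    upper_envelope,
)
from bradykinet.types import PeakSet, SpectrumPeaks, TimeCurve

from oracles import brute_force_peaks, naive_local_maxima, one_fourth_rule


def _curve(values, fps=30.0, units="normalized_distance", task="finger_tapping",
           normalized=True, cal=None):
    return TimeCurve(np.asarray(values, float), fps, units, task,
                     normalized=normalized, calibration_frames=cal)


class TestLocalMaxima:
    def test_simple_peak(self):
        assert list(local_maxima([0, 1, 0])) == [1]

    def test_plateau_keeps_leftmost_sample(self):
        assert list(local_maxima([0, 2, 2, 2, 1, 0])) == [1]

    def test_endpoints_never_qualify(self):
        assert list(local_maxima([3, 1, 2, 1, 3])) == [2]
        assert list(local_maxima([5, 1, 1, 5])) == []

    def test_monotone_has_none(self):
        assert len(local_maxima(np.arange(10.0))) == 0

    def test_short_inputs_empty(self):
        assert len(local_maxima([1.0])) == 0
        assert len(local_maxima([1.0, 2.0])) == 0

    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=3, max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_matches_naive_oracle(self, vals):
        assert list(local_maxima(np.array(vals, float))) == naive_local_maxima(vals)


class TestSpectrum:
    def test_pure_tone_peak_at_its_frequency(self):
        fps, f = 30.0, 3.0
        t = np.arange(300) / fps
        peaks = magnitude_spectrum(_curve(0.5 + 0.4 * np.sin(2 * np.pi * f * t)))
        top = peaks.frequencies[np.argmax(peaks.magnitudes)]
        assert abs(top - f) <= peaks.resolution

    def test_constant_curve_has_no_peaks(self):
        peaks = magnitude_spectrum(_curve(np.full(64, 0.7)))
        assert len(peaks) == 0

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 8"):
            magnitude_spectrum(_curve(np.zeros(5)))

    def test_mean_offset_does_not_change_peaks(self):
        t = np.arange(256) / 30.0
        v = 0.3 * np.sin(2 * np.pi * 2.0 * t)
        a = magnitude_spectrum(_curve(v))
        b = magnitude_spectrum(_curve(v + 0.6))
        np.testing.assert_allclose(a.frequencies, b.frequencies)
        np.testing.assert_allclose(a.magnitudes, b.magnitudes, rtol=1e-9)


class TestSelectCutoff:
    @staticmethod
    def _peaks(freq_mag):
        f = np.array(sorted(freq_mag), float)
        return SpectrumPeaks(f[:, 0], f[:, 1], resolution=0.1)

    def test_worked_example(self):
        # Peaks 1 Hz:10, 3 Hz:4, 7 Hz:1 -> reference 10, quarter 2.5,
        # qualifying {1, 3}, highest qualifying frequency 3 Hz.
        peaks = self._peaks([(1.0, 10.0), (3.0, 4.0), (7.0, 1.0)])
        assert select_cutoff(peaks, 30.0) == 3.0

    def test_single_peak_returns_it(self):
        assert select_cutoff(self._peaks([(2.5, 8.0)]), 30.0) == 2.5

    def test_scale_invariant(self):
        base = [(1.0, 10.0), (3.0, 4.0), (7.0, 1.0)]
        scaled = [(f, 17.0 * m) for f, m in base]
        assert select_cutoff(self._peaks(base), 30.0) == select_cutoff(
            self._peaks(scaled), 30.0
        )

    def test_alternative_rule_uses_highest_frequency_peak(self):
        # Reference from the 7 Hz peak (mag 1): every peak qualifies, so the
        # alternative reading returns 7 Hz where the default returns 3 Hz.
        peaks = self._peaks([(1.0, 10.0), (3.0, 4.0), (7.0, 1.0)])
        assert select_cutoff(peaks, 30.0, rule="highest_frequency_peak") == 7.0

    def test_empty_spectrum_falls_back(self):
        empty = SpectrumPeaks(np.array([]), np.array([]), resolution=0.1)
        assert select_cutoff(empty, 30.0) == pytest.approx(5.0)
        assert select_cutoff(empty, 30.0, fallback=2.0) == 2.0

    def test_capped_at_nyquist(self):
        peaks = self._peaks([(20.0, 10.0)])
        assert select_cutoff(peaks, 30.0) == 15.0

    def test_matches_oracle_on_random_spectra(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(1, 12)
            freqs = np.sort(rng.uniform(0.2, 10.0, n))
            mags = rng.uniform(0.01, 20.0, n)
            peaks = SpectrumPeaks(freqs, mags, resolution=0.1)
            assert select_cutoff(peaks, 60.0) == pytest.approx(
                one_fourth_rule(freqs, mags)
            )


class TestButterworth:
    def test_tone_below_corner_passes(self):
        fps = 30.0
        t = np.arange(600) / fps
        v = np.sin(2 * np.pi * 2.0 * t)
        out = butterworth_lowpass(_curve(v, fps), cutoff_hz=6.0)
        mid = slice(100, 500)
        assert np.ptp(out.values[mid]) >= 0.99 * np.ptp(v[mid])

    def test_tone_above_corner_attenuated(self):
        fps = 30.0
        t = np.arange(600) / fps
        v = np.sin(2 * np.pi * 12.0 * t)
        out = butterworth_lowpass(_curve(v, fps), cutoff_hz=3.0)
        assert np.max(np.abs(out.values[100:500])) < 0.05

    def test_zero_phase_keeps_peak_location(self):
        fps = 30.0
        t = np.arange(300) / fps
        v = np.sin(2 * np.pi * 1.0 * t)
        out = butterworth_lowpass(_curve(v, fps), cutoff_hz=5.0)
        assert abs(int(np.argmax(out.values[:60])) - int(np.argmax(v[:60]))) <= 1

    def test_dc_gain_is_unity(self):
        v = np.full(200, 3.14)
        out = butterworth_lowpass(_curve(v, 30.0, units="pixels", normalized=False), 4.0)
        np.testing.assert_allclose(out.values, 3.14, rtol=1e-9)

    @pytest.mark.parametrize("cutoff", [0.0, -1.0, 15.0, 20.0])
    def test_invalid_cutoff_errors(self, cutoff):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_lowpass(_curve(np.zeros(50)), cutoff)


class TestDetectPeaks:
    def test_matches_brute_force_on_random_signals(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            v = rng.normal(0, 1, rng.integers(3, 200))
            thr = float(rng.uniform(0.05, 1.5))
            got = detect_peaks(_curve(v), "finger_tapping",
                               threshold_override=thr)
            assert list(got.indices) == brute_force_peaks(v, thr)

    def test_small_wiggle_rejected_large_peak_kept(self):
        v = np.array([0.0, 1.0, 0.0, 0.04, 0.0, 1.0, 0.0])
        got = detect_peaks(_curve(v), "finger_tapping")  # threshold 0.1
        assert list(got.indices) == [1, 5]

    def test_height_mode(self):
        v = np.array([0.5, 0.6, 0.5, 0.0, 0.05, 0.0])
        cfg = SignalConfig(threshold_mode="height", thresholds={"finger_tapping": 0.3})
        got = detect_peaks(_curve(v), "finger_tapping", cfg)
        assert list(got.indices) == [1]  # 0.05 peak fails the height test

    def test_no_peaks_is_valid(self):
        got = detect_peaks(_curve(np.linspace(0, 1, 20)), "finger_tapping")
        assert len(got) == 0

    def test_rotation_threshold_scales_with_calibration_range(self):
        # Calibration sweep spans 100 degrees -> threshold 0.25 * 100 = 25.
        cal_sweep = np.concatenate([np.linspace(0, 100, 10), np.linspace(100, 0, 10)])
        motion = np.concatenate([cal_sweep, [0, 60, 0, 10, 0, 60, 0]])
        curve = _curve(motion, units="degrees", task="pronation_supination",
                       normalized=False, cal=(0, 20))
        got = detect_peaks(curve, "pronation_supination")
        assert got.threshold_used == pytest.approx(25.0)
        assert 23 not in got.indices  # the 10-degree wiggle
        assert {21, 25} <= set(got.indices)

    def test_unknown_task_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            detect_peaks(_curve(np.zeros(10)), "toe_tapping")


class TestUpperEnvelope:
    def test_interpolates_between_peaks_and_extends_ends(self):
        v = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 3.0, 0.0])
        peaks = PeakSet(np.array([1, 5]), np.array([1.0, 3.0]), threshold_used=0.1)
        env = upper_envelope(_curve(v), peaks)
        np.testing.assert_allclose(env.values, [1.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.0])

    def test_single_peak_gives_constant_envelope(self):
        v = np.array([0.0, 2.0, 0.0, 0.0])
        peaks = PeakSet(np.array([1]), np.array([2.0]), threshold_used=0.1)
        env = upper_envelope(_curve(v), peaks)
        np.testing.assert_allclose(env.values, 2.0)

    def test_empty_peaks_error(self):
        empty = PeakSet(np.array([], dtype=int), np.array([]), threshold_used=0.1)
        with pytest.raises(ValueError, match="empty"):
            upper_envelope(_curve(np.zeros(5)), empty)
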