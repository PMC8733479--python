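"""Spectrum-adaptive filtering, movement-peak detection, and upper envelopes.

The filter cutoff is chosen from the signal itself: the one-sided magnitude
spectrum of the mean-removed curve is scanned for local maxima, and the
cutoff is the highest frequency among peaks whose magnitude reaches at least
one fourth of the largest peak magnitude. The curve is then low-pass filtered
with a zero-phase Butterworth filter, movement peaks are kept when their
prominence clears a task-specific amplitude threshold, and the upper envelope
interpolates linearly between successive peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import signal as sps

from .types import Envelope, PeakSet, SpectrumPeaks, TimeCurve

__all__ = [
    "SignalConfig",
    "magnitude_spectrum",
    "select_cutoff",
    "butterworth_lowpass",
    "detect_peaks",
    "upper_envelope",
    "local_maxima",
]

#: Amplitude-correction thresholds per task: normalized units for the
#: distance tasks; for pronation-supination the value is a *fraction* of the
#: rotation range (the curve is in degrees, so a raw normalized-pixel
#: threshold is dimensionally inapplicable).
DEFAULT_THRESHOLDS: Dict[str, float] = {
    "finger_tapping": 0.1,
    "hand_grasp": 0.25,
    "pronation_supination": 0.25,
}


@dataclass(frozen=True)
class SignalConfig:
    """Tunable knobs of the filtering / peak-detection stage."""

    filter_order: int = 4
    #: The selected spectral frequency is the highest component to preserve;
    #: the Butterworth corner is placed this factor above it so that the
    #: component passes with < 1% amplitude loss under zero-phase filtering.
    cutoff_margin: float = 2.0
    #: "max_magnitude": the one-fourth reference M is the largest peak
    #: magnitude. "highest_frequency_peak": the literal alternative reading,
    #: M = magnitude of the highest-frequency peak.
    cutoff_rule: str = "max_magnitude"
    #: Peak amplitude correction on prominence (default) or absolute height.
    threshold_mode: str = "prominence"
    thresholds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def threshold_for(self, task: str) -> float:
        try:
            return self.thresholds[task]
        except KeyError:
            raise ValueError(f"no amplitude threshold configured for task {task!r}")


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima; on a flat plateau the leftmost
    plateau sample is the peak. Endpoints never qualify."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        return np.array([], dtype=int)
    peaks = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append(i)  # leftmost plateau index
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=int)


def magnitude_spectrum(curve: TimeCurve) -> SpectrumPeaks:
    """Spectral peaks of the mean-removed curve (one-sided magnitude
    spectrum, DC excluded). A constant curve has no peaks."""
    v = curve.values
    if len(v) < 8:
        raise ValueError(f"need at least 8 samples for a spectrum, got {len(v)}")
    centered = v - np.mean(v)
    if np.max(np.abs(centered)) < 1e-12 * max(1.0, abs(float(np.mean(v)))):
        return SpectrumPeaks(np.array([]), np.array([]), resolution=curve.fps / len(v))
    mag = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(len(v), d=1.0 / curve.fps)
    # DC bin is ~0 after mean removal; peak search runs over the full
    # one-sided spectrum, and bin 0 can never be a *local* maximum candidate
    # that matters because mag[0] ~ 0.
    idx = local_maxima(mag)
    idx = idx[freqs[idx] > 0]
    return SpectrumPeaks(freqs[idx], mag[idx], resolution=float(freqs[1]))


def select_cutoff(
    peaks: SpectrumPeaks,
    fps: float,
    rule: str = "max_magnitude",
    fallback: Optional[float] = None,
) -> float:
    """The one-fourth rule: return the highest frequency among spectral peaks
    whose magnitude is at least one fourth of the reference magnitude M.

    With the default rule M is the largest peak magnitude; the alternative
    literal reading takes M from the highest-frequency peak. Scale-invariant.
    An empty peak list returns the documented fallback (fps / 6).
    """
    nyquist = fps / 2.0
    if len(peaks) == 0:
        return fallback if fallback is not None else fps / 6.0
    if rule == "max_magnitude":
        ref = float(np.max(peaks.magnitudes))
    elif rule == "highest_frequency_peak":
        ref = float(peaks.magnitudes[-1])
    else:
        raise ValueError(f"unknown cutoff rule {rule!r}")
    qualifying = peaks.frequencies[peaks.magnitudes >= ref / 4.0]
    cutoff = float(qualifying[-1]) if len(qualifying) else float(peaks.frequencies[-1])
    return min(cutoff, nyquist)


def butterworth_lowpass(curve: TimeCurve, cutoff_hz: float, order: int = 4) -> TimeCurve:
    """Zero-phase (forward-backward) Butterworth low-pass; unit DC gain,
    same length. Cutoff must lie strictly below Nyquist.

    Edge handling uses Gustafsson's method (initial conditions chosen so the
    forward and backward passes agree), which keeps the first and last
    movement peaks essentially transient-free — padding-based edge handling
    biases the envelope endpoints and hence the fatigue feature.
    """
    nyquist = curve.fps / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist}) Hz")
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=curve.fps)
    filtered = sps.filtfilt(b, a, curve.values, method="gust")
    return curve.with_values(filtered)


def _resolve_threshold(curve: TimeCurve, task: str, config: SignalConfig) -> float:
    thr = config.threshold_for(task)
    if task != "pronation_supination":
        return thr
    # Degrees curve: the configured fraction scales the rotation range held
    # during calibration; if the calibration segment is degenerate (or not
    # part of this curve) fall back to the full observed rotation range.
    scale = 0.0
    if curve.calibration_frames is not None:
        start, stop = curve.calibration_frames
        start, stop = max(0, start), min(len(curve.values), stop)
        if stop > start:
            seg = curve.values[start:stop]
            scale = float(np.ptp(seg))
    if scale < 1e-6:
        scale = float(np.ptp(curve.values))
    return thr * scale


def detect_peaks(
    curve: TimeCurve,
    task: str,
    config: Optional[SignalConfig] = None,
    threshold_override: Optional[float] = None,
) -> PeakSet:
    """Movement peaks of a filtered curve after amplitude correction.

    Local maxima (leftmost plateau sample) are kept when their prominence
    (default) or height clears the task threshold. ``threshold_override``
    bypasses the task-threshold resolution with an absolute value in the
    curve's units. An empty PeakSet is a valid result.
    """
    config = config or SignalConfig()
    if threshold_override is not None:
        threshold = float(threshold_override)
    else:
        threshold = _resolve_threshold(curve, task, config)
    candidates = local_maxima(curve.values)
    if len(candidates) == 0:
        return PeakSet(np.array([], dtype=int), np.array([]), threshold)
    if config.threshold_mode == "prominence":
        criterion = sps.peak_prominences(curve.values, candidates)[0]
    elif config.threshold_mode == "height":
        criterion = curve.values[candidates]
    else:
        raise ValueError(f"unknown threshold mode {config.threshold_mode!r}")
    keep = candidates[criterion >= threshold]
    return PeakSet(keep, curve.values[keep], threshold)


def upper_envelope(curve: TimeCurve, peaks: PeakSet) -> Envelope:
    """Linear interpolation between consecutive peak values; constant
    extension of the nearest peak before the first and after the last."""
    if len(peaks) == 0:
        raise ValueError("cannot build an envelope from an empty peak set")
    frames = np.arange(len(curve.values))
    values = np.interp(frames, peaks.indices, peaks.values)
    return Envelope(values, peaks.indices)
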