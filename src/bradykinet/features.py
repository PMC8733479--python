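"""The four bradykinesia features and the end-to-end extraction chain.

From a kinematic time curve the chain runs: amplitude normalization (distance
tasks) -> calibration-segment excision -> magnitude spectrum -> adaptive
cutoff -> zero-phase Butterworth -> peak detection with amplitude correction
-> upper envelope -> features:

* ``amplitude_mean`` / ``amplitude_std`` — mean and population SD of the
  detected peak values (normalized units, or degrees for rotation),
* ``speed`` — peaks per second over the analyzed segment,
* ``fatigue`` — max minus min of the upper envelope (the literal decrement
  measure, always >= 0); a signed companion ``fatigue_signed`` (mean of the
  envelope's first third minus its last third) is reported alongside.

A curve with no surviving peaks yields NaN features, never zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import signal_processing as sp
from .kinematics import DEFAULT_CALIBRATION_FRAMES, normalize_curve
from .types import Envelope, PeakSet, TaskFeatures, TimeCurve

__all__ = [
    "ExtractionConfig",
    "amplitude_stats",
    "speed",
    "fatigue",
    "fatigue_signed",
    "extract_features",
    "BradykinesiaFeatureExtractor",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Configuration of the full curve -> features chain."""

    signal: sp.SignalConfig = field(default_factory=sp.SignalConfig)
    calibration_frames: Tuple[int, int] = DEFAULT_CALIBRATION_FRAMES
    #: The corner frequency is capped at this fraction of Nyquist so the
    #: filter design stays well-posed.
    max_cutoff_fraction_of_nyquist: float = 0.95


@dataclass(frozen=True)
class ExtractionArtifacts:
    """Intermediate products of one extraction, kept for audit."""

    analysis_curve: TimeCurve
    filtered_curve: TimeCurve
    spectrum: "sp.SpectrumPeaks"
    cutoff_hz: float
    corner_hz: float
    peaks: PeakSet
    envelope: Optional[Envelope]


def amplitude_stats(peaks: PeakSet) -> Tuple[float, float]:
    """Arithmetic mean and population SD of the peak values.

    The features are descriptors of the observed movement train, not
    estimators of a population parameter, hence the population (ddof=0) SD;
    a single peak has SD exactly 0.
    """
    if len(peaks) == 0:
        raise ValueError("amplitude statistics are undefined for an empty peak set")
    return float(np.mean(peaks.values)), float(np.std(peaks.values))


def speed(peaks: PeakSet, duration_s: float) -> float:
    """Number of peaks per second over the analyzed segment."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(peaks) / duration_s


def fatigue(envelope: Envelope) -> float:
    """Difference between the highest and lowest envelope values (>= 0)."""
    return float(np.max(envelope.values) - np.min(envelope.values))


def fatigue_signed(envelope: Envelope) -> float:
    """Mean of the envelope's first third minus the mean of its last third;
    positive when the movement amplitude decays over the recording."""
    n = len(envelope.values)
    third = max(1, n // 3)
    return float(np.mean(envelope.values[:third]) - np.mean(envelope.values[-third:]))


def _undefined(duration_s: float) -> TaskFeatures:
    nan = float("nan")
    return TaskFeatures(nan, nan, 0.0, nan, nan, n_peaks=0, duration_s=duration_s)


def extract_features(
    curve: TimeCurve,
    task: Optional[str] = None,
    config: Optional[ExtractionConfig] = None,
    return_artifacts: bool = False,
) -> Union[TaskFeatures, Tuple[TaskFeatures, ExtractionArtifacts]]:
    """Run the full chain on one curve and compute the four features.

    The calibration segment (the held maximum-aperture / reference pose) is
    used for normalization and then excised; ``duration_s`` and ``speed``
    refer to the remaining analyzed segment.
    """
    config = config or ExtractionConfig()
    task = task or curve.task
    cal = curve.calibration_frames or config.calibration_frames

    if curve.units == "pixels":
        curve = normalize_curve(curve, cal)

    # Threshold scale for the rotation task comes from the calibration
    # sweep when one exists; it is resolved before the segment is excised.
    # A near-constant calibration pose (its span dwarfed by the movement
    # itself — e.g. jitter around a held reference) is not a sweep, and the
    # threshold then falls back to the observed rotation range.
    degrees_scale = None
    if task == "pronation_supination":
        start, stop = max(0, cal[0]), min(len(curve.values), cal[1])
        if stop > start:
            seg_range = float(np.ptp(curve.values[start:stop]))
            overall = float(np.ptp(curve.values))
            if seg_range > 0.1 * overall:
                degrees_scale = seg_range

    start, stop = cal
    stop = min(stop, len(curve.values))
    analysis_values = curve.values[stop:]
    if len(analysis_values) < 8:
        raise ValueError(
            f"only {len(analysis_values)} frames remain after the calibration "
            f"segment; need at least 8"
        )
    # Rotation sign depends on which hand (and whether the image is
    # mirrored); orient the curve so the dominant excursion is positive.
    if curve.units == "degrees" and abs(float(np.min(analysis_values))) > abs(
        float(np.max(analysis_values))
    ):
        analysis_values = -analysis_values

    analysis = TimeCurve(
        analysis_values,
        fps=curve.fps,
        units=curve.units,
        task=task,
        normalized=curve.normalized,
        calibration_frames=None,
    )
    duration_s = analysis.duration_s

    spectrum = sp.magnitude_spectrum(analysis)
    cutoff = sp.select_cutoff(spectrum, analysis.fps, rule=config.signal.cutoff_rule)
    corner = min(
        config.signal.cutoff_margin * cutoff,
        config.max_cutoff_fraction_of_nyquist * analysis.fps / 2.0,
    )
    filtered = sp.butterworth_lowpass(analysis, corner, order=config.signal.filter_order)

    override = None
    if degrees_scale is not None:
        override = config.signal.thresholds["pronation_supination"] * degrees_scale
    peaks = sp.detect_peaks(filtered, task, config.signal, threshold_override=override)

    if len(peaks) == 0:
        feats = _undefined(duration_s)
        if return_artifacts:
            return feats, ExtractionArtifacts(analysis, filtered, spectrum, cutoff, corner, peaks, None)
        return feats

    envelope = sp.upper_envelope(filtered, peaks)
    amp_mean, amp_std = amplitude_stats(peaks)
    feats = TaskFeatures(
        amplitude_mean=amp_mean,
        amplitude_std=amp_std,
        speed=speed(peaks, duration_s),
        fatigue=fatigue(envelope),
        fatigue_signed=fatigue_signed(envelope),
        n_peaks=len(peaks),
        duration_s=duration_s,
    )
    if return_artifacts:
        return feats, ExtractionArtifacts(analysis, filtered, spectrum, cutoff, corner, peaks, envelope)
    return feats


FEATURE_NAMES = ("amplitude_mean", "amplitude_std", "speed", "fatigue")


class BradykinesiaFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: kinematic time curves in, feature table out.

    ``transform`` accepts a sequence of :class:`~bradykinet.types.TimeCurve`
    (each carrying its task and calibration interval) and returns a pandas
    DataFrame with one row per curve and the four bradykinesia features plus
    ``fatigue_signed``, ``n_peaks`` and ``duration_s``. Stateless at fit time;
    ``fit`` only validates parameters, per the transformer contract.

    Parameters mirror :class:`ExtractionConfig` as flat scalars so the
    estimator composes with sklearn model selection.
    """

    def __init__(
        self,
        filter_order: int = 4,
        cutoff_margin: float = 2.0,
        cutoff_rule: str = "max_magnitude",
        threshold_mode: str = "prominence",
        tap_threshold: float = 0.1,
        grasp_threshold: float = 0.25,
        rotation_threshold: float = 0.25,
        calibration_frames: Tuple[int, int] = DEFAULT_CALIBRATION_FRAMES,
    ) -> None:
        self.filter_order = filter_order
        self.cutoff_margin = cutoff_margin
        self.cutoff_rule = cutoff_rule
        self.threshold_mode = threshold_mode
        self.tap_threshold = tap_threshold
        self.grasp_threshold = grasp_threshold
        self.rotation_threshold = rotation_threshold
        self.calibration_frames = calibration_frames

    def _config(self) -> ExtractionConfig:
        return ExtractionConfig(
            signal=sp.SignalConfig(
                filter_order=self.filter_order,
                cutoff_margin=self.cutoff_margin,
                cutoff_rule=self.cutoff_rule,
                threshold_mode=self.threshold_mode,
                thresholds={
                    "finger_tapping": self.tap_threshold,
                    "hand_grasp": self.grasp_threshold,
                    "pronation_supination": self.rotation_threshold,
                },
            ),
            calibration_frames=tuple(self.calibration_frames),
        )

    def fit(self, X: Sequence[TimeCurve], y=None) -> "BradykinesiaFeatureExtractor":
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.cutoff_margin <= 0:
            raise ValueError("cutoff_margin must be positive")
        for name in ("tap_threshold", "grasp_threshold", "rotation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.config_ = self._config()
        self.n_curves_seen_ = len(X) if X is not None else 0
        return self

    def transform(self, X: Iterable[TimeCurve]) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            raise RuntimeError("BradykinesiaFeatureExtractor is not fitted; call fit first")
        rows: List[dict] = []
        for curve in X:
            feats = extract_features(curve, config=self.config_)
            row = {"task": curve.task, **feats.as_dict()}
            rows.append(row)
        return pd.DataFrame(rows)
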