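"""Domain types shared across the pipeline.

The hand model is the canonical 21-keypoint skeleton: wrist at index 0, then
four joints per finger (thumb 1-4, index 5-8, middle 9-12, ring 13-16,
pinky 17-20), fingertips at 4/8/12/16/20. Every keypoint carries pixel
coordinates plus a detector confidence in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Tuple

import numpy as np

__all__ = [
    "WRIST",
    "THUMB_TIP",
    "INDEX_TIP",
    "MIDDLE_TIP",
    "RING_TIP",
    "PINKY_TIP",
    "N_KEYPOINTS",
    "TASKS",
    "Task",
    "Condition",
    "Side",
    "Group",
    "DetectionRecord",
    "HandLandmarkFrame",
    "RecordingMeta",
    "TimeCurve",
    "SpectrumPeaks",
    "PeakSet",
    "Envelope",
    "TaskFeatures",
]

WRIST = 0
THUMB_TIP = 4
INDEX_TIP = 8
MIDDLE_TIP = 12
RING_TIP = 16
PINKY_TIP = 20
FINGERTIPS_NO_THUMB = (INDEX_TIP, MIDDLE_TIP, RING_TIP, PINKY_TIP)
N_KEYPOINTS = 21

Task = Literal["finger_tapping", "hand_grasp", "pronation_supination"]
TASKS: Tuple[str, ...] = ("finger_tapping", "hand_grasp", "pronation_supination")
Condition = Literal["unilateral", "bilateral"]
Side = Literal["left", "right"]
Group = Literal["PD", "HS"]


@dataclass(frozen=True)
class DetectionRecord:
    """A single hand-detector bounding box for one frame."""

    frame_index: int
    box: Tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    probability: float
    side: str = "unassigned"

    def __post_init__(self) -> None:
        x_min, y_min, x_max, y_max = self.box
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (x_min < x_max and y_min < y_max):
            raise ValueError(f"degenerate box {self.box} at frame {self.frame_index}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"probability {self.probability} outside [0, 1] at frame {self.frame_index}"
            )
        if self.side not in ("left", "right", "unassigned"):
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def center(self) -> Tuple[float, float]:
        x_min, y_min, x_max, y_max = self.box
        return (0.5 * (x_min + x_max), 0.5 * (y_min + y_max))


@dataclass(frozen=True)
class HandLandmarkFrame:
    """One frame's 21 keypoints for one hand: array of shape (21, 3) = (x, y, conf)."""

    frame_index: int
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValueError(
                f"frame {self.frame_index}: expected {N_KEYPOINTS} keypoints with "
                f"(x, y, confidence), got array of shape {kp.shape}"
            )
        if not np.all(np.isfinite(kp[:, :2])):
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")
        conf = kp[:, 2]
        if np.any(conf < 0.0) or np.any(conf > 1.0):
            raise ValueError(f"frame {self.frame_index}: confidence outside [0, 1]")
        object.__setattr__(self, "keypoints", kp)

    @property
    def xy(self) -> np.ndarray:
        """(21, 2) pixel coordinates."""
        return self.keypoints[:, :2]


@dataclass(frozen=True)
class RecordingMeta:
    """Per-recording metadata: who, which task, how it was captured."""

    subject_id: str
    group: str  # PD | HS
    task: str
    condition: str  # unilateral | bilateral
    hand: str  # left | right
    fps: float = 30.0
    frame_size: Tuple[int, int] = (640, 426)
    max_duration_s: float = 12.0
    calibration_frames: Tuple[int, int] = (0, 15)  # half-open [start, stop)
    most_affected_side: str = "none"  # left | right | none (HS)
    dominant_side: str = "right"

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HS"):
            raise ValueError(f"group must be PD or HS, got {self.group!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.condition not in ("unilateral", "bilateral"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.hand not in ("left", "right"):
            raise ValueError(f"unknown hand {self.hand!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        start, stop = self.calibration_frames
        if not (0 <= start < stop):
            raise ValueError(f"empty or invalid calibration interval {self.calibration_frames}")
        if self.most_affected_side not in ("left", "right", "none"):
            raise ValueError(f"bad most_affected_side {self.most_affected_side!r}")
        if self.group == "HS" and self.most_affected_side != "none":
            raise ValueError("healthy subjects have no most-affected side")


@dataclass(frozen=True)
class TimeCurve:
    """A per-frame scalar kinematic signal.

    ``units`` is ``pixels`` for raw distance curves, ``normalized_distance``
    after amplitude normalization, or ``degrees`` for rotation curves (which
    are scale-free and never normalized).
    """

    values: np.ndarray
    fps: float
    units: str  # pixels | normalized_distance | degrees
    task: str
    normalized: bool = False
    calibration_frames: Optional[Tuple[int, int]] = None

    _NORM_TOL = 0.05  # normalized curves may overshoot 1 by this much

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("curve values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve contains non-finite values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.units not in ("pixels", "normalized_distance", "degrees"):
            raise ValueError(f"unknown units {self.units!r}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps

    def with_values(self, values: np.ndarray, **changes) -> "TimeCurve":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass(frozen=True)
class SpectrumPeaks:
    """Spectral peaks of a curve: local maxima of the one-sided magnitude
    spectrum of the mean-removed signal, DC excluded."""

    frequencies: np.ndarray  # Hz, strictly increasing, > 0
    magnitudes: np.ndarray
    resolution: float  # Hz per bin

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequencies and magnitudes must be matching 1-D arrays")
        if len(f) and (np.any(f <= 0) or np.any(np.diff(f) <= 0)):
            raise ValueError("peak frequencies must be positive and strictly increasing")
        if np.any(m < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", m)

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class PeakSet:
    """Movement peaks detected on a filtered curve."""

    indices: np.ndarray  # frame indices, strictly increasing
    values: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        val = np.asarray(self.values, dtype=float)
        if idx.shape != val.shape or idx.ndim != 1:
            raise ValueError("indices and values must be matching 1-D arrays")
        if len(idx) and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class Envelope:
    """Upper envelope: linear interpolation through the peak values, constant
    extension before the first and after the last peak."""

    values: np.ndarray
    anchor_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "anchor_indices", np.asarray(self.anchor_indices, dtype=int))


@dataclass(frozen=True)
class TaskFeatures:
    """The four bradykinesia features for one hand/task/condition.

    Undefined features (no detected peaks) are NaN, never 0 — a zero would
    mimic extreme bradykinesia.
    """

    amplitude_mean: float
    amplitude_std: float
    speed: float
    fatigue: float
    fatigue_signed: float
    n_peaks: int
    duration_s: float

    @property
    def defined(self) -> bool:
        return self.n_peaks > 0 and np.isfinite(self.amplitude_mean)

    def as_dict(self) -> dict:
        return {
            "amplitude_mean": self.amplitude_mean,
            "amplitude_std": self.amplitude_std,
            "speed": self.speed,
            "fatigue": self.fatigue,
            "fatigue_signed": self.fatigue_signed,
            "n_peaks": self.n_peaks,
            "duration_s": self.duration_s,
        }
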