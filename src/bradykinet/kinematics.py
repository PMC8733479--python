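"""Task-specific kinematic time curves from landmark streams.

Each MDS-UPDRS-III upper-limb bradykinesia task maps to one scalar signal:

* finger tapping      -> thumb-tip to index-tip Euclidean distance (pixels)
* hand grasp          -> wrist to mean(non-thumb fingertips) distance (pixels)
* pronation-supination -> polar angle of the (pinky tip - thumb tip) vector,
  unwrapped and referenced to the calibration pose (degrees)

Distance curves are later normalized by the maximum aperture held during the
calibration frames, which cancels camera distance and hand size; angle curves
are already scale-free and never normalized.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np

from .types import (
    FINGERTIPS_NO_THUMB,
    HandLandmarkFrame,
    INDEX_TIP,
    PINKY_TIP,
    THUMB_TIP,
    TimeCurve,
    WRIST,
)

__all__ = [
    "finger_tap_curve",
    "hand_grasp_curve",
    "pronation_supination_curve",
    "normalize_curve",
    "curve_for_task",
    "DEFAULT_CALIBRATION_FRAMES",
    "MAX_GAP_FRAMES",
]

#: Default calibration segment: first 15 frames (0.5 s at 30 fps).
DEFAULT_CALIBRATION_FRAMES: Tuple[int, int] = (0, 15)

#: Dropout gaps strictly shorter than this many frames are linearly
#: interpolated when the curve is built; longer gaps abort with an error.
MAX_GAP_FRAMES = 5


def _fill_gaps(frames: Sequence[HandLandmarkFrame], values: np.ndarray) -> np.ndarray:
    """Re-index per-frame values onto the contiguous frame range, linearly
    interpolating short dropouts. Raises on gaps of MAX_GAP_FRAMES or more."""
    indices = np.array([f.frame_index for f in frames])
    if np.any(np.diff(indices) <= 0):
        raise ValueError("frames must be sorted by strictly increasing frame_index")
    gaps = np.diff(indices) - 1
    worst = int(gaps.max()) if len(gaps) else 0
    if worst >= MAX_GAP_FRAMES:
        at = int(indices[int(np.argmax(gaps))])
        raise ValueError(
            f"gap of {worst} missing frames after frame {at} exceeds the "
            f"{MAX_GAP_FRAMES - 1}-frame interpolation limit"
        )
    full = np.arange(indices[0], indices[-1] + 1)
    return np.interp(full, indices, values)


def _require_frames(frames: Sequence[HandLandmarkFrame]) -> None:
    if len(frames) < 2:
        raise ValueError(f"need at least 2 frames, got {len(frames)}")


def finger_tap_curve(frames: Sequence[HandLandmarkFrame], fps: float) -> TimeCurve:
    """Thumb-tip to index-tip distance per frame, in pixels."""
    _require_frames(frames)
    xy = np.stack([f.xy for f in frames])
    d = np.linalg.norm(xy[:, THUMB_TIP] - xy[:, INDEX_TIP], axis=1)
    return TimeCurve(_fill_gaps(frames, d), fps=fps, units="pixels", task="finger_tapping")


def hand_grasp_curve(frames: Sequence[HandLandmarkFrame], fps: float) -> TimeCurve:
    """Wrist to mean non-thumb fingertip distance per frame, in pixels."""
    _require_frames(frames)
    xy = np.stack([f.xy for f in frames])
    tips = xy[:, list(FINGERTIPS_NO_THUMB)].mean(axis=1)
    d = np.linalg.norm(xy[:, WRIST] - tips, axis=1)
    return TimeCurve(_fill_gaps(frames, d), fps=fps, units="pixels", task="hand_grasp")


def _circular_mean(angles_rad: np.ndarray) -> float:
    return math.atan2(np.mean(np.sin(angles_rad)), np.mean(np.cos(angles_rad)))


def pronation_supination_curve(
    frames: Sequence[HandLandmarkFrame],
    fps: float,
    calibration_frames: Tuple[int, int] = DEFAULT_CALIBRATION_FRAMES,
) -> TimeCurve:
    """Rotation angle of the (pinky tip - thumb tip) vector, in degrees,
    unwrapped and referenced to the circular mean angle over the calibration
    segment (so a constant calibration pose reads exactly 0 deg)."""
    _require_frames(frames)
    xy = np.stack([f.xy for f in frames])
    vec = xy[:, PINKY_TIP] - xy[:, THUMB_TIP]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-9):
        at = frames[int(np.argmin(norms))].frame_index
        raise ValueError(f"zero-length pinky-thumb vector at frame {at}")
    theta = np.unwrap(np.arctan2(vec[:, 1], vec[:, 0]))
    theta = _fill_gaps(frames, theta)

    start, stop = calibration_frames
    first = frames[0].frame_index
    lo, hi = max(0, start - first), max(0, stop - first)
    if hi <= lo or lo >= len(theta):
        raise ValueError(f"calibration interval {calibration_frames} outside recording")
    ref = _circular_mean(theta[lo:hi])
    # shift the wrapped circular mean onto the unwrapped branch of the segment
    branch = np.mean(theta[lo:hi])
    ref += round((branch - ref) / (2 * math.pi)) * 2 * math.pi
    degrees = np.degrees(theta - ref)
    return TimeCurve(
        degrees,
        fps=fps,
        units="degrees",
        task="pronation_supination",
        calibration_frames=calibration_frames,
    )


def normalize_curve(
    curve: TimeCurve,
    calibration_frames: Optional[Tuple[int, int]] = None,
) -> TimeCurve:
    """Divide a pixel-distance curve by its maximum over the calibration
    segment (the deliberate maximum-aperture pose).

    Falls back to the global maximum when the calibration maximum is
    negligible (< 1e-6 of the global max). Degree curves are scale-free and
    are rejected; an all-zero curve is an error.
    """
    if curve.units == "degrees":
        raise ValueError("degree curves are scale-free and are not normalized")
    if curve.normalized:
        return curve
    if calibration_frames is None:
        calibration_frames = curve.calibration_frames or DEFAULT_CALIBRATION_FRAMES
    v = curve.values
    global_max = float(np.max(v))
    if global_max <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    start, stop = calibration_frames
    start, stop = max(0, start), min(len(v), stop)
    if stop <= start:
        raise ValueError(f"calibration interval {calibration_frames} outside curve")
    denom = float(np.max(v[start:stop]))
    if denom < 1e-6 * global_max:
        denom = global_max
    return curve.with_values(
        v / denom,
        units="normalized_distance",
        normalized=True,
        calibration_frames=(start, stop),
    )


def curve_for_task(
    frames: Sequence[HandLandmarkFrame],
    task: str,
    fps: float,
    calibration_frames: Tuple[int, int] = DEFAULT_CALIBRATION_FRAMES,
) -> TimeCurve:
    """Dispatch to the task's curve constructor (raw units; no normalization)."""
    if task == "finger_tapping":
        curve = finger_tap_curve(frames, fps)
    elif task == "hand_grasp":
        curve = hand_grasp_curve(frames, fps)
    elif task == "pronation_supination":
        return pronation_supination_curve(frames, fps, calibration_frames)
    else:
        raise ValueError(f"unknown task {task!r}")
    return TimeCurve(
        curve.values,
        fps=fps,
        units=curve.units,
        task=task,
        calibration_frames=calibration_frames,
    )
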