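"""Synthetic hand-motion simulator with a parameterized bradykinesia phenotype.

Generates 21-keypoint landmark streams (and optional detector boxes) for the
three upper-limb tasks, so every downstream stage is testable without video.
Each recording starts with a held calibration pose (maximum aperture for the
distance tasks, palm-down for rotation), followed by the task oscillation:

* aperture/extension follows a raised-cosine pulse ``sin^2(pi * phase)`` —
  exactly one movement peak per cycle and a single spectral line at the
  cadence, which keeps the closed forms for peak count and peak amplitude
  exact through the filtering stage;
* amplitude decays linearly, ``A(t) = A0 * max(0, 1 - d t)`` (decrement);
* hesitations freeze the pose for a fixed length with a per-cycle
  probability;
* Gaussian pixel jitter is added to every keypoint.

The parkinsonian phenotype is slower cadence, smaller amplitude, stronger
decrement, more hesitations, and a multiplicative worse-side asymmetry; the
bilateral condition degrades the worse side by an extra factor, mirroring
the disproportionate dual-task impairment of PD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    DetectionRecord,
    HandLandmarkFrame,
    RecordingMeta,
    TASKS,
)

__all__ = [
    "MotionSimParams",
    "GroupParams",
    "CohortSpec",
    "SimulatedRecording",
    "SimulatedSubject",
    "Cohort",
    "simulate_track",
    "simulate_subject",
    "simulate_cohort",
    "simulate_detections",
    "HAND_TEMPLATE",
]

# Unit right-hand skeleton, wrist at the origin, middle fingertip at
# distance 1; x toward the thumb, y along the fingers. Only anatomical
# plausibility matters: downstream uses wrist + fingertips.
HAND_TEMPLATE = np.array(
    [
        (0.00, 0.00),  # 0 wrist
        (0.22, 0.12), (0.40, 0.26), (0.54, 0.40), (0.64, 0.52),   # thumb 1-4
        (0.17, 0.48), (0.22, 0.72), (0.25, 0.88), (0.27, 0.98),   # index 5-8
        (0.02, 0.50), (0.02, 0.78), (0.01, 0.93), (0.00, 1.00),   # middle 9-12
        (-0.13, 0.48), (-0.15, 0.73), (-0.16, 0.87), (-0.17, 0.94),  # ring 13-16
        (-0.27, 0.42), (-0.31, 0.60), (-0.33, 0.72), (-0.34, 0.80),  # pinky 17-20
    ]
)

_THUMB_CHAIN = slice(1, 5)
_NON_THUMB = np.arange(5, 21)
_INDEX_TIP = 8
_THUMB_TIP = 4

#: Fraction of the hand span reachable as thumb-index aperture.
_MAX_APERTURE_FRACTION = 0.9
#: Residual wrist-fingertip extension of a fully closed fist.
_CLOSED_FRACTION = 0.1


@dataclass(frozen=True)
class MotionSimParams:
    """Kinematic phenotype of one hand performing one task."""

    cadence_hz: float = 2.5
    base_amplitude: float = 0.85  # fraction of the maximum aperture/rotation
    decrement_rate: float = 0.0  # fraction of A0 lost per second
    hesitation_prob: float = 0.0  # per movement cycle
    hesitation_len_s: float = 0.4
    jitter_px_sd: float = 0.0
    hand_span_px: float = 140.0
    rotation_range_deg: float = 160.0  # full pronation-supination sweep
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be positive")
        if not 0 < self.base_amplitude <= 1:
            raise ValueError("base_amplitude must be in (0, 1]")
        if self.decrement_rate < 0:
            raise ValueError("decrement_rate must be >= 0")
        if not 0 <= self.hesitation_prob < 1:
            raise ValueError("hesitation_prob must be in [0, 1)")
        if self.jitter_px_sd < 0:
            raise ValueError("jitter_px_sd must be >= 0")


def _pulse_series(
    params: MotionSimParams,
    n_frames: int,
    fps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-frame activation in [0, 1]: decrement-scaled raised-cosine pulses
    with hesitation freezes. One peak per completed cycle."""
    out = np.empty(n_frames)
    dt = 1.0 / fps
    phase = 0.0
    hold = 0.0
    for i in range(n_frames):
        t = i * dt
        if hold > 0:
            hold -= dt
        else:
            prev_cycle = math.floor(phase)
            phase += params.cadence_hz * dt
            if math.floor(phase) > prev_cycle and params.hesitation_prob > 0:
                if rng.random() < params.hesitation_prob:
                    hold = params.hesitation_len_s
        decay = max(0.0, 1.0 - params.decrement_rate * t)
        out[i] = params.base_amplitude * decay * math.sin(math.pi * phase) ** 2
    return out


def _assemble_frames(
    positions: np.ndarray,
    jitter_px_sd: float,
    rng: np.random.Generator,
    start_index: int = 0,
) -> List[HandLandmarkFrame]:
    n = positions.shape[0]
    if jitter_px_sd > 0:
        positions = positions + rng.normal(0.0, jitter_px_sd, size=positions.shape)
    conf = np.clip(rng.normal(0.92, 0.03, size=(n, 21, 1)), 0.5, 1.0)
    kps = np.concatenate([positions, conf], axis=2)
    return [HandLandmarkFrame(start_index + i, kps[i]) for i in range(n)]


def _tap_positions(template: np.ndarray, aperture_px: np.ndarray) -> np.ndarray:
    """Translate the thumb chain so the thumb tip sits at the requested
    distance from the (fixed) index tip."""
    n = len(aperture_px)
    pos = np.broadcast_to(template, (n, 21, 2)).copy()
    index_tip = template[_INDEX_TIP]
    direction = template[_THUMB_TIP] - index_tip
    direction = direction / np.linalg.norm(direction)
    target_tip = index_tip[None, :] + aperture_px[:, None] * direction[None, :]
    delta = target_tip - template[_THUMB_TIP]
    pos[:, _THUMB_CHAIN, :] += delta[:, None, :]
    return pos


def _grasp_positions(template: np.ndarray, extension: np.ndarray) -> np.ndarray:
    """Scale the four fingers radially toward the wrist by a common factor."""
    n = len(extension)
    pos = np.broadcast_to(template, (n, 21, 2)).copy()
    wrist = template[0]
    pos[:, _NON_THUMB, :] = wrist + extension[:, None, None] * (
        template[_NON_THUMB] - wrist
    )
    return pos


def _rotate_positions(template: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Rotate the whole skeleton about the wrist."""
    theta = np.radians(angles_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)  # (n, 2, 2)
    rel = template - template[0]
    return template[0] + np.einsum("nij,kj->nki", rot, rel)


def simulate_track(
    params: MotionSimParams,
    task: str,
    fps: float = 30.0,
    duration_s: float = 12.0,
    calibration_s: float = 0.5,
    hand: str = "right",
    origin: Tuple[float, float] = (160.0, 280.0),
    bilateral_factor: float = 1.0,
) -> List[HandLandmarkFrame]:
    """Simulate one recording of one hand. The first ``calibration_s``
    seconds hold the reference pose; the rest is the task oscillation.
    Deterministic under ``params.seed``."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if duration_s <= calibration_s:
        raise ValueError("duration must exceed the calibration segment")
    if hand not in ("left", "right"):
        raise ValueError(f"unknown hand {hand!r}")

    rng = np.random.default_rng(params.seed)
    n_cal = int(round(calibration_s * fps))
    n_motion = int(round(duration_s * fps)) - n_cal

    eff = params
    if bilateral_factor != 1.0:
        eff = replace(
            params,
            cadence_hz=params.cadence_hz * bilateral_factor,
            base_amplitude=min(1.0, params.base_amplitude * bilateral_factor),
        )
    pulse = _pulse_series(eff, n_motion, fps, rng)

    template = HAND_TEMPLATE * params.hand_span_px
    if hand == "left":
        template = template * np.array([-1.0, 1.0])
    template = template + np.asarray(origin)

    if task == "finger_tapping":
        max_aperture = _MAX_APERTURE_FRACTION * params.hand_span_px
        aperture = np.concatenate([np.full(n_cal, max_aperture), max_aperture * pulse])
        positions = _tap_positions(template, aperture)
    elif task == "hand_grasp":
        extension = np.concatenate(
            [np.ones(n_cal), _CLOSED_FRACTION + (1 - _CLOSED_FRACTION) * pulse]
        )
        positions = _grasp_positions(template, extension)
    else:  # pronation_supination: palm-down hold, then rotation pulses
        sign = 1.0 if hand == "right" else -1.0
        angles = np.concatenate(
            [np.zeros(n_cal), sign * params.rotation_range_deg * pulse]
        )
        positions = _rotate_positions(template, angles)

    return _assemble_frames(positions, params.jitter_px_sd, rng)


@dataclass(frozen=True)
class GroupParams:
    """Sampling distributions of MotionSimParams for one subject group.

    Defaults encode the healthy phenotype; :meth:`parkinsonian` returns the
    slowed, smaller, more fatigable, asymmetric variant. These defaults ARE
    the study conditions of the bundled experiments.
    """

    cadence_mean: float = 2.8
    cadence_sd: float = 0.35
    amplitude_mean: float = 0.82
    amplitude_sd: float = 0.07
    decrement_mean: float = 0.005
    decrement_sd: float = 0.004
    hesitation_prob: float = 0.01
    asymmetry_mean: float = 0.97
    asymmetry_sd: float = 0.02
    jitter_px_sd: float = 1.0
    hand_span_mean: float = 140.0
    hand_span_sd: float = 15.0

    @staticmethod
    def healthy() -> "GroupParams":
        return GroupParams()

    @staticmethod
    def parkinsonian() -> "GroupParams":
        return GroupParams(
            cadence_mean=1.9,
            cadence_sd=0.35,
            amplitude_mean=0.60,
            amplitude_sd=0.10,
            decrement_mean=0.030,
            decrement_sd=0.012,
            hesitation_prob=0.08,
            asymmetry_mean=0.75,
            asymmetry_sd=0.08,
        )

    def draw(self, rng: np.random.Generator, seed: int) -> MotionSimParams:
        return MotionSimParams(
            cadence_hz=float(np.clip(rng.normal(self.cadence_mean, self.cadence_sd), 0.5, 6.0)),
            base_amplitude=float(
                np.clip(rng.normal(self.amplitude_mean, self.amplitude_sd), 0.2, 1.0)
            ),
            decrement_rate=float(
                np.clip(rng.normal(self.decrement_mean, self.decrement_sd), 0.0, 0.08)
            ),
            hesitation_prob=self.hesitation_prob,
            jitter_px_sd=self.jitter_px_sd,
            hand_span_px=float(
                np.clip(rng.normal(self.hand_span_mean, self.hand_span_sd), 80.0, 220.0)
            ),
            seed=seed,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout and acquisition settings."""

    n_pd: int = 22
    n_hs: int = 20
    fps: float = 30.0
    duration_s: float = 12.0
    calibration_s: float = 0.5
    frame_size: Tuple[int, int] = (640, 426)
    seed: int = 0
    tasks: Tuple[str, ...] = TASKS
    conditions: Tuple[str, ...] = ("unilateral", "bilateral")
    pd_params: GroupParams = field(default_factory=GroupParams.parkinsonian)
    hs_params: GroupParams = field(default_factory=GroupParams.healthy)
    #: Extra degradation of the worse side in the bilateral condition.
    bilateral_worse_factor: float = 0.85
    #: Probability a subject is right-hand dominant.
    p_right_dominant: float = 0.9

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_hs < 1:
            raise ValueError("need at least one subject per group")
        if self.duration_s <= self.calibration_s:
            raise ValueError("duration must exceed the calibration segment")

    @property
    def calibration_frames(self) -> Tuple[int, int]:
        return (0, int(round(self.calibration_s * self.fps)))


@dataclass(frozen=True)
class SimulatedRecording:
    frames: List[HandLandmarkFrame]
    meta: RecordingMeta
    params: MotionSimParams  # effective per-hand parameters (ground truth)


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    group: str
    worse_side: str  # most-affected (PD) or non-dominant (HS)
    dominant_side: str
    recordings: Dict[Tuple[str, str, str], SimulatedRecording]  # (task, condition, hand)


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    subjects: List[SimulatedSubject]

    def __len__(self) -> int:
        return len(self.subjects)


def _hand_origin(hand: str, frame_size: Tuple[int, int]) -> Tuple[float, float]:
    # mirror convention: the subject's right hand appears in the image's left half
    w, h = frame_size
    x = 0.25 * w if hand == "right" else 0.75 * w
    return (x, 0.55 * h)


def simulate_subject(
    group: str,
    spec: CohortSpec,
    subject_seed: int,
    subject_id: Optional[str] = None,
) -> SimulatedSubject:
    """Draw one subject's phenotype and simulate all requested recordings.

    PD subjects draw slower cadence, smaller amplitude, stronger decrement
    and a worse-side asymmetry factor < 1 (applied multiplicatively to
    cadence and amplitude); the worse side is recorded as the most-affected
    side. HS subjects have near-unit asymmetry with the non-dominant side
    nominally worse.
    """
    if group not in ("PD", "HS"):
        raise ValueError(f"group must be PD or HS, got {group!r}")
    gp = spec.pd_params if group == "PD" else spec.hs_params
    ss = np.random.SeedSequence([spec.seed, subject_seed])
    rng = np.random.default_rng(ss)
    track_seeds = iter(ss.generate_state(4 * len(spec.tasks) * len(spec.conditions) + 8))

    base = gp.draw(rng, seed=0)
    asymmetry = float(np.clip(rng.normal(gp.asymmetry_mean, gp.asymmetry_sd), 0.4, 1.0))
    dominant = "right" if rng.random() < spec.p_right_dominant else "left"
    if group == "PD":
        worse = "left" if rng.random() < 0.5 else "right"
    else:
        worse = "left" if dominant == "right" else "right"
    subject_id = subject_id or f"{group}{subject_seed:03d}"

    recordings: Dict[Tuple[str, str, str], SimulatedRecording] = {}
    for task in spec.tasks:
        for condition in spec.conditions:
            for hand in ("left", "right"):
                params = base
                if hand == worse:
                    params = replace(
                        params,
                        cadence_hz=params.cadence_hz * asymmetry,
                        base_amplitude=params.base_amplitude * asymmetry,
                    )
                params = replace(params, seed=int(next(track_seeds) % (2**31)))
                bf = (
                    spec.bilateral_worse_factor
                    if (condition == "bilateral" and hand == worse)
                    else 1.0
                )
                frames = simulate_track(
                    params,
                    task,
                    fps=spec.fps,
                    duration_s=spec.duration_s,
                    calibration_s=spec.calibration_s,
                    hand=hand,
                    origin=_hand_origin(hand, spec.frame_size),
                    bilateral_factor=bf,
                )
                meta = RecordingMeta(
                    subject_id=subject_id,
                    group=group,
                    task=task,
                    condition=condition,
                    hand=hand,
                    fps=spec.fps,
                    frame_size=spec.frame_size,
                    max_duration_s=spec.duration_s,
                    calibration_frames=spec.calibration_frames,
                    most_affected_side=worse if group == "PD" else "none",
                    dominant_side=dominant,
                )
                recordings[(task, condition, hand)] = SimulatedRecording(frames, meta, params)
    return SimulatedSubject(subject_id, group, worse, dominant, recordings)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full cohort, reproducibly from ``spec.seed``."""
    subjects = [
        simulate_subject("PD", spec, i, subject_id=f"PD{i:03d}") for i in range(spec.n_pd)
    ] + [
        simulate_subject("HS", spec, 1000 + i, subject_id=f"HS{i:03d}")
        for i in range(spec.n_hs)
    ]
    return Cohort(spec, subjects)


def simulate_detections(
    frames: Sequence[HandLandmarkFrame],
    frame_size: Tuple[int, int] = (640, 426),
    seed: int = 0,
    distractor_rate: float = 0.3,
    margin_px: float = 10.0,
) -> List[DetectionRecord]:
    """Detector-style bounding boxes for a landmark stream: one true box per
    frame (keypoint bounding box plus a margin, probability ~0.8-0.99) and
    Poisson-thinned random distractor boxes at lower probability."""
    rng = np.random.default_rng(seed)
    w, h = frame_size
    out: List[DetectionRecord] = []
    for frame in frames:
        xy = frame.xy
        x0, y0 = np.maximum(xy.min(axis=0) - margin_px, 0.0)
        x1 = min(float(xy[:, 0].max() + margin_px), w - 1.0)
        y1 = min(float(xy[:, 1].max() + margin_px), h - 1.0)
        prob = float(np.clip(rng.normal(0.92, 0.04), 0.6, 0.99))
        out.append(DetectionRecord(frame.frame_index, (float(x0), float(y0), x1, y1), prob))
        if rng.random() < distractor_rate:
            dx = rng.uniform(0, w - 60)
            dy = rng.uniform(0, h - 60)
            dw = rng.uniform(30, 60)
            dh = rng.uniform(30, 60)
            dprob = float(rng.uniform(0.05, 0.5))
            out.append(
                DetectionRecord(
                    frame.frame_index, (dx, dy, min(dx + dw, w - 1), min(dy + dh, h - 1)), dprob
                )
            )
    return out
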