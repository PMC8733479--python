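"""Landmark / detection stream I/O and detector post-processing.

Two on-disk dialects are supported for landmark streams:

* ``flat_csv`` — one row per (frame, keypoint):
  ``frame_index,hand,kp_index,x,y,confidence``; header mandatory, UTF-8,
  ``.`` decimal separator. Round-trips bit-compatibly.
* ``openpose_json`` — one JSON file per frame in a directory, with keys
  ``hand_left_keypoints_2d`` / ``hand_right_keypoints_2d`` holding flat
  ``[x1, y1, c1, ...]`` arrays of length 63. The frame index is the last
  integer in the file name (e.g. ``frame_000012.json`` -> 12).

Detector post-processing mirrors the acquisition pipeline: per-frame boxes
are assigned a side, the highest-probability box per needed side is kept,
and a temporal correction carries the previous box forward whenever the
current probability does not exceed it.
"""

from __future__ import annotations

import csv
import json
import re
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .types import DetectionRecord, HandLandmarkFrame, N_KEYPOINTS

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "assign_side",
    "select_boxes",
    "temporal_correct",
]

_CSV_HEADER = ["frame_index", "hand", "kp_index", "x", "y", "confidence"]
_FRAME_INDEX_RE = re.compile(r"(\d+)(?!.*\d)")


class LandmarkParseError(ValueError):
    """Malformed landmark record; the message names the offending frame."""


def _parse_flat_csv(path: Path) -> Dict[str, List[HandLandmarkFrame]]:
    per_hand: Dict[str, Dict[int, np.ndarray]] = defaultdict(dict)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LandmarkParseError(f"{path}: empty file, expected header {_CSV_HEADER}")
        if header != _CSV_HEADER:
            raise LandmarkParseError(f"{path}: bad header {header}, expected {_CSV_HEADER}")
        rows: Dict[str, Dict[int, Dict[int, tuple]]] = defaultdict(lambda: defaultdict(dict))
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                frame = int(row[0])
                hand = row[1]
                kp = int(row[2])
                x, y, c = float(row[3]), float(row[4]), float(row[5])
            except (ValueError, IndexError) as exc:
                raise LandmarkParseError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if hand not in ("left", "right"):
                raise LandmarkParseError(f"{path}:{lineno}: unknown hand {hand!r}")
            if not 0 <= kp < N_KEYPOINTS:
                raise LandmarkParseError(
                    f"{path}:{lineno}: keypoint index {kp} outside 0..{N_KEYPOINTS - 1} "
                    f"(frame {frame})"
                )
            rows[hand][frame][kp] = (x, y, c)
    for hand, frames in rows.items():
        for frame, kps in frames.items():
            if len(kps) != N_KEYPOINTS:
                raise LandmarkParseError(
                    f"{path}: frame {frame} hand {hand} has {len(kps)} keypoints, "
                    f"expected {N_KEYPOINTS}"
                )
            arr = np.array([kps[i] for i in range(N_KEYPOINTS)], dtype=float)
            per_hand[hand][frame] = arr
    return {
        hand: [HandLandmarkFrame(idx, frames[idx]) for idx in sorted(frames)]
        for hand, frames in per_hand.items()
    }


def _parse_openpose_json(path: Path) -> Dict[str, List[HandLandmarkFrame]]:
    files = sorted(p for p in path.iterdir() if p.suffix == ".json")
    if not files:
        raise LandmarkParseError(f"{path}: no .json frame files found")
    per_hand: Dict[str, List[HandLandmarkFrame]] = defaultdict(list)
    for order, file in enumerate(files):
        m = _FRAME_INDEX_RE.search(file.stem)
        frame_index = int(m.group(1)) if m else order
        with open(file, encoding="utf-8") as fh:
            record = json.load(fh)
        for key, hand in (
            ("hand_left_keypoints_2d", "left"),
            ("hand_right_keypoints_2d", "right"),
        ):
            flat = record.get(key)
            if flat is None:
                continue
            if len(flat) != 3 * N_KEYPOINTS:
                raise LandmarkParseError(
                    f"{file}: frame {frame_index} key {key} has {len(flat) // 3} "
                    f"keypoints, expected {N_KEYPOINTS}"
                )
            arr = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
            per_hand[hand].append(HandLandmarkFrame(frame_index, arr))
    return {hand: sorted(frames, key=lambda f: f.frame_index) for hand, frames in per_hand.items()}


def read_landmarks(path, dialect: str = "flat_csv") -> Dict[str, List[HandLandmarkFrame]]:
    """Read a landmark stream; returns ``{hand: [HandLandmarkFrame, ...]}``
    with frames sorted by frame index. Missing frames remain gaps — they are
    interpolated only later, at curve-construction time."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "flat_csv":
        return _parse_flat_csv(path)
    if dialect == "openpose_json":
        return _parse_openpose_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _repr_float(x: float) -> str:
    # repr round-trips doubles exactly, giving bit-compatible CSV round trips
    return repr(float(x))


def write_landmarks(
    frames: Mapping[str, Sequence[HandLandmarkFrame]] | Sequence[HandLandmarkFrame],
    path,
    dialect: str = "flat_csv",
) -> None:
    """Write a landmark stream. ``frames`` is ``{hand: frames}`` or a bare
    sequence (written as the right hand). Frame validation happens in the
    HandLandmarkFrame constructor, so non-finite coordinates never reach disk.
    """
    if not isinstance(frames, Mapping):
        frames = {"right": list(frames)}
    for hand, seq in frames.items():
        for f in seq:
            if not isinstance(f, HandLandmarkFrame):
                raise TypeError(f"hand {hand}: expected HandLandmarkFrame, got {type(f)}")
    path = Path(path)
    if dialect == "flat_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for hand in sorted(frames):
                for frame in frames[hand]:
                    for kp in range(N_KEYPOINTS):
                        x, y, c = frame.keypoints[kp]
                        writer.writerow(
                            [frame.frame_index, hand, kp, _repr_float(x), _repr_float(y), _repr_float(c)]
                        )
    elif dialect == "openpose_json":
        path.mkdir(parents=True, exist_ok=True)
        all_indices = sorted({f.frame_index for seq in frames.values() for f in seq})
        by_hand = {h: {f.frame_index: f for f in seq} for h, seq in frames.items()}
        for idx in all_indices:
            record = {"version": 1.3, "people": []}
            for hand in ("left", "right"):
                frame = by_hand.get(hand, {}).get(idx)
                if frame is not None:
                    record[f"hand_{hand}_keypoints_2d"] = [
                        float(v) for v in frame.keypoints.ravel()
                    ]
            with open(path / f"frame_{idx:06d}.json", "w", encoding="utf-8") as fh:
                json.dump(record, fh, sort_keys=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def assign_side(box: DetectionRecord, frame_width: float, mirror: bool = True) -> str:
    """Attribute a subject side to a box from its horizontal position.

    With the default mirror convention (subject faces the camera), a box whose
    center lies in the image's left half (including exactly at width/2) is the
    subject's *right* hand. ``mirror=False`` flips this for non-mirrored setups.
    """
    cx = box.center[0]
    left_half = cx <= frame_width / 2.0
    if mirror:
        return "right" if left_half else "left"
    return "left" if left_half else "right"


def select_boxes(
    detections: Iterable[DetectionRecord],
    condition: str,
    required_side: Optional[str] = None,
    frame_width: float = 640.0,
    mirror: bool = True,
) -> Dict[str, List[Optional[DetectionRecord]]]:
    """Keep the highest-probability box per needed side per frame.

    Unassigned boxes get a side from their position first. Returns
    ``{side: [box or None per frame]}`` over the contiguous frame range;
    ``None`` marks a frame with no detection on that side (a gap left for
    temporal correction to fill).
    """
    detections = list(detections)
    if not detections:
        raise ValueError("empty detection stream")
    if condition == "unilateral":
        if required_side not in ("left", "right"):
            raise ValueError("unilateral selection requires a side")
        sides = [required_side]
    elif condition == "bilateral":
        sides = ["left", "right"]
    else:
        raise ValueError(f"unknown condition {condition!r}")

    per_frame: Dict[int, List[DetectionRecord]] = defaultdict(list)
    for det in detections:
        side = det.side
        if side == "unassigned":
            side = assign_side(det, frame_width, mirror=mirror)
            det = DetectionRecord(det.frame_index, det.box, det.probability, side)
        per_frame[det.frame_index].append(det)

    first, last = min(per_frame), max(per_frame)
    out: Dict[str, List[Optional[DetectionRecord]]] = {s: [] for s in sides}
    for frame in range(first, last + 1):
        candidates = per_frame.get(frame, [])
        for side in sides:
            on_side = [d for d in candidates if d.side == side]
            out[side].append(max(on_side, key=lambda d: d.probability) if on_side else None)
    return out


def temporal_correct(
    track: Sequence[Optional[DetectionRecord]],
    carry_probability: bool = True,
) -> List[Optional[DetectionRecord]]:
    """Carry the previous box forward when the current probability does not
    exceed it.

    If ``p(t) <= p(t-1)`` the previous box is kept. By default the carried
    probability is the previous frame's (a long plateau keeps substituting);
    with ``carry_probability=False`` the box is kept but the current frame's
    probability is recorded. Gaps (``None``) always inherit the previous box.
    The first frame is never changed. Idempotent.
    """
    track = list(track)
    if not track:
        return []
    out: List[Optional[DetectionRecord]] = [track[0]]
    for t in range(1, len(track)):
        prev, cur = out[-1], track[t]
        if prev is None:
            out.append(cur)
        elif cur is None or cur.probability <= prev.probability:
            prob = prev.probability if (carry_probability or cur is None) else cur.probability
            frame_index = cur.frame_index if cur is not None else prev.frame_index + 1
            out.append(DetectionRecord(frame_index, prev.box, prob, prev.side))
        else:
            out.append(cur)
    return out
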