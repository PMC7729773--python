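"""Reading and writing 2D skeleton keypoint streams.

Consumes the OpenPose BODY_25 JSON dialect — one file per frame with a
top-level ``people`` list whose entries carry ``pose_keypoints_2d`` as a
flat list of 75 numbers (x0, y0, c0, ..., x24, y24, c24) — plus an
internal CSV fixture format used for tests and round-tripping.

Coordinates are image coordinates throughout the package: origin at the
top-left corner, x rightward, y *downward*, in pixels.  An undetected
keypoint is encoded as (0, 0, 0).

The downstream posture features only use the main torso, so a frame is
*valid* when the neck, mid-hip, both hips, knees and ankles are all
detected with adequate confidence and the waist has nonzero pixel width
(the waist width is a denominator in the spine-ratio feature).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

N_KEYPOINTS = 25

# BODY_25 indices used by the main-torso features.
NOSE = 0
NECK = 1
MID_HIP = 8
HIP_L, KNEE_L, ANKLE_L = 9, 10, 11
HIP_R, KNEE_R, ANKLE_R = 12, 13, 14

#: Keypoints that must be detected for a frame to be usable.
REQUIRED_IDS = frozenset({NECK, MID_HIP, HIP_L, KNEE_L, ANKLE_L, HIP_R, KNEE_R, ANKLE_R})

#: Lower-limb keypoints entering the energy value (knees and ankles).
LOWER_LIMB_IDS = (KNEE_L, ANKLE_L, KNEE_R, ANKLE_R)

DEFAULT_MIN_CONFIDENCE = 0.1
DEFAULT_MIN_WAIST_PX = 1.0

CSV_COLUMNS = ["frame", "person", "kp", "x", "y", "conf"]


class OpenPoseFormatError(ValueError):
    """Raised when a keypoint file does not conform to the BODY_25 dialect."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One person's 25 BODY_25 keypoints at one frame index.

    ``keypoints`` is a float array of shape (25, 3): columns are x, y
    (pixels) and confidence in [0, 1].
    """

    frame_index: int
    person_id: int
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValueError(
                f"keypoints must have shape ({N_KEYPOINTS}, 3), got {kp.shape}"
            )
        object.__setattr__(self, "keypoints", kp)

    def xy(self, kp_id: int) -> np.ndarray:
        """(x, y) of one keypoint."""
        return self.keypoints[kp_id, :2]

    def confidence(self, kp_id: int) -> float:
        return float(self.keypoints[kp_id, 2])

    def is_detected(self, kp_id: int) -> bool:
        return self.confidence(kp_id) > 0.0


@dataclass(frozen=True)
class ValidityFlag:
    """Outcome of the frame-validity rules."""

    valid: bool
    missing_ids: frozenset = field(default_factory=frozenset)


def validate_frame(
    frame: SkeletonFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_waist_px: float = DEFAULT_MIN_WAIST_PX,
) -> ValidityFlag:
    """Check that every required torso keypoint is confidently detected.

    A frame passes when all of ``REQUIRED_IDS`` have confidence >=
    ``min_confidence`` and the waist width (hip 9 to hip 12 distance) is
    at least ``min_waist_px`` pixels.  ``missing_ids`` lists every
    required keypoint that failed the confidence test.
    """
    missing = frozenset(
        kp for kp in REQUIRED_IDS if frame.confidence(kp) < min_confidence
    )
    if missing:
        return ValidityFlag(False, missing)
    waist = float(np.linalg.norm(frame.xy(HIP_L) - frame.xy(HIP_R)))
    if waist < min_waist_px:
        return ValidityFlag(False, frozenset())
    return ValidityFlag(True, frozenset())


def select_subject(
    persons: Sequence[SkeletonFrame],
    previous_midhip: Optional[tuple[float, float]] = None,
) -> Optional[SkeletonFrame]:
    """Pick the tracked subject among the people detected in one frame.

    With no prior position the person with the highest mean confidence
    over the required torso keypoints wins; otherwise the person whose
    mid-hip is nearest (Euclidean) to ``previous_midhip``.  Ties break to
    the lowest person index.  Returns ``None`` for an empty list.
    """
    if not persons:
        return None
    if previous_midhip is None:
        req = sorted(REQUIRED_IDS)

        def score(p: SkeletonFrame) -> float:
            return -float(np.mean(p.keypoints[req, 2]))

    else:
        prev = np.asarray(previous_midhip, dtype=float)

        def score(p: SkeletonFrame) -> float:
            return float(np.linalg.norm(p.xy(MID_HIP) - prev))

    best_i = min(range(len(persons)), key=lambda i: (score(persons[i]), i))
    return persons[best_i]


# ---------------------------------------------------------------------------
# OpenPose BODY_25 JSON dialect
# ---------------------------------------------------------------------------

_FRAME_DIGITS = re.compile(r"(\d+)")


def _frame_index_from_name(path: Path, fallback: int) -> int:
    """OpenPose writes e.g. ``clip_000000000042_keypoints.json``; take the
    longest digit run in the stem as the frame index."""
    runs = _FRAME_DIGITS.findall(path.stem)
    if not runs:
        return fallback
    longest = max(runs, key=len)
    return int(longest)

def _parse_people(obj: dict, frame_index: int, where: str) -> list[SkeletonFrame]:
    people = obj.get("people")
    if people is None or not isinstance(people, list):
        raise OpenPoseFormatError(f"{where}: missing 'people' list")
    persons = []
    for pid, person in enumerate(people):
        flat = person.get("pose_keypoints_2d")
        if flat is None:
            raise OpenPoseFormatError(
                f"{where}, person {pid}: missing 'pose_keypoints_2d'"
            )
        if len(flat) != 3 * N_KEYPOINTS:
            raise OpenPoseFormatError(
                f"{where}, person {pid}: expected {3 * N_KEYPOINTS} numbers in "
                f"'pose_keypoints_2d', got {len(flat)}"
            )
        kp = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
        persons.append(SkeletonFrame(frame_index, pid, kp))
    return persons


def read_openpose_frames(
    source: Union[str, Path, IO[str]],
) -> list[tuple[int, list[SkeletonFrame]]]:
    """Read an OpenPose BODY_25 keypoint stream.

    ``source`` may be a directory of per-frame ``*.json`` files (the
    usual OpenPose layout; frame indices come from the file names), a
    single JSON file holding either one frame object or a list of frame
    objects (each optionally carrying ``frame_index``), or an open text
    stream with the same content.

    Returns frames in index order as ``(frame_index, persons)`` pairs; a
    frame whose ``people`` list is empty yields an empty persons list
    rather than an error.
    """
    if hasattr(source, "read"):
        return _read_openpose_stream(source, where="<stream>")
    path = Path(source)
    if path.is_dir():
        out = []
        files = sorted(path.glob("*keypoints*.json")) or sorted(path.glob("*.json"))
        if not files:
            raise FileNotFoundError(f"no .json keypoint files under {path}")
        for i, f in enumerate(files):
            try:
                with open(f, "r") as fh:
                    obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise OpenPoseFormatError(f"{f.name}: malformed JSON: {exc}") from exc
            idx = _frame_index_from_name(f, fallback=i)
            out.append((idx, _parse_people(obj, idx, where=f.name)))
        out.sort(key=lambda t: t[0])
        return out
    with open(path, "r") as fh:
        return _read_openpose_stream(fh, where=path.name)


def _read_openpose_stream(fh: IO[str], where: str) -> list[tuple[int, list[SkeletonFrame]]]:
    try:
        obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise OpenPoseFormatError(f"{where}: malformed JSON: {exc}") from exc
    if isinstance(obj, dict):
        obj = [obj]
    out = []
    for i, frame_obj in enumerate(obj):
        idx = int(frame_obj.get("frame_index", i))
        out.append((idx, _parse_people(frame_obj, idx, where=f"{where}[{i}]")))
    out.sort(key=lambda t: t[0])
    return out


def write_openpose_frame(path: Union[str, Path], persons: Sequence[SkeletonFrame]) -> None:
    """Write one frame in the OpenPose BODY_25 JSON dialect."""
    obj = {
        "version": 1.3,
        "people": [
            {"person_id": [p.person_id], "pose_keypoints_2d": p.keypoints.ravel().tolist()}
            for p in persons
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


# ---------------------------------------------------------------------------
# Internal CSV fixture format
# ---------------------------------------------------------------------------

def write_csv_frames(
    path: Union[str, Path], frames: Iterable[tuple[int, Sequence[SkeletonFrame]]]
) -> None:
    """Write a keypoint stream as the internal CSV fixture format.

    One row per keypoint, header ``frame,person,kp,x,y,conf``.  Floats
    are written with ``repr`` precision so coordinates round-trip
    bit-exactly.
    """
    rows = []
    for frame_index, persons in frames:
        for p in persons:
            for k in range(N_KEYPOINTS):
                x, y, c = (float(v) for v in p.keypoints[k])
                rows.append((frame_index, p.person_id, k, repr(x), repr(y), repr(c)))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_csv_frames(path: Union[str, Path]) -> list[tuple[int, list[SkeletonFrame]]]:
    """Read the internal CSV fixture format (inverse of write_csv_frames)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CSV columns {sorted(missing)}")
    out: list[tuple[int, list[SkeletonFrame]]] = []
    for frame_index, frame_df in df.groupby("frame", sort=True):
        persons = []
        for person_id, pdf in frame_df.groupby("person", sort=True):
            if len(pdf) != N_KEYPOINTS:
                raise ValueError(
                    f"{path}: frame {frame_index} person {person_id} has "
                    f"{len(pdf)} keypoint rows, expected {N_KEYPOINTS}"
                )
            kp = np.zeros((N_KEYPOINTS, 3))
            pdf = pdf.sort_values("kp")
            kp[pdf["kp"].to_numpy(), 0] = pdf["x"].to_numpy()
            kp[pdf["kp"].to_numpy(), 1] = pdf["y"].to_numpy()
            kp[pdf["kp"].to_numpy(), 2] = pdf["conf"].to_numpy()
            persons.append(SkeletonFrame(int(frame_index), int(person_id), kp))
        out.append((int(frame_index), persons))
    return out
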