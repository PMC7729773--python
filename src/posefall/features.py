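"""Per-frame posture features: deflection angles, spine ratio, torso length.

Six posture vectors are formed from the main-torso keypoints:

* spine (neck 1 -> mid-hip 8)
* left thigh (hip 9 -> knee 10), right thigh (hip 12 -> knee 13)
* left calf (knee 10 -> ankle 11), right calf (knee 13 -> ankle 14)
* waist width (hip 9 -> hip 12)

A segment vector (a -> b) is (X_a - X_b, Y_a - Y_b), i.e. it points from
the distal joint toward the proximal one; for an upright body it points
up-image.  The *deflection angle* of a segment is the angle in [0, 180]
degrees between its vector and the up-image vertical (0, -1), which
serves as the gravity reference: an upright torso scores ~0 deg, a body
lying on the floor ~90 deg.  The *spine ratio* |spine| / |waist| is a
foreshortening cue: it collapses below 1 when the body pitches toward or
away from a monocular camera, a geometry where the deflection angles
barely move.  The torso length H = |neck - mid-hip| normalises the
temporal-detector features against apparent body size.

All features are invariant to translating the skeleton, and all but H
are invariant to uniform rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .io import (
    ANKLE_L,
    ANKLE_R,
    DEFAULT_MIN_WAIST_PX,
    HIP_L,
    HIP_R,
    KNEE_L,
    KNEE_R,
    MID_HIP,
    NECK,
    SkeletonFrame,
)

#: Up-image vertical used as the gravity reference (y grows downward).
GRAVITY_REFERENCE = np.array([0.0, -1.0])

#: (from_id, to_id) pairs of the named posture vectors.
SEGMENTS = {
    "spine": (NECK, MID_HIP),
    "left_thigh": (HIP_L, KNEE_L),
    "right_thigh": (HIP_R, KNEE_R),
    "left_calf": (KNEE_L, ANKLE_L),
    "right_calf": (KNEE_R, ANKLE_R),
    "waist": (HIP_L, HIP_R),
}


@dataclass(frozen=True)
class KeyFeatures:
    """The five deflection angles (degrees), spine ratio and torso length
    of one valid frame."""

    spine_angle: float
    left_thigh_angle: float
    right_thigh_angle: float
    left_calf_angle: float
    right_calf_angle: float
    spine_ratio: float
    torso_length_h: float

    @property
    def angles(self) -> tuple[float, float, float, float, float]:
        return (
            self.spine_angle,
            self.left_thigh_angle,
            self.right_thigh_angle,
            self.left_calf_angle,
            self.right_calf_angle,
        )


def posture_vector(frame: SkeletonFrame, from_id: int, to_id: int) -> np.ndarray:
    """Segment vector (X_from - X_to, Y_from - Y_to) in pixels.

    Both endpoints must be detected (confidence > 0); the caller is
    expected to have validated the frame.
    """
    for kp in (from_id, to_id):
        if frame.confidence(kp) <= 0.0:
            raise ValueError(
                f"keypoint {kp} undetected in frame {frame.frame_index}; "
                "posture vector undefined"
            )
    return frame.xy(from_id) - frame.xy(to_id)


def deflection_angle(v: Union[np.ndarray, tuple[float, float]]) -> float:
    """Angle in degrees, within [0, 180], between ``v`` and the up-image
    vertical (0, -1).

    Computed from the normalised dot product (cosine law); the argument
    is clipped to [-1, 1] before ``acos`` so that collinear vectors with
    rounding noise do not raise.
    """
    v = np.asarray(v, dtype=float)
    norm = float(np.hypot(v[0], v[1]))
    if norm == 0.0:
        raise ValueError("deflection angle undefined for the zero vector")
    cosang = float(np.dot(v, GRAVITY_REFERENCE)) / norm
    cosang = min(1.0, max(-1.0, cosang))
    return math.degrees(math.acos(cosang))


def spine_ratio(
    frame: SkeletonFrame, min_waist_px: float = DEFAULT_MIN_WAIST_PX
) -> float:
    """|spine vector| / |waist width vector| (unitless)."""
    spine = posture_vector(frame, *SEGMENTS["spine"])
    waist = posture_vector(frame, *SEGMENTS["waist"])
    waist_norm = float(np.linalg.norm(waist))
    if waist_norm < min_waist_px:
        raise ValueError(
            f"waist width {waist_norm:.3g} px below floor {min_waist_px} px "
            f"in frame {frame.frame_index}; frame should have been invalidated"
        )
    return float(np.linalg.norm(spine)) / waist_norm


def torso_length(frame: SkeletonFrame) -> float:
    """H = Euclidean distance from neck (1) to mid-hip (8), pixels."""
    return float(np.linalg.norm(posture_vector(frame, NECK, MID_HIP)))


def extract_key_features(
    frame: SkeletonFrame, min_waist_px: float = DEFAULT_MIN_WAIST_PX
) -> KeyFeatures:
    """Bundle the five deflection angles, spine ratio and H for a valid frame."""
    return KeyFeatures(
        spine_angle=deflection_angle(posture_vector(frame, *SEGMENTS["spine"])),
        left_thigh_angle=deflection_angle(posture_vector(frame, *SEGMENTS["left_thigh"])),
        right_thigh_angle=deflection_angle(posture_vector(frame, *SEGMENTS["right_thigh"])),
        left_calf_angle=deflection_angle(posture_vector(frame, *SEGMENTS["left_calf"])),
        right_calf_angle=deflection_angle(posture_vector(frame, *SEGMENTS["right_calf"])),
        spine_ratio=spine_ratio(frame, min_waist_px=min_waist_px),
        torso_length_h=torso_length(frame),
    )


FEATURE_TABLE_COLUMNS = [
    "frame",
    "spine_angle",
    "l_thigh",
    "r_thigh",
    "l_calf",
    "r_calf",
    "spine_ratio",
    "H",
    "valid",
]


def feature_table(
    rows: Iterable[tuple[int, Union[KeyFeatures, None]]]
) -> pd.DataFrame:
    """One row per frame; feature columns are NaN for invalid frames."""
    out = []
    for frame_index, feats in rows:
        if feats is None:
            out.append([frame_index] + [np.nan] * 7 + [False])
        else:
            out.append(
                [
                    frame_index,
                    feats.spine_angle,
                    feats.left_thigh_angle,
                    feats.right_thigh_angle,
                    feats.left_calf_angle,
                    feats.right_calf_angle,
                    feats.spine_ratio,
                    feats.torso_length_h,
                    True,
                ]
            )
    return pd.DataFrame(out, columns=FEATURE_TABLE_COLUMNS)
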