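"""Seeded generator of labelled BODY_25 keypoint sequences.

A stick figure (segment lengths plus per-frame joint-angle and mid-hip
trajectories, orthographic projection) is animated through six action
archetypes and rendered as full 25-keypoint frames, standing in for
video-derived skeleton streams:

* WALK — upright gait: spine deflection stays below the 12.5 deg
  postural-stability limit, legs swing alternately so every frame keeps
  at least one angle Pair; never triggers the detector.
* SIT_STAND — sit-down/stand-up transient: spine ramps into the
  30-50 deg cross band, thighs past 60 deg, mid-hip dips ~0.35 torso.
* SQUAT — deep knee bend with near-vertical spine; thighs past 70 deg.
* BEND — leaning over: spine to ~70 deg with both legs still (< 15 deg),
  hips fixed.
* LATERAL_FALL — all five segment angles ramp past 50 deg within 15
  frames while the mid-hip descends by >= 0.8 torso lengths.
* FORWARD_FALL — a camera-facing fall: the projected spine length
  shrinks (hips fixed width) so the spine ratio collapses from >= 2.0 to
  below 1.0 while all angles stay below 30 deg; the mid-hip descends.

The three confusing activities (SIT_STAND, SQUAT, BEND) all open an
NSRP, which is what makes them useful negatives for the stage-two
classifier; WALK never does.  Gaussian keypoint jitter (default sd 1 px)
and optional dropout (keypoint zeroed with confidence 0) are applied
after the kinematic contracts, which therefore hold exactly only for the
noise-free skeleton.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .detector import DetectorConfig
from .io import N_KEYPOINTS, SkeletonFrame, write_csv_frames, write_openpose_frame
from .pipeline import detect_sequence
from .states import StageOneThresholds


class Action(str, Enum):
    WALK = "walk"
    SIT_STAND = "sit_stand"
    SQUAT = "squat"
    BEND = "bend"
    LATERAL_FALL = "lateral_fall"
    FORWARD_FALL = "forward_fall"


FALL_ACTIONS = frozenset({Action.LATERAL_FALL, Action.FORWARD_FALL})

#: Minimum frames for a fall sequence: trigger run + feature window.
MIN_FALL_FRAMES = 13


@dataclass(frozen=True)
class ActionSpec:
    action: Action
    n_frames: int = 40
    torso_length_px: float = 100.0
    hip_width_px: float = 40.0
    jitter_sd_px: float = 1.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.torso_length_px <= 0 or self.hip_width_px <= 0:
            raise ValueError("segment lengths must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.jitter_sd_px < 0:
            raise ValueError("jitter_sd_px must be nonnegative")
        min_frames = MIN_FALL_FRAMES if self.action in FALL_ACTIONS else 2
        if self.n_frames < min_frames:
            raise ValueError(
                f"{self.action.value} needs at least {min_frames} frames, "
                f"got {self.n_frames}"
            )

    @property
    def label(self) -> str:
        return "FALL" if self.action in FALL_ACTIONS else "ADL"


@dataclass(frozen=True)
class LabeledSequence:
    frames: list[SkeletonFrame]
    label: str
    action: ActionSpec


# ---------------------------------------------------------------------------
# Stick-figure rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """Joint-angle parameterisation of one frame (angles in degrees,
    measured from the up-image vertical; positive leans right-image)."""

    cx: float  # mid-hip x
    cy: float  # mid-hip y
    spine_angle: float
    thigh_l: float
    thigh_r: float
    calf_l: float
    calf_r: float
    spine_scale: float = 1.0  # projected-length factor (forward-fall foreshortening)


def pose_frame(
    pose: Pose,
    frame_index: int = 0,
    torso_length_px: float = 100.0,
    hip_width_px: float = 40.0,
    person_id: int = 0,
    confidence: float = 0.9,
) -> SkeletonFrame:
    """Render a Pose into a full 25-keypoint BODY_25 frame.

    A segment with deflection angle theta hangs from its proximal joint
    along (sin theta, cos theta); the spine rises from the mid-hip along
    (sin theta, -cos theta) scaled by ``spine_scale``.  The non-torso
    keypoints (head, arms, feet) are placed plausibly relative to the
    torso but carry no information the pipeline uses.
    """
    L = torso_length_px
    w = hip_width_px
    thigh_len, calf_len = 0.55 * L, 0.45 * L
    kp = np.zeros((N_KEYPOINTS, 3))

    def seg(origin: np.ndarray, angle_deg: float, length: float, up: bool = False) -> np.ndarray:
        a = math.radians(angle_deg)
        dy = -math.cos(a) if up else math.cos(a)
        return origin + length * np.array([math.sin(a), dy])

    midhip = np.array([pose.cx, pose.cy])
    neck = seg(midhip, pose.spine_angle, L * pose.spine_scale, up=True)
    hip_l = midhip + np.array([-w / 2.0, 0.0])
    hip_r = midhip + np.array([w / 2.0, 0.0])
    knee_l = seg(hip_l, pose.thigh_l, thigh_len)
    knee_r = seg(hip_r, pose.thigh_r, thigh_len)
    ankle_l = seg(knee_l, pose.calf_l, calf_len)
    ankle_r = seg(knee_r, pose.calf_r, calf_len)

    spine_dir = (neck - midhip) / max(float(np.linalg.norm(neck - midhip)), 1e-9)
    nose = neck + 0.25 * L * spine_dir
    sh_l, sh_r = neck + np.array([-0.55 * w, 0.0]), neck + np.array([0.55 * w, 0.0])

    pts = {
        0: nose,
        1: neck,
        2: sh_r,
        3: sh_r + np.array([0.1 * w, 0.3 * L]),
        4: sh_r + np.array([0.15 * w, 0.55 * L]),
        5: sh_l,
        6: sh_l + np.array([-0.1 * w, 0.3 * L]),
        7: sh_l + np.array([-0.15 * w, 0.55 * L]),
        8: midhip,
        9: hip_l,
        10: knee_l,
        11: ankle_l,
        12: hip_r,
        13: knee_r,
        14: ankle_r,
        15: nose + np.array([0.1 * w, -0.02 * L]),
        16: nose + np.array([-0.1 * w, -0.02 * L]),
        17: nose + np.array([0.2 * w, 0.02 * L]),
        18: nose + np.array([-0.2 * w, 0.02 * L]),
        19: ankle_l + np.array([-0.1 * w, 0.05 * L]),
        20: ankle_l + np.array([-0.15 * w, 0.05 * L]),
        21: ankle_l + np.array([0.05 * w, 0.06 * L]),
        22: ankle_r + np.array([0.1 * w, 0.05 * L]),
        23: ankle_r + np.array([0.15 * w, 0.05 * L]),
        24: ankle_r + np.array([-0.05 * w, 0.06 * L]),
    }
    for k, p in pts.items():
        kp[k, :2] = p
        kp[k, 2] = confidence
    return SkeletonFrame(frame_index, person_id, kp)


# ---------------------------------------------------------------------------
# Action trajectories
# ---------------------------------------------------------------------------

def _ramp(t: float, t0: float, t1: float) -> float:
    """Linear 0 -> 1 between t0 and t1, clamped outside."""
    if t1 <= t0:
        return 1.0 if t >= t1 else 0.0
    return min(1.0, max(0.0, (t - t0) / (t1 - t0)))


def _updown(t: float, t0: float, t1: float, t2: float, t3: float) -> float:
    """Ramp up over [t0,t1], hold 1 over [t1,t2], ramp down over [t2,t3]."""
    return min(_ramp(t, t0, t1), 1.0 - _ramp(t, t2, t3))


def _trajectory(spec: ActionSpec) -> list[Pose]:
    n, L = spec.n_frames, spec.torso_length_px
    cx0, cy0 = 160.0, 120.0
    poses = []
    for t in range(n):
        if spec.action is Action.WALK:
            swing = 2.0 * math.pi * t / 20.0
            thigh_l = 16.0 * abs(math.sin(swing))
            thigh_r = 16.0 * abs(math.cos(swing))
            poses.append(
                Pose(
                    cx=cx0 + 1.2 * t,
                    cy=cy0,
                    spine_angle=5.0 + 5.0 * math.sin(2.0 * math.pi * t / 16.0),
                    thigh_l=thigh_l,
                    thigh_r=thigh_r,
                    calf_l=0.5 * thigh_l + 2.0,
                    calf_r=0.5 * thigh_r + 2.0,
                )
            )
        elif spec.action is Action.SIT_STAND:
            s = _updown(t, 0.2 * n, 0.5 * n, 0.7 * n, n)
            poses.append(
                Pose(
                    cx=cx0,
                    cy=cy0 + 0.35 * L * s,
                    spine_angle=5.0 + 35.0 * s,
                    thigh_l=5.0 + 70.0 * s,
                    thigh_r=5.0 + 70.0 * s,
                    calf_l=5.0 + 20.0 * s,
                    calf_r=5.0 + 20.0 * s,
                )
            )
        elif spec.action is Action.SQUAT:
            s = _updown(t, 0.2 * n, 0.5 * n, 0.7 * n, n)
            poses.append(
                Pose(
                    cx=cx0,
                    cy=cy0 + 0.35 * L * s,
                    spine_angle=8.0 + 16.0 * s,
                    thigh_l=8.0 + 72.0 * s,
                    thigh_r=8.0 + 72.0 * s,
                    calf_l=8.0 + 40.0 * s,
                    calf_r=8.0 + 40.0 * s,
                )
            )
        elif spec.action is Action.BEND:
            s = _updown(t, 0.3 * n, 0.55 * n, 0.75 * n, n)
            poses.append(
                Pose(
                    cx=cx0,
                    cy=cy0,
                    spine_angle=5.0 + 65.0 * s,
                    thigh_l=6.0,
                    thigh_r=6.0,
                    calf_l=6.0,
                    calf_r=6.0,
                )
            )
        elif spec.action is Action.LATERAL_FALL:
            s = _ramp(t, 8.0, 16.0)  # angles pass 50 deg within 8 frames
            a = 8.0 + 60.0 * s
            poses.append(
                Pose(
                    cx=cx0 + 0.3 * L * s,
                    cy=cy0 + 0.85 * L * s,
                    spine_angle=a,
                    thigh_l=a,
                    thigh_r=a,
                    calf_l=a,
                    calf_r=a,
                )
            )
        elif spec.action is Action.FORWARD_FALL:
            scale = 1.0 - 0.75 * _ramp(t, 8.0, 16.0)  # ratio 2.5 -> 0.625
            poses.append(
                Pose(
                    cx=cx0,
                    cy=cy0 + 0.8 * L * _ramp(t, 10.0, 26.0),
                    spine_angle=8.0 + 4.0 * _ramp(t, 8.0, 16.0),
                    thigh_l=8.0,
                    thigh_r=8.0,
                    calf_l=8.0,
                    calf_r=8.0,
                    spine_scale=scale,
                )
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown action {spec.action}")
    return poses


def generate_sequence(spec: ActionSpec) -> LabeledSequence:
    """Generate one labelled sequence (deterministic given spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for t, pose in enumerate(_trajectory(spec)):
        frame = pose_frame(
            pose, frame_index=t,
            torso_length_px=spec.torso_length_px,
            hip_width_px=spec.hip_width_px,
        )
        kp = frame.keypoints.copy()
        if spec.jitter_sd_px > 0:
            kp[:, :2] += rng.normal(0.0, spec.jitter_sd_px, size=(N_KEYPOINTS, 2))
        if spec.dropout_prob > 0:
            drop = rng.random(N_KEYPOINTS) < spec.dropout_prob
            kp[drop] = 0.0
        frames.append(SkeletonFrame(t, 0, kp))
    return LabeledSequence(frames, spec.label, spec)


SAMPLE_TABLE_COLUMNS = ["gamma", "epsilon", "tau", "label", "action", "seed"]


def generate_corpus(
    n_per_action: Mapping[Action, int],
    seed: int = 0,
    jitter_sd_px: float = 1.0,
    dropout_prob: float = 0.0,
    n_frames: Optional[int] = None,
    thresholds: StageOneThresholds = StageOneThresholds(),
    detector_cfg: DetectorConfig = DetectorConfig(),
) -> tuple[list[LabeledSequence], pd.DataFrame]:
    """Generate sequences per action and their NSRP feature samples.

    Each sequence is run through stage one and the detector (no
    classifier); the first NSRP event, when there is one, contributes one
    labelled (gamma, epsilon, tau) row to the returned sample table.
    Per-sequence seeds derive deterministically from ``seed``.
    """
    sequences: list[LabeledSequence] = []
    rows = []
    actions = list(Action)  # fixed iteration order keeps corpora reproducible
    for a_idx, action in enumerate(actions):
        count = int(n_per_action.get(action, 0))
        if count < 0:
            raise ValueError(f"negative count for {action}")
        for i in range(count):
            child_seed = int((seed * 1_000_003 + a_idx * 10_007 + i) % 2**31)
            spec = ActionSpec(
                action=action,
                n_frames=n_frames if n_frames is not None else 40,
                jitter_sd_px=jitter_sd_px,
                dropout_prob=dropout_prob,
                seed=child_seed,
            )
            seq = generate_sequence(spec)
            sequences.append(seq)
            _, events = detect_sequence(
                seq.frames, thresholds=thresholds, cfg=detector_cfg
            )
            if events:
                fv = events[0].features
                rows.append(
                    (fv.gamma, fv.epsilon, fv.tau, seq.label, action.value, child_seed)
                )
    table = pd.DataFrame(rows, columns=SAMPLE_TABLE_COLUMNS)
    return sequences, table


def write_sequence(seq: LabeledSequence, out_dir: Union[str, Path]) -> None:
    """Write one sequence as per-frame OpenPose JSON plus the internal CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for frame in seq.frames:
        write_openpose_frame(
            out / f"frame_{frame.frame_index:012d}_keypoints.json", [frame]
        )
    write_csv_frames(out / "keypoints.csv", [(f.frame_index, [f]) for f in seq.frames])
    manifest = {
        "action": seq.action.action.value,
        "label": seq.label,
        "n_frames": seq.action.n_frames,
        "seed": seq.action.seed,
        "jitter_sd_px": seq.action.jitter_sd_px,
        "dropout_prob": seq.action.dropout_prob,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
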