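"""Glue: run a keypoint sequence through stage one and stage two.

Invalid frames (missing torso keypoints or degenerate waist) do not
advance the state machine: they carry the previous frame's state
forward, and before any valid frame has been seen the state is
FLUCTUATING — a sequence is never silently stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .detector import DetectionEvent, DetectorConfig, run_detector
from .features import KeyFeatures, extract_key_features, feature_table
from .io import (
    DEFAULT_MIN_CONFIDENCE,
    DEFAULT_MIN_WAIST_PX,
    SkeletonFrame,
    validate_frame,
)
from .states import (
    HumanState,
    StageOneThresholds,
    SteadySymbol,
    Tendency,
    classify_features,
    state_table,
)


@dataclass(frozen=True)
class FrameAnnotation:
    """Stage-one output for one input frame."""

    frame_index: int
    valid: bool
    features: Optional[KeyFeatures]
    tendency: Optional[Tendency]
    steady: Optional[SteadySymbol]
    state: HumanState
    frame: Optional[SkeletonFrame]  # None when invalid


def annotate_frames(
    frames: Sequence[SkeletonFrame],
    thresholds: StageOneThresholds = StageOneThresholds(),
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_waist_px: float = DEFAULT_MIN_WAIST_PX,
) -> list[FrameAnnotation]:
    """Validate each frame, extract features, and assign human states."""
    out: list[FrameAnnotation] = []
    carried = HumanState.FLUCTUATING  # conservative default before any valid frame
    for frame in frames:
        flag = validate_frame(frame, min_confidence, min_waist_px)
        if not flag.valid:
            out.append(
                FrameAnnotation(frame.frame_index, False, None, None, None, carried, None)
            )
            continue
        feats = extract_key_features(frame, min_waist_px=min_waist_px)
        t, s, state = classify_features(feats, thresholds)
        carried = state
        out.append(FrameAnnotation(frame.frame_index, True, feats, t, s, state, frame))
    return out


def detect_sequence(
    frames: Sequence[SkeletonFrame],
    thresholds: StageOneThresholds = StageOneThresholds(),
    cfg: DetectorConfig = DetectorConfig(),
    classifier=None,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_waist_px: float = DEFAULT_MIN_WAIST_PX,
) -> tuple[list[FrameAnnotation], list[DetectionEvent]]:
    """Full two-stage run on one sequence: annotations plus NSRP events."""
    annotations = annotate_frames(frames, thresholds, min_confidence, min_waist_px)
    stream = [(a.frame, a.state) for a in annotations]
    events = run_detector(stream, classifier=classifier, cfg=cfg)
    return annotations, events


def annotation_feature_table(annotations: Sequence[FrameAnnotation]) -> pd.DataFrame:
    return feature_table((a.frame_index, a.features) for a in annotations)


def annotation_state_table(annotations: Sequence[FrameAnnotation]) -> pd.DataFrame:
    """State stream for the valid frames (invalid ones carry no symbols)."""
    return state_table(
        (a.frame_index, a.tendency, a.steady, a.state)
        for a in annotations
        if a.valid
    )
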