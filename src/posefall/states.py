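"""Stage one: divide frames into stable / fluctuating / disorder states.

The scattered per-frame features are integrated into two symbols and a
three-way state:

* **Tendency symbol** (T1/T2/T3) grades how far the body leans, from the
  spine deflection angle and the spine ratio.  T1 = near upright, T3 =
  strong falling tendency (large spine angle OR collapsed spine ratio —
  the ratio branch catches camera-facing falls that the angle misses).
* **Steady symbol** (S1/S2) grades lower-body stability.  Four angle
  *Pairs* are tested, each requiring both angles below the angle limit:
  spine+left-thigh, spine+right-thigh, left-calf+left-thigh,
  right-calf+right-thigh.  One true Pair suffices for S1.
* **Human state**: STABLE iff (T1, S1); DISORDER iff (T3, S2); anything
  else is FLUCTUATING.  States score 0 / 1 / 2 for the cumulative state
  score used by the temporal detector.

Thresholds default to ALL=30 deg, AUL=50 deg, RB=1.0, AL=30 deg.
Comparisons are strict, so boundary equality falls to the middle/unsteady
branch (T2 or S2), which keeps threshold behaviour deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable

import pandas as pd

from .features import KeyFeatures


@dataclass(frozen=True)
class StageOneThresholds:
    """Decision thresholds for the tendency and steady symbols.

    angle_lower_limit (ALL) and angle_upper_limit (AUL) bracket the
    spine-angle cross area between everyday activity and falls;
    ratio_boundary (RB) splits the spine-ratio axis; angle_limit (AL)
    is the per-segment bound used by the Pair tests.
    """

    angle_lower_limit: float = 30.0
    angle_upper_limit: float = 50.0
    ratio_boundary: float = 1.0
    angle_limit: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.angle_lower_limit < self.angle_upper_limit):
            raise ValueError("need 0 < angle_lower_limit < angle_upper_limit")
        if self.ratio_boundary <= 0 or self.angle_limit <= 0:
            raise ValueError("ratio_boundary and angle_limit must be positive")


class Tendency(str, Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"


class SteadyLevel(str, Enum):
    S1 = "S1"
    S2 = "S2"


@dataclass(frozen=True)
class SteadySymbol:
    level: SteadyLevel
    pair_count: int  # number of true Pair cases, 0..4

    def __post_init__(self) -> None:
        if not 0 <= self.pair_count <= 4:
            raise ValueError("pair_count must be in 0..4")
        if (self.level is SteadyLevel.S1) != (self.pair_count >= 1):
            raise ValueError("level must be S1 iff pair_count >= 1")


class HumanState(IntEnum):
    """Per-frame body state; the integer value is the state score."""

    STABLE = 0
    FLUCTUATING = 1
    DISORDER = 2

    @property
    def score(self) -> int:
        return int(self)


def tendency_symbol(f: KeyFeatures, th: StageOneThresholds = StageOneThresholds()) -> Tendency:
    """Three-level leaning-tendency label from spine angle and spine ratio."""
    if f.spine_angle < th.angle_lower_limit and f.spine_ratio > th.ratio_boundary:
        return Tendency.T1
    if f.spine_angle > th.angle_upper_limit or f.spine_ratio < th.ratio_boundary:
        return Tendency.T3
    return Tendency.T2


def steady_symbol(f: KeyFeatures, th: StageOneThresholds = StageOneThresholds()) -> SteadySymbol:
    """Two-level lower-body stability label from the four angle Pairs."""
    al = th.angle_limit
    cases = (
        f.spine_angle < al and f.left_thigh_angle < al,
        f.spine_angle < al and f.right_thigh_angle < al,
        f.left_calf_angle < al and f.left_thigh_angle < al,
        f.right_calf_angle < al and f.right_thigh_angle < al,
    )
    n = sum(cases)
    return SteadySymbol(SteadyLevel.S1 if n >= 1 else SteadyLevel.S2, n)


def human_state(t: Tendency, s: SteadySymbol) -> HumanState:
    """STABLE iff (S1, T1); DISORDER iff (S2, T3); else FLUCTUATING."""
    if s.level is SteadyLevel.S1 and t is Tendency.T1:
        return HumanState.STABLE
    if s.level is SteadyLevel.S2 and t is Tendency.T3:
        return HumanState.DISORDER
    return HumanState.FLUCTUATING


def classify_features(
    f: KeyFeatures, th: StageOneThresholds = StageOneThresholds()
) -> tuple[Tendency, SteadySymbol, HumanState]:
    """Run the full stage-one pipeline on one frame's features."""
    t = tendency_symbol(f, th)
    s = steady_symbol(f, th)
    return t, s, human_state(t, s)


STATE_TABLE_COLUMNS = ["frame", "tendency", "steady", "pair_count", "state", "score"]


def state_table(
    rows: Iterable[tuple[int, Tendency, SteadySymbol, HumanState]]
) -> pd.DataFrame:
    """State-stream table: frame, tendency, steady, pair_count, state, score."""
    return pd.DataFrame(
        [
            (i, t.value, s.level.value, s.pair_count, st.name, st.score)
            for i, t, s, st in rows
        ],
        columns=STATE_TABLE_COLUMNS,
    )
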