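"""Stage two: the time-continuous NSRP detector.

A fall is modelled as a sustained transition away from the stable state.
While the body is stable the detector keeps a *reference template*
xi = (Px, Py, H): the mid-hip position and torso length at the most
recent stable frame.  Three consecutive unstable frames (fluctuating or
disorder) open a *non-stationary residence period* (NSRP).  Inside the
NSRP:

* three consecutive stable frames abort it — no event, the template is
  refreshed and scanning resumes;
* otherwise, once the feature window (default 10 frames, the frames
  *following* the 3 trigger frames) has elapsed, a feature vector
  D = (gamma, epsilon, tau) is computed and handed to the classifier
  once, producing one detection event.

The three window features, each normalised by the template's H so they
are invariant to apparent body size:

* ``gamma`` (compare value): sum over window frames of
  mu = softsign(Py - y8) * ||(Px,Py) - (x8,y8)|| / H, with
  softsign(x) = x / (1 + |x|).  mu is negative when the mid-hip has
  moved down-image (toward the floor), so a plunging centroid drives
  gamma strongly negative.  Stable frames contribute mu = 0.
* ``epsilon`` (energy value): sum over window frames and lower-limb
  keypoints (knees 10/13, ankles 11/14) of |y - mean_y| / H — the
  vertical dispersion of the lower limbs, zero when the legs hold still.
* ``tau`` (state score): sum of per-frame state scores (0/1/2), so
  10 disorder frames give tau = 20.

Invalid frames inside the window keep the window advancing and keep
their carried-forward state (contributing to tau) but are skipped for
gamma and epsilon — coordinates are never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .features import torso_length
from .io import LOWER_LIMB_IDS, MID_HIP, SkeletonFrame
from .states import HumanState


def softsign(x: float) -> float:
    """x / (1 + |x|): a smooth sign with pixel-scale saturation."""
    return x / (1.0 + abs(x))


@dataclass(frozen=True)
class ReferenceTemplate:
    """(Px, Py, H): mid-hip position and torso length at the last stable frame."""

    px: float
    py: float
    h: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("template torso length H must be positive")


@dataclass(frozen=True)
class NsrpFeatureVector:
    gamma: float
    epsilon: float
    tau: int

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma, self.epsilon, float(self.tau)])


@dataclass(frozen=True)
class DetectionEvent:
    """One closed NSRP: stream positions of the first trigger frame and the
    last window frame, the feature vector, and the classifier verdict
    (None when no classifier was supplied)."""

    start_frame: int
    end_frame: int
    features: NsrpFeatureVector
    is_fall: Optional[bool]


@dataclass(frozen=True)
class DetectorConfig:
    """Temporal-detector tuning.

    unstable_run: consecutive unstable frames that open an NSRP.
    stable_run: consecutive stable frames that abort it.
    nsrp_window: feature-window length in frames.
    lower_limb_ids: keypoints entering the energy value.
    include_trigger_frames: also fold the trigger frames into the
        feature window (off by default: features are formed over the
        frames following the trigger).
    strict_sign: replace softsign by a hard sign in mu.
    """

    unstable_run: int = 3
    stable_run: int = 3
    nsrp_window: int = 10
    lower_limb_ids: tuple[int, ...] = LOWER_LIMB_IDS
    include_trigger_frames: bool = False
    strict_sign: bool = False

    def __post_init__(self) -> None:
        if min(self.unstable_run, self.stable_run, self.nsrp_window) < 1:
            raise ValueError("run lengths and window must be positive")
        if self.stable_run > self.nsrp_window:
            raise ValueError("stable_run must not exceed nsrp_window")


def update_template(frame: SkeletonFrame) -> ReferenceTemplate:
    """Refresh xi from a valid stable frame."""
    x8, y8 = frame.xy(MID_HIP)
    return ReferenceTemplate(float(x8), float(y8), torso_length(frame))


def centroid_increment(
    xi: Optional[ReferenceTemplate], frame: SkeletonFrame, strict_sign: bool = False
) -> float:
    """mu: signed, H-normalised displacement of the mid-hip from the template."""
    if xi is None:
        raise ValueError("reference template not set; no stable frame seen yet")
    x8, y8 = frame.xy(MID_HIP)
    dist = float(np.hypot(xi.px - x8, xi.py - y8))
    direction = xi.py - float(y8)  # negative when the centroid moved down-image
    sign = float(np.sign(direction)) if strict_sign else softsign(direction)
    return sign * dist / xi.h


def compare_value(mu_values: Iterable[float]) -> float:
    """gamma: arithmetic sum of mu over the NSRP (0 for an empty window)."""
    return float(sum(mu_values))


def energy_value(
    nsrp_frames: Sequence[SkeletonFrame],
    xi: Optional[ReferenceTemplate],
    cfg: DetectorConfig = DetectorConfig(),
) -> float:
    """epsilon: H-normalised vertical dispersion of the lower limbs.

    Falls back to the first frame's own torso length when no template is
    available (no stable frame preceded the NSRP).
    """
    if len(nsrp_frames) == 0:
        raise ValueError("energy value undefined for an empty NSRP")
    h = xi.h if xi is not None else torso_length(nsrp_frames[0])
    ys = np.array(
        [[f.keypoints[t, 1] for t in cfg.lower_limb_ids] for f in nsrp_frames]
    )  # (n_frames, n_limb)
    dev = np.abs(ys - ys.mean(axis=0, keepdims=True))
    return float(dev.sum() / h)


def state_score(states: Iterable[HumanState]) -> int:
    """tau: cumulative state score (stable 0, fluctuating 1, disorder 2)."""
    return int(sum(s.score for s in states))


ClassifierLike = Union[Callable[[NsrpFeatureVector], bool], object]


def _query_classifier(classifier: ClassifierLike, fv: NsrpFeatureVector) -> bool:
    if hasattr(classifier, "predict_one"):
        from .classify import FALL  # late import avoids a cycle

        return classifier.predict_one(fv) == FALL
    return bool(classifier(fv))


def _window_features(
    items: Sequence[tuple[Optional[SkeletonFrame], HumanState]],
    xi: Optional[ReferenceTemplate],
    cfg: DetectorConfig,
) -> NsrpFeatureVector:
    mus = []
    for frame, state in items:
        if frame is None or state is HumanState.STABLE or xi is None:
            mus.append(0.0)
        else:
            mus.append(centroid_increment(xi, frame, strict_sign=cfg.strict_sign))
    valid_frames = [f for f, _ in items if f is not None]
    eps = energy_value(valid_frames, xi, cfg) if valid_frames else 0.0
    return NsrpFeatureVector(
        gamma=compare_value(mus),
        epsilon=eps,
        tau=state_score(s for _, s in items),
    )


def run_detector(
    stream: Iterable[tuple[Optional[SkeletonFrame], HumanState]],
    classifier: Optional[ClassifierLike] = None,
    cfg: DetectorConfig = DetectorConfig(),
) -> list[DetectionEvent]:
    """Run the time-continuous recognition loop over an annotated stream.

    ``stream`` yields one ``(frame, state)`` pair per input frame in time
    order; an invalid frame is passed as ``(None, carried_state)``.  The
    classifier (anything with ``predict_one`` or a plain callable on the
    feature vector) is queried exactly once per completed NSRP; with no
    classifier, events carry ``is_fall=None``.

    The detector is deterministic: replaying a stream yields identical
    events.  Events never overlap, so there is at most one per
    ``unstable_run + nsrp_window`` frames.
    """
    events: list[DetectionEvent] = []
    xi: Optional[ReferenceTemplate] = None
    unstable = 0
    trigger_buf: list[tuple[Optional[SkeletonFrame], HumanState]] = []
    in_nsrp = False
    trigger_start = -1
    window: list[tuple[Optional[SkeletonFrame], HumanState]] = []
    stable_in_nsrp = 0

    for pos, (frame, state) in enumerate(stream):
        if not in_nsrp:
            if state is HumanState.STABLE:
                unstable = 0
                trigger_buf.clear()
                if frame is not None:
                    xi = update_template(frame)
            else:
                unstable += 1
                trigger_buf.append((frame, state))
                if unstable >= cfg.unstable_run:
                    in_nsrp = True
                    trigger_start = pos - cfg.unstable_run + 1
                    window = list(trigger_buf) if cfg.include_trigger_frames else []
                    stable_in_nsrp = 0
                    unstable = 0
                    trigger_buf = []
            continue

        # inside the NSRP
        window.append((frame, state))
        stable_in_nsrp = stable_in_nsrp + 1 if state is HumanState.STABLE else 0
        if stable_in_nsrp >= cfg.stable_run:
            # sustained recovery: abort with no event, refresh the template
            in_nsrp = False
            window = []
            if frame is not None:
                xi = update_template(frame)
            continue
        target = cfg.nsrp_window + (cfg.unstable_run if cfg.include_trigger_frames else 0)
        if len(window) >= target:
            fv = _window_features(window, xi, cfg)
            is_fall = _query_classifier(classifier, fv) if classifier is not None else None
            events.append(DetectionEvent(trigger_start, pos, fv, is_fall))
            in_nsrp = False
            window = []

    return events
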