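import numpy as np
import pytest

from posefall.io import N_KEYPOINTS, SkeletonFrame
from posefall.synthetic import Pose, pose_frame


@pytest.fixture
def upright_frame() -> SkeletonFrame:
    """A perfectly upright stick figure: all angles 0, ratio = 100/40."""
    return pose_frame(
        Pose(cx=160.0, cy=120.0, spine_angle=0.0, thigh_l=0.0, thigh_r=0.0,
             calf_l=0.0, calf_r=0.0)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201205)


def make_frame(coords: dict, frame_index: int = 0, conf: float = 0.9) -> SkeletonFrame:
    """Frame with the given {keypoint_id: (x, y)} set; the rest undetected."""
    kp = np.zeros((N_KEYPOINTS, 3))
    for k, (x, y) in coords.items():
        kp[k] = (x, y, conf)
    return SkeletonFrame(frame_index, 0, kp)
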