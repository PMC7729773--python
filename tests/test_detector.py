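import numpy as np
import pytest

from oracles import detector_oracle
from posefall.detector import (
    DetectorConfig,
    NsrpFeatureVector,
    ReferenceTemplate,
    centroid_increment,
    compare_value,
    energy_value,
    run_detector,
    softsign,
    state_score,
    update_template,
)
from posefall.io import SkeletonFrame
from posefall.states import HumanState
from posefall.synthetic import Pose, pose_frame

S, F, D = HumanState.STABLE, HumanState.FLUCTUATING, HumanState.DISORDER


def frame_at(cy: float, idx: int = 0, angles: float = 0.0) -> SkeletonFrame:
    return pose_frame(
        Pose(cx=160.0, cy=cy, spine_angle=angles, thigh_l=angles, thigh_r=angles,
             calf_l=angles, calf_r=angles),
        frame_index=idx,
    )


class CountingClassifier:
    """Stub classifier recording every query."""

    def __init__(self, verdict=True):
        self.calls: list[NsrpFeatureVector] = []
        self.verdict = verdict

    def __call__(self, fv):
        self.calls.append(fv)
        return self.verdict


class TestTemplateAndIncrements:
    def test_template_reads_midhip_and_torso(self):
        xi = update_template(frame_at(200.0))
        assert (xi.px, xi.py, xi.h) == pytest.approx((160.0, 200.0, 100.0))

    def test_template_last_writer_wins(self):
        xi = update_template(frame_at(150.0))
        xi = update_template(frame_at(200.0))
        assert xi.py == pytest.approx(200.0)

    def test_template_rejects_zero_torso(self):
        with pytest.raises(ValueError):
            ReferenceTemplate(0.0, 0.0, 0.0)

    def test_mu_zero_for_zero_displacement(self):
        xi = ReferenceTemplate(160.0, 200.0, 100.0)
        assert centroid_increment(xi, frame_at(200.0)) == pytest.approx(0.0)

    def test_mu_descending_centroid(self):
        # down-image move of 50 px: softsign(-50) * 50 / 100
        xi = ReferenceTemplate(100.0, 200.0, 100.0)
        frame = frame_at(250.0)
        frame.keypoints[8, :2] = (100.0, 250.0)
        mu = centroid_increment(xi, frame)
        assert mu == pytest.approx((-50.0 / 51.0) * 0.5, abs=1e-12)
        assert mu == pytest.approx(-0.4901960784, abs=1e-9)

    def test_mu_ascending_centroid(self):
        # up-image move (130,160) from (100,200): distance 50, softsign(40)
        xi = ReferenceTemplate(100.0, 200.0, 100.0)
        frame = frame_at(160.0)
        frame.keypoints[8, :2] = (130.0, 160.0)
        mu = centroid_increment(xi, frame)
        assert mu == pytest.approx((40.0 / 41.0) * 0.5, abs=1e-12)
        assert mu == pytest.approx(0.4878048780, abs=1e-9)

    def test_mu_requires_template(self):
        with pytest.raises(ValueError, match="template"):
            centroid_increment(None, frame_at(200.0))

    def test_strict_sign_variant(self):
        xi = ReferenceTemplate(100.0, 200.0, 100.0)
        frame = frame_at(250.0)
        frame.keypoints[8, :2] = (100.0, 250.0)
        assert centroid_increment(xi, frame, strict_sign=True) == pytest.approx(-0.5)

    def test_softsign_definition(self):
        assert softsign(-50.0) == pytest.approx(-50.0 / 51.0)
        assert softsign(0.0) == 0.0


class TestWindowStatistics:
    def test_gamma_sums(self):
        assert compare_value([]) == 0.0
        assert compare_value([0.0, 0.0, 0.0]) == 0.0
        assert compare_value([-0.49020, -0.49020]) == pytest.approx(-0.98039, abs=1e-4)

    def test_epsilon_zero_for_static_legs(self):
        xi = ReferenceTemplate(160.0, 120.0, 100.0)
        frames = [frame_at(120.0, idx=i) for i in range(10)]
        assert energy_value(frames, xi) == pytest.approx(0.0)

    def test_epsilon_direct_evaluation(self):
        # keypoint 10 y in {100, 110}, everything else constant, H = 100
        xi = ReferenceTemplate(160.0, 120.0, 100.0)
        f1, f2 = frame_at(120.0, 0), frame_at(120.0, 1)
        f1.keypoints[10, 1] = 100.0
        f2.keypoints[10, 1] = 110.0
        f2.keypoints[[11, 13, 14], 1] = f1.keypoints[[11, 13, 14], 1]
        assert energy_value([f1, f2], xi) == pytest.approx(0.10)

    def test_epsilon_scale_invariance(self):
        xi = ReferenceTemplate(160.0, 120.0, 100.0)
        frames = [frame_at(120.0 + 3 * i, idx=i) for i in range(5)]
        eps = energy_value(frames, xi)
        doubled = [SkeletonFrame(f.frame_index, 0,
                                 np.column_stack([f.keypoints[:, :2] * 2,
                                                  f.keypoints[:, 2]]))
                   for f in frames]
        xi2 = ReferenceTemplate(320.0, 240.0, 200.0)
        assert energy_value(doubled, xi2) == pytest.approx(eps)

    def test_epsilon_invariant_to_constant_y_shift(self):
        xi = ReferenceTemplate(160.0, 120.0, 100.0)
        frames = [frame_at(120.0 + 5 * i, idx=i) for i in range(6)]
        shifted = [SkeletonFrame(f.frame_index, 0,
                                 f.keypoints + np.array([0.0, 37.0, 0.0]))
                   for f in frames]
        assert energy_value(shifted, xi) == pytest.approx(energy_value(frames, xi))

    def test_epsilon_empty_window_raises(self):
        with pytest.raises(ValueError):
            energy_value([], ReferenceTemplate(0, 0, 100.0))

    def test_tau_arithmetic(self):
        assert state_score([D] * 10) == 20
        assert state_score([F] * 10) == 10
        assert state_score([S, F, D]) == 3
        assert state_score([]) == 0


class TestRunDetector:
    def test_all_stable_stream_never_opens(self):
        stream = [(frame_at(120.0, i), S) for i in range(200)]
        assert run_detector(stream) == []

    def test_three_stable_frames_abort_the_nsrp(self):
        states = [S] * 5 + [F] * 3 + [S] * 3 + [S] * 20
        stream = [(frame_at(120.0, i), st) for i, st in enumerate(states)]
        clf = CountingClassifier()
        assert run_detector(stream, classifier=clf) == []
        assert clf.calls == []

    def test_disorder_plunge_yields_one_event(self):
        """100 stable frames, then a 13-frame disorder plunge: one event,
        tau = 20, gamma < 0, classifier queried exactly once."""
        stream = [(frame_at(120.0, i), S) for i in range(100)]
        for j in range(13):
            stream.append((frame_at(120.0 + 8.0 * (j + 1), 100 + j, angles=70.0), D))
        clf = CountingClassifier(verdict=True)
        events = run_detector(stream, classifier=clf)
        assert len(events) == 1
        ev = events[0]
        assert len(clf.calls) == 1
        assert ev.start_frame == 100 and ev.end_frame == 112
        assert ev.features.tau == 20
        assert ev.features.gamma < 0
        assert ev.is_fall is True

    def test_gamma_sign_tracks_centroid_direction(self):
        down = [(frame_at(120.0, i), S) for i in range(10)]
        down += [(frame_at(120.0 + 5.0 * j, 10 + j), D) for j in range(1, 14)]
        up = [(frame_at(120.0, i), S) for i in range(10)]
        up += [(frame_at(120.0 - 5.0 * j, 10 + j), D) for j in range(1, 14)]
        assert run_detector(down)[0].features.gamma < 0
        assert run_detector(up)[0].features.gamma > 0

    def test_invalid_frames_carry_state_but_skip_coordinates(self):
        stream = [(frame_at(120.0, i), S) for i in range(5)]
        stream += [(None, D)] * 13
        events = run_detector(stream)
        assert len(events) == 1
        assert events[0].features.tau == 20
        assert events[0].features.gamma == 0.0
        assert events[0].features.epsilon == 0.0

    def test_determinism_on_replay(self):
        rng = np.random.default_rng(7)
        states = [HumanState(int(s)) for s in rng.integers(0, 3, 120)]
        stream = [(frame_at(120.0 + float(rng.uniform(-30, 30)), i), st)
                  for i, st in enumerate(states)]
        assert run_detector(stream) == run_detector(stream)

    def test_include_trigger_frames_lengthens_tau(self):
        stream = [(frame_at(120.0, i), S) for i in range(5)]
        stream += [(frame_at(125.0 + j, 5 + j), D) for j in range(13)]
        default = run_detector(stream)[0]
        with_trigger = run_detector(
            stream, cfg=DetectorConfig(include_trigger_frames=True)
        )[0]
        assert default.features.tau == 20
        assert with_trigger.features.tau == 26  # 3 trigger + 10 window frames


def random_state_streams(n_streams, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_streams):
        n = int(rng.integers(20, 90))
        p_stable = rng.uniform(0.2, 0.8)
        probs = [p_stable, (1 - p_stable) * 0.5, (1 - p_stable) * 0.5]
        yield [int(s) for s in rng.choice(3, size=n, p=probs)]


class TestOracleEquivalence:
    def test_matches_literal_transcription_on_random_streams(self):
        """Event spans and tau agree with an unoptimised transcription of
        the scanning loop on 300 random state streams."""
        for scores in random_state_streams(300, seed=123):
            states = [HumanState(s) for s in scores]
            stream = [(None, st) for st in states]
            got = [(e.start_frame, e.end_frame, e.features.tau)
                   for e in run_detector(stream)]
            want = [(t0, w[-1], tau) for t0, w, tau in detector_oracle(scores)]
            assert got == want

    def test_events_never_overlap(self):
        for scores in random_state_streams(100, seed=321):
            stream = [(None, HumanState(s)) for s in scores]
            events = run_detector(stream)
            for a, b in zip(events, events[1:]):
                assert a.end_frame < b.start_frame
            cfg = DetectorConfig()
            span = cfg.unstable_run + cfg.nsrp_window
            assert len(events) <= len(scores) // span + 1
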