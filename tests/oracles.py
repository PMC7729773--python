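"""Independent reference implementations used to check posefall.

Each oracle is written as a literal, unoptimised transcription of the
procedure it checks, deliberately avoiding the code paths of the
package (arctangent instead of cosine law for angles; plain nested
if/else for the symbol logic; an explicit scanning loop for the
temporal detector).
"""

from __future__ import annotations

import math

import numpy as np

STABLE, FLUCTUATING, DISORDER = 0, 1, 2


def angle_oracle(vx: float, vy: float) -> float:
    """Degrees between (vx, vy) and the up-image vertical (0, -1), via
    atan2 of the cross/dot pair (no acos, no clipping)."""
    # g = (0, -1): dot = -vy; |cross| = |vx * (-1) - vy * 0| = |vx|
    return math.degrees(math.atan2(abs(vx), -vy))


def tendency_oracle(spine_angle, spine_ratio, all_=30.0, aul=50.0, rb=1.0):
    if spine_angle < all_ and spine_ratio > rb:
        return "T1"
    elif spine_angle > aul or spine_ratio < rb:
        return "T3"
    else:
        return "T2"


def steady_oracle(spine, thigh_l, thigh_r, calf_l, calf_r, al=30.0):
    case1 = spine < al and thigh_l < al
    case2 = spine < al and thigh_r < al
    case3 = calf_l < al and thigh_l < al
    case4 = calf_r < al and thigh_r < al
    pairs = int(case1) + int(case2) + int(case3) + int(case4)
    if case1 or case2 or case3 or case4:
        return "S1", pairs
    else:
        return "S2", pairs


def state_oracle(tendency: str, steady: str) -> int:
    if steady == "S1" and tendency == "T1":
        return STABLE
    elif steady == "S2" and tendency == "T3":
        return DISORDER
    else:
        return FLUCTUATING


def detector_oracle(states, unstable_run=3, stable_run=3, window_len=10):
    """Literal scanning loop for the time-continuous recognition algorithm.

    ``states`` is a list of 0/1/2 scores.  Returns one tuple per
    completed NSRP: (first trigger position, window positions, tau).
    """
    events = []
    n = len(states)
    i = 0
    while i < n:
        # scan for `unstable_run` consecutive unstable frames
        run = 0
        opened = False
        while i < n:
            if states[i] == STABLE:
                run = 0
            else:
                run += 1
                if run == unstable_run:
                    opened = True
                    break
            i += 1
        if not opened:
            break
        trigger_start = i - unstable_run + 1
        i += 1
        # accumulate the feature window; a stable run aborts it
        window = []
        stable = 0
        aborted = False
        while i < n and len(window) < window_len:
            window.append(i)
            stable = stable + 1 if states[i] == STABLE else 0
            i += 1
            if stable >= stable_run:
                aborted = True
                break
        if not aborted and len(window) == window_len:
            tau = sum(states[p] for p in window)
            events.append((trigger_start, window, tau))
    return events


def perceptron_separable(X, y, max_epochs=200):
    """Brute-force linear-separability check: a bias-augmented perceptron
    converges iff the labelled points are linearly separable."""
    X = np.hstack([np.asarray(X, dtype=float), np.ones((len(X), 1))])
    t = np.where(np.asarray(y) == 1, 1.0, -1.0)
    w = np.zeros(X.shape[1])
    scale = max(1.0, np.abs(X).max())
    for _ in range(max_epochs):
        mistakes = 0
        for xi, ti in zip(X, t):
            if ti * (w @ xi) <= 0:
                w = w + ti * xi / scale
                mistakes += 1
        if mistakes == 0:
            return True
    return False
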