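import json
import math

import numpy as np
import pytest

from dyadsync.pose_io import BODY25_INDICES, JOINTS, DyadRecording, PoseTimeSeries


def make_series(coords, fps=60.0, conf=None, person_id="p", smoothed=False):
    coords = np.asarray(coords, float)
    if conf is None:
        conf = np.ones(coords.shape[:2])
    s = PoseTimeSeries(person_id=person_id, coords=coords, conf=conf, fps=fps)
    s.smoothed = smoothed
    return s


def make_recording(coords_a, coords_b, fps=60.0, condition="mirroring", smoothed=False,
                   conf_a=None, conf_b=None):
    return DyadRecording(
        dyad_id="d0",
        leader_id="L0",
        condition=condition,
        series_a=make_series(coords_a, fps, conf_a, "a", smoothed),
        series_b=make_series(coords_b, fps, conf_b, "b", smoothed),
    )


def write_openpose_frame(path, people_xy, confidence=0.9):
    """Write one OpenPose-style BODY_25 JSON frame.

    ``people_xy`` is a list of (7, 2) arrays in canonical joint order; they
    are scattered into BODY_25 positions with zeros elsewhere.
    """
    people = []
    for xy in people_xy:
        flat = [0.0] * 75
        for canonical, b25 in enumerate(BODY25_INDICES):
            flat[3 * b25] = float(xy[canonical][0])
            flat[3 * b25 + 1] = float(xy[canonical][1])
            flat[3 * b25 + 2] = confidence
        people.append({"pose_keypoints_2d": flat})
    path.write_text(json.dumps({"version": 1.3, "people": people}))


def random_pose(rng, spread=50.0):
    """A random non-degenerate 7-joint pose."""
    return rng.uniform(-spread, spread, size=(len(JOINTS), 2))


def brute_force_sample_entropy(x, m=2, r_factor=0.2):
    """Independent O(N^2) double-loop oracle for sample entropy."""
    x = [float(v) for v in x]
    n = len(x)
    r = r_factor * float(np.std(x))
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


@pytest.fixture(scope="session")
def small_pool():
    """A 30-clip measured synthetic pool shared across model tests."""
    from dyadsync.synthetic import simulate_stimulus_pool

    return simulate_stimulus_pool(n_clips=30, prop_high=0.8, n_leaders=6, seed=11)
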