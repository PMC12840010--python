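import numpy as np
import pytest

from remapflow import synth
from remapflow.geometry import default_geometry
from remapflow.preprocess import compute_speed, extract_analysis_frames


@pytest.fixture(scope="session")
def geo():
    return default_geometry("discrimination")


@pytest.fixture(scope="session")
def geo_gen():
    return default_geometry("generalization")


@pytest.fixture(scope="session")
def small_session(geo):
    """12-min mixed-population discrimination session, shared across tests."""
    truth = synth.make_ground_truth(
        geo, seed=8, n_place=4, n_directional=2, n_background=2,
        remapping="rate-only", gain_b=0.5,
    )
    sess = synth.simulate_session(truth, geo, duration_min=12.0, n_trials=40,
                                  seed=9)
    return sess, truth


@pytest.fixture(scope="session")
def small_frames(small_session):
    sess, _ = small_session
    speed = compute_speed(sess.body_xy, sess.frame_rate)
    return extract_analysis_frames(sess, speed), speed


@pytest.fixture(scope="session")
def long_trajectory(geo):
    """40-min trajectory (body and head series) for coverage/statistics."""
    head, body = synth.simulate_trajectory(geo, 2400.0, seed=3)
    return head, body


def wrap(a):
    return np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi
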