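import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remapflow import synth
from remapflow.core import DirectionalSpec, GroundTruth, NeuronTruth
from remapflow.directional import (
    BIN_CENTERS,
    DirectionalMapper,
    classify_directional_cell,
    direction_bin,
    landmark_tuning_summary,
    rayleigh_vector,
    reconstruct_map,
    reconstruct_tuning,
    reconstruction_error,
    relative_running_direction,
    wall_categories,
    wrap_angle,
)
from remapflow.geometry import default_geometry
from remapflow.preprocess import compute_speed, extract_analysis_frames


def straight_path(start, direction, n=6, step=1.0):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.asarray(start) + step * np.outer(np.arange(n), d)


class TestRelativeDirection:
    @pytest.mark.parametrize("direction,expected_H", [
        ((0.0, 1.0), 0.0),       # at (0,-10) moving +y: toward the reference
        ((0.0, -1.0), -np.pi),   # moving away: boundary wraps to -pi
        ((1.0, 0.0), -np.pi / 2),  # moving +x: reference 90 deg to the left
        ((-1.0, 0.0), np.pi / 2),
    ])
    def test_geometry_cases(self, direction, expected_H):
        # the path is centred so the smoothed head sits exactly at (0, -10)
        # at index 2, where the bearing to the reference is exactly +90 deg
        d = np.asarray(direction, float)
        head = straight_path((0.0, -10.0) - 2 * d, direction)
        _, _, H, defined = relative_running_direction(head, (0.0, 0.0), 20.0)
        assert defined[2]
        assert H[2] == pytest.approx(expected_H, abs=1e-9)

    def test_zero_displacement_dropped(self):
        head = np.ones((10, 2))
        _, _, H, defined = relative_running_direction(head, (0.0, 0.0), 20.0)
        assert not defined.any()
        assert np.isnan(H).all()

    @given(
        st.floats(-15, 15), st.floats(-15, 15),      # start
        st.floats(-np.pi, np.pi - 1e-9),             # heading
        st.floats(-30, 30), st.floats(-30, 30),      # reference
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_vector_angle_oracle(self, x0, y0, theta, rx, ry):
        d = np.array([np.cos(theta), np.sin(theta)])
        head = straight_path((x0, y0), d)
        _, _, H, defined = relative_running_direction(head, (rx, ry), 20.0)
        i = 2
        b = np.array([rx, ry]) - head[i]
        if np.linalg.norm(b) < 1e-6 or not defined[i]:
            return
        # oracle: signed angle from bearing vector to displacement vector
        oracle = np.arctan2(b[0] * d[1] - b[1] * d[0], b @ d)
        assert wrap_angle(H[i] - oracle) == pytest.approx(0.0, abs=1e-9)


class TestRayleigh:
    def test_uniform_curve_zero_length(self):
        L, _ = rayleigh_vector(np.ones(8))
        assert L == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_unit_length(self):
        curve = np.zeros(8)
        curve[3] = 5.0
        L, ang = rayleigh_vector(curve)
        assert L == pytest.approx(1.0)
        assert ang == pytest.approx(BIN_CENTERS[3])

    def test_length_invariant_under_rotation(self):
        rng = np.random.default_rng(0)
        curve = rng.random(8) + 0.5
        L0, a0 = rayleigh_vector(curve)
        for k in range(1, 8):
            Lk, ak = rayleigh_vector(np.roll(curve, k))
            assert Lk == pytest.approx(L0)
            assert wrap_angle(ak - a0 - k * np.pi / 4) == pytest.approx(0, abs=1e-9)

    def test_empty_bins_excluded(self):
        curve = np.full(8, np.nan)
        curve[0] = 2.0
        L, ang = rayleigh_vector(curve)
        assert L == pytest.approx(1.0) and ang == pytest.approx(0.0)

    def test_direction_bins_cover_circle(self):
        H = np.linspace(-np.pi, np.pi - 1e-9, 1000)
        b = direction_bin(H)
        assert set(b) == set(range(8))


class TestReconstruction:
    def test_constant_spatial_map_gives_constant_tuning(self):
        rng = np.random.default_rng(1)
        joint = rng.random((50, 8))
        r_xy = np.full(50, 3.0)
        rH = reconstruct_tuning(joint, r_xy)
        np.testing.assert_allclose(rH, 3.0, atol=1e-9)

    def test_constant_tuning_gives_constant_map(self):
        rng = np.random.default_rng(2)
        joint = rng.random((50, 8))
        r_H = np.full(8, 2.0)
        np.testing.assert_allclose(reconstruct_map(joint, r_H), 2.0, atol=1e-9)

    def test_flat_observed_map_error_undefined(self):
        obs = np.full(8, 1.0)
        rec = np.full(8, 1.0)
        assert np.isnan(reconstruction_error(obs, rec))

    def test_perfect_reconstruction_zero_error(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert reconstruction_error(obs, obs.copy()) == pytest.approx(0.0)

    def test_nan_rows_excluded(self):
        joint = np.ones((4, 8))
        r_xy = np.array([1.0, np.nan, 1.0, 1.0])
        rH = reconstruct_tuning(joint, r_xy)
        np.testing.assert_allclose(rH, 1.0)


@pytest.fixture(scope="module")
def tuned_session():
    geo = default_geometry("discrimination")
    truth = GroundTruth(neurons=[
        NeuronTruth("directional", 15.0,
                    directional=DirectionalSpec(mu=np.pi / 4, kappa=2.0,
                                                depth=0.8)),
        NeuronTruth("background", 15.0),
    ])
    sess = synth.simulate_session(truth, geo, duration_min=20.0, n_trials=60,
                                  seed=17)
    speed = compute_speed(sess.body_xy, sess.frame_rate)
    frames = extract_analysis_frames(sess, speed)
    mappers = {c: DirectionalMapper(sess, frames, c) for c in sess.contexts}
    return sess, mappers


class TestMapper:
    def test_planted_angle_recovered_within_one_bin(self, tuned_session):
        sess, mappers = tuned_session
        best = None
        for c, mp in mappers.items():
            _, L, ang = mp.tuning(mp.event_positions(sess.events[0]))
            if best is None or L > best[0]:
                best = (L, ang)
        assert abs(wrap_angle(best[1] - np.pi / 4)) <= np.pi / 4

    def test_tuned_cell_has_larger_L_than_untuned(self, tuned_session):
        sess, mappers = tuned_session
        mp = list(mappers.values())[0]
        _, L_tuned, _ = mp.tuning(mp.event_positions(sess.events[0]))
        _, L_flat, _ = mp.tuning(mp.event_positions(sess.events[1]))
        assert L_tuned > L_flat

    def test_nulls_reproducible_and_distinct(self, tuned_session):
        sess, mappers = tuned_session
        mp = list(mappers.values())[0]
        pos = mp.event_positions(sess.events[0])
        n1a, n2a = mp.nulls(pos, n=50, seed=3)
        n1b, n2b = mp.nulls(pos, n=50, seed=3)
        np.testing.assert_array_equal(n1a, n1b)
        np.testing.assert_array_equal(n2a, n2b)
        assert not np.array_equal(n1a, n2a)  # independent offset draws

    def test_classification_rule(self, tuned_session):
        sess, mappers = tuned_session
        res = classify_directional_cell(0, mappers, sess.events[0],
                                        is_place_cell=False, n_shuffles=200,
                                        seed=7)
        # conjunctive requires the place flag
        assert not res.is_conjunctive
        res_pc = classify_directional_cell(0, mappers, sess.events[0],
                                           is_place_cell=True, n_shuffles=200,
                                           seed=7)
        assert res_pc.is_conjunctive == res_pc.is_dc

    def test_event_floor_excludes(self, tuned_session):
        sess, mappers = tuned_session
        res = classify_directional_cell(0, mappers, sess.events[0][:9],
                                        n_shuffles=50, seed=7)
        assert not res.is_dc and res.tuned_contexts == []


class TestLandmarks:
    def test_shared_wall_excluded_in_discrimination(self):
        geo = default_geometry("discrimination")
        cats, chance = wall_categories(geo)
        # wall 0 is both context-B reward and context-A light cue
        assert cats[0] is None
        assert sum(v is None for v in cats.values()) == 1
        assert sum(chance.values()) == pytest.approx(1.0)
        assert chance["light cue"] == pytest.approx(3 / 7)
        assert chance["reward"] == pytest.approx(1 / 7)

    def test_generalization_categories(self):
        geo = default_geometry("generalization")
        cats, chance = wall_categories(geo)
        assert cats[2] == "reward"
        assert sum(v == "light cue" for v in cats.values()) == 4
        assert chance["other"] == pytest.approx(3 / 8)

    def test_summary_counts_tuned_cells(self, tuned_session):
        sess, mappers = tuned_session
        res = classify_directional_cell(0, mappers, sess.events[0],
                                        n_shuffles=200, seed=7)
        out = landmark_tuning_summary([res], default_geometry("discrimination"))
        total = sum(out["composition"].values())
        assert total == (1 if res.is_dc else 0)
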