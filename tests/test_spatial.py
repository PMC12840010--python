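import numpy as np
import pytest

from remapflow.spatial import (
    ContextMapper,
    MapGrid,
    RateMap,
    classify_place_cell,
    fisher_z,
    masked_pearson,
    remapping_correlation,
)


@pytest.fixture(scope="module")
def mapper(small_session, small_frames):
    sess, _ = small_session
    frames, _ = small_frames
    return sess, {c: ContextMapper(sess, frames, c) for c in sess.contexts}


class TestRateMap:
    def test_zero_events_gives_zero_map(self, mapper):
        sess, mp = mapper
        rm = mp["A"].rate_map(np.zeros(0, dtype=int))
        assert np.all(rm.rate[rm.valid] == 0)
        assert np.isnan(rm.rate[~rm.valid]).all()

    def test_single_bin_rate_matches_definition_unsmoothed(self, small_session,
                                                           small_frames, geo):
        # with a vanishing smoothing kernel the rate in a bin must equal
        # events / occupancy-minutes exactly
        sess, _ = small_session
        frames, _ = small_frames
        grid = MapGrid(geo, bin_cm=2.0, sigma_cm=1e-6)
        m = ContextMapper(sess, frames, "A", grid=grid)
        pos = np.arange(min(50, m.T))  # events on the first analyzed frames
        rm = m.rate_map(pos)
        counts = np.bincount(m.binidx[pos], minlength=grid.n_bins)
        counts = counts.reshape(grid.n, grid.n)
        occ_min = m.occ_s["all"] / 60.0
        sel = rm.valid & (counts > 0)
        np.testing.assert_allclose(rm.rate[sel], counts[sel] / occ_min[sel],
                                   rtol=1e-6)

    def test_smoothing_conserves_counts(self, mapper):
        sess, mp = mapper
        m = mp["A"]
        counts = np.zeros((m.grid.n, m.grid.n))
        valid = m.valid["all"]
        rng = np.random.default_rng(0)
        counts[valid] = rng.poisson(2.0, valid.sum())
        sm = m.grid.smooth(counts, valid)
        np.testing.assert_allclose(sm.sum(), counts[valid].sum(), rtol=1e-4)

    def test_argmax_recovers_planted_center(self, small_session, mapper):
        sess, truth = small_session
        _, mp = mapper
        # neuron 0 is a planted place cell
        m = mp["A"]
        rm = m.rate_map(m.event_positions(sess.events[0]))
        est = rm.argmax_xy()
        true = truth.neurons[0].fields[0].center
        assert np.hypot(est[0] - true[0], est[1] - true[1]) <= 4.0


class TestStability:
    def test_identical_maps_give_r_one(self):
        rng = np.random.default_rng(1)
        a = rng.random((10, 10))
        valid = np.ones((10, 10), bool)
        assert masked_pearson(a, a.copy(), valid) == pytest.approx(1.0)

    def test_constant_half_map_undefined(self):
        a = np.ones((5, 5))
        b = np.random.default_rng(2).random((5, 5))
        assert np.isnan(masked_pearson(a, b, np.ones((5, 5), bool)))

    def test_stability_of_planted_cells_exceeds_background(self, small_session,
                                                           mapper):
        sess, truth = small_session

        def best_r(ni):
            _, mp = mapper
            vals = [mp[c].stability(mp[c].event_positions(sess.events[ni]))[2]
                    for c in mp]
            vals = [v for v in vals if np.isfinite(v)]
            return max(vals) if vals else np.nan

        place = [best_r(ni) for ni, nt in enumerate(truth.neurons)
                 if nt.cell_class == "place"]
        background = [best_r(ni) for ni, nt in enumerate(truth.neurons)
                      if nt.cell_class == "background"]
        assert sum(r > 0.4 for r in place if np.isfinite(r)) >= len(place) - 1
        assert all(not (r > 0.4) for r in background)

    def test_fisher_z_monotone(self):
        r = np.array([-0.5, 0.0, 0.3, 0.9])
        assert np.all(np.diff(fisher_z(r)) > 0)


class TestShuffleNull:
    def test_reproducible_under_seed(self, small_session, mapper):
        sess, _ = small_session
        _, mp = mapper
        m = mp["A"]
        pos = m.event_positions(sess.events[0])
        a = m.shuffle_null(pos, n=50, seed=5)
        b = m.shuffle_null(pos, n=50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_offsets_respect_margin(self, mapper):
        _, mp = mapper
        m = mp["A"]
        off = m.shuffle_offsets(500, np.random.default_rng(0))
        assert np.all(off >= 60 * 20)
        assert np.all(off <= m.T - 60 * 20)

    def test_batch_matches_single_shuffle(self, small_session, mapper):
        sess, _ = small_session
        _, mp = mapper
        m = mp["A"]
        pos = m.event_positions(sess.events[0])
        shifted = (pos + 1500) % m.T
        batch = m.stability_batch(shifted[None, :])[0]
        single = m.stability(shifted)[2]
        assert batch == pytest.approx(single, abs=1e-10)


class TestClassification:
    def test_stable_cell_with_enough_events_is_place_cell(self):
        r = classify_place_cell(0, {"A": 0.9}, {"A": 0.9}, {"A": 0.9},
                                {"A": 0.3}, total_events=50)
        assert r.is_place_cell

    def test_event_floor_excludes(self):
        r = classify_place_cell(0, {"A": 0.9}, {"A": 0.9}, {"A": 0.9},
                                {"A": 0.3}, total_events=9)
        assert not r.is_place_cell

    def test_absolute_floor_applies_even_above_null(self):
        r = classify_place_cell(0, {"A": 0.38}, {"A": 0.38}, {"A": 0.38},
                                {"A": 0.2}, total_events=50)
        assert not r.is_place_cell

    def test_one_passing_context_suffices(self):
        r = classify_place_cell(0, {"A": 0.1, "B": 0.8}, {"A": 0.1, "B": 0.8},
                                {"A": 0.1, "B": 0.8},
                                {"A": 0.3, "B": 0.3}, total_events=50)
        assert r.is_place_cell and r.passes == {"A": False, "B": True}

    def test_undefined_stability_fails(self):
        r = classify_place_cell(0, {"A": np.nan}, {"A": np.nan}, {"A": np.nan},
                                {"A": 0.3}, total_events=50)
        assert not r.is_place_cell


class TestRemappingCorrelation:
    def _map(self, rate, valid, grid):
        return RateMap(rate=rate, occupancy_s=np.ones_like(rate), valid=valid,
                       context="A", grid=grid)

    def test_identity_gives_one(self, geo):
        grid = MapGrid(geo)
        rng = np.random.default_rng(3)
        rate = rng.random((grid.n, grid.n))
        valid = grid.inside
        a = self._map(rate, valid, grid)
        b = self._map(rate.copy(), valid, grid)
        assert remapping_correlation(a, b) == pytest.approx(1.0)

    def test_symmetric(self, geo):
        grid = MapGrid(geo)
        rng = np.random.default_rng(4)
        a = self._map(rng.random((grid.n, grid.n)), grid.inside, grid)
        b = self._map(rng.random((grid.n, grid.n)), grid.inside, grid)
        assert remapping_correlation(a, b) == pytest.approx(
            remapping_correlation(b, a))

    def test_shuffled_bins_decorrelate(self, geo):
        grid = MapGrid(geo)
        rng = np.random.default_rng(5)
        rate = rng.random((grid.n, grid.n))
        a = self._map(rate, grid.inside, grid)
        rs = []
        for _ in range(50):
            perm = rate.copy()
            idx = np.flatnonzero(grid.inside.ravel())
            vals = perm.ravel()[idx]
            rng.shuffle(vals)
            flat = perm.ravel()
            flat[idx] = vals
            rs.append(remapping_correlation(
                a, self._map(flat.reshape(rate.shape), grid.inside, grid)))
        assert abs(np.mean(rs)) < 0.1

    def test_insufficient_shared_bins_undefined(self, geo):
        grid = MapGrid(geo)
        rate = np.ones((grid.n, grid.n))
        few = np.zeros((grid.n, grid.n), bool)
        few[0, :5] = True
        a = self._map(rate, few, grid)
        b = self._map(rate, few, grid)
        assert np.isnan(remapping_correlation(a, b))
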