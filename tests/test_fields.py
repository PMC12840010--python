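import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remapflow.fields import (
    PlaceField,
    apply_field_overrides,
    assign_reward_fields,
    field_distance_histogram,
    firing_preference,
    local_maxima_prominence,
    preference_category,
    rate_overlap_score,
    segment_place_fields,
    weighted_gmm,
)
from remapflow.spatial import MapGrid, RateMap

rates = st.floats(min_value=0.0, max_value=50.0)


class TestRateOverlap:
    @pytest.mark.parametrize("r1,r2,expected", [
        (2.0, 2.0, 1.0),
        (3.0, 1.0, 0.5),
        (5.0, 0.0, 0.0),
        (1.0, 1.0, 1.0),
    ])
    def test_exact_values(self, r1, r2, expected):
        assert rate_overlap_score(r1, r2) == pytest.approx(expected)

    def test_zero_rates_undefined(self):
        assert np.isnan(rate_overlap_score(0.0, 0.0))

    @given(rates, rates)
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_symmetric(self, r1, r2):
        s = rate_overlap_score(r1, r2)
        if np.isnan(s):
            assert r1 + r2 == 0
        else:
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(rate_overlap_score(r2, r1))
            if s == pytest.approx(1.0):
                assert r1 == pytest.approx(r2, rel=1e-9, abs=1e-12)


class TestFiringPreference:
    @pytest.mark.parametrize("r1,r2,k,fp,cat", [
        (4.0, 1.0, 1, 0.6, "match"),
        (4.0, 1.0, 2, -0.6, "mismatch"),
        (1.0, 4.0, 1, -0.6, "mismatch"),
        (2.0, 2.0, 1, 0.0, "neutral"),
        (1.2, 1.0, 1, 0.2 / 2.2, "neutral"),
    ])
    def test_sign_table(self, r1, r2, k, fp, cat):
        got = firing_preference(r1, r2, k)
        assert got == pytest.approx(fp)
        assert preference_category(got) == cat

    @given(rates, rates)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_context_and_k_swap(self, r1, r2):
        a = firing_preference(r1, r2, 1)
        b = firing_preference(r2, r1, 2)
        if np.isfinite(a):
            assert a == pytest.approx(-(-b))  # swap context AND k: unchanged
            assert firing_preference(r1, r2, 2) == pytest.approx(-a)


class TestPeakDetection:
    def test_flat_map_has_no_prominent_peaks(self):
        rate = np.ones((10, 10))
        valid = np.ones((10, 10), bool)
        peaks = [p for p in local_maxima_prominence(rate, valid) if p[2] >= 1.0]
        assert len(peaks) <= 1  # at most the global plateau representative

    def test_two_peaks_with_known_prominence(self):
        # a connected ridge: 5 - 1 (saddle) - 3; the minor peak's prominence
        # is its height above the saddle, the major one's is height above
        # the surrounding floor
        rate = np.zeros((5, 5))
        valid = np.ones((5, 5), bool)
        rate[2, 1], rate[2, 2], rate[2, 3] = 5.0, 1.0, 3.0
        peaks = local_maxima_prominence(rate, valid)
        main = [p for p in peaks if p[0] == 2 * 5 + 1][0]
        minor = [p for p in peaks if p[0] == 2 * 5 + 3][0]
        assert main[1] == 5.0 and main[2] == pytest.approx(5.0)
        assert minor[1] == 3.0 and minor[2] == pytest.approx(3.0 - 1.0)

    def test_plateau_collapses_to_earliest_index(self):
        rate = np.zeros((6, 6))
        valid = np.ones((6, 6), bool)
        rate[2, 2] = rate[2, 3] = 4.0
        peaks = [p for p in local_maxima_prominence(rate, valid) if p[2] >= 1]
        assert len(peaks) == 1
        assert peaks[0][0] == 2 * 6 + 2


class TestWeightedGMM:
    def test_recovers_two_weighted_blobs(self):
        rng = np.random.default_rng(0)
        xa = rng.normal([-8, 0], 2.0, (300, 2))
        xb = rng.normal([8, 4], 2.0, (150, 2))
        X = np.vstack([xa, xb])
        w = np.ones(len(X))
        means, covs, mix, resp = weighted_gmm(
            X, w, means_init=np.array([[-6.0, 1.0], [6.0, 3.0]]))
        order = np.argsort(means[:, 0])
        np.testing.assert_allclose(means[order[0]], [-8, 0], atol=1.0)
        np.testing.assert_allclose(means[order[1]], [8, 4], atol=1.0)
        assert mix[order[0]] > mix[order[1]]  # twice the weight on blob a


def _gaussian_map(grid, centers, amps, width=4.0):
    xy = grid.bin_centers()
    rate = np.zeros(grid.n_bins)
    for c, a in zip(centers, amps):
        d2 = ((xy - np.asarray(c)) ** 2).sum(axis=1)
        rate += a * np.exp(-d2 / (2 * width**2))
    rate = rate.reshape(grid.n, grid.n)
    valid = grid.inside
    return RateMap(rate=np.where(valid, rate, np.nan),
                   occupancy_s=np.full_like(rate, 5.0), valid=valid,
                   context="pooled", grid=grid)


class TestSegmentation:
    def test_flat_map_yields_no_fields(self, geo):
        grid = MapGrid(geo)
        rm = _gaussian_map(grid, [], [])
        assert segment_place_fields(rm, np.zeros(grid.n_bins)) == []

    def test_single_gaussian_single_field(self, geo):
        grid = MapGrid(geo)
        rm = _gaussian_map(grid, [(-5.0, 3.0)], [10.0])
        counts = np.where(np.nan_to_num(rm.rate) > 2, 3, 0).ravel()
        flds = segment_place_fields(rm, counts)
        assert len(flds) == 1
        f = flds[0]
        assert np.hypot(f.center[0] + 5.0, f.center[1] - 3.0) < 2.0
        # the 20 % cutoff keeps only pixels at >= 2 events/min
        assert np.nanmin(rm.rate.ravel()[f.pixels]) >= 0.2 * f.peak_rate - 1e-9

    def test_two_separated_gaussians_disjoint_fields(self, geo):
        grid = MapGrid(geo)
        rm = _gaussian_map(grid, [(-9.0, 0.0), (9.0, 2.0)], [10.0, 8.0])
        counts = np.where(np.nan_to_num(rm.rate) > 2, 3, 0).ravel()
        flds = segment_place_fields(rm, counts)
        assert len(flds) == 2
        assert len(np.intersect1d(flds[0].pixels, flds[1].pixels)) == 0

    def test_low_peak_field_discarded(self, geo):
        grid = MapGrid(geo)
        rm = _gaussian_map(grid, [(0.0, 0.0)], [0.8])  # below 1 event/min
        counts = np.full(grid.n_bins, 5)
        assert segment_place_fields(rm, counts) == []

    def test_event_floor_discards(self, geo):
        grid = MapGrid(geo)
        rm = _gaussian_map(grid, [(0.0, 0.0)], [10.0])
        counts = np.zeros(grid.n_bins)  # one attributed event only
        counts[grid.bin_index(np.array([[0.0, 0.0]]))[0]] = 1
        assert segment_place_fields(rm, counts) == []


class TestRewardAssignment:
    def _field(self, center):
        return PlaceField(neuron=0, field_id=0, pixels=np.array([0]),
                          center=center, size_cm2=4.0, peak_rate=2.0)

    def test_center_at_port_is_reward_field(self, geo):
        port = geo.port_position(geo.reward_wall["A"])
        f = assign_reward_fields([self._field(tuple(port))], geo)[0]
        assert f.reward_distance == pytest.approx(0.0)
        assert f.distance_class == "reward"

    def test_12cm_center_in_first_bin(self, geo):
        port = geo.port_position(geo.reward_wall["A"])
        towards = port / np.linalg.norm(port)
        f = assign_reward_fields(
            [self._field(tuple(port - 12.0 * towards))], geo)[0]
        assert f.distance_class == "10-15"

    def test_closer_of_two_rewards_counts(self, geo):
        # discrimination has ports at W and E: a centre 9 cm from the E port
        # is a reward field regardless of its distance to the W port
        port_e = geo.port_position(geo.reward_wall["B"])
        center = (port_e[0] - 9.0, port_e[1])
        f = assign_reward_fields([self._field(center)], geo)[0]
        assert f.distance_class == "reward"
        assert f.reward_index == 2

    def test_generalization_single_reward_index(self, geo_gen):
        port = geo_gen.port_position(geo_gen.reward_wall["C"])
        f = assign_reward_fields([self._field(tuple(port))], geo_gen)[0]
        assert f.reward_index == 1

    def test_histogram_counts(self, geo):
        ports = [geo.port_position(geo.reward_wall[c]) for c in "AB"]
        fields = [self._field(tuple(p)) for p in ports]
        fields.append(self._field((0.0, 0.0)))
        assign_reward_fields(fields, geo)
        h = field_distance_histogram(fields)
        assert h["reward"] == 2
        assert sum(h.values()) == 3


class TestOverrides:
    def _field(self, fid, n_pix):
        return PlaceField(neuron=0, field_id=fid,
                          pixels=np.arange(fid * 100, fid * 100 + n_pix),
                          center=(0.0, 0.0), size_cm2=4.0 * n_pix,
                          peak_rate=2.0, n_events=5)

    def test_drop(self):
        out = apply_field_overrides([self._field(0, 5), self._field(1, 3)],
                                    {"drop": [1]})
        assert [f.field_id for f in out] == [0]

    def test_merge_keeps_larger(self):
        out = apply_field_overrides([self._field(0, 5), self._field(1, 3)],
                                    {"merge": [[0, 1]]})
        assert len(out) == 1
        assert len(out[0].pixels) == 8

    def test_no_overrides_identity(self):
        fields = [self._field(0, 5)]
        assert apply_field_overrides(fields, None) is fields
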