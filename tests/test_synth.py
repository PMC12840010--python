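import numpy as np
import pytest
from scipy import stats

from remapflow import synth
from remapflow.core import FieldSpec, GroundTruth, NeuronTruth
from remapflow.io import read_dataset, write_dataset
from remapflow.preprocess import detect_events, label_trace_stability
from remapflow.spatial import MapGrid


class TestTrajectory:
    def test_zero_duration_gives_empty_series(self, geo):
        head, body = synth.simulate_trajectory(geo, 0.0, seed=0)
        assert head.shape == (0, 2) and body.shape == (0, 2)

    def test_deterministic_under_seed(self, geo):
        a = synth.simulate_trajectory(geo, 30.0, seed=7)
        b = synth.simulate_trajectory(geo, 30.0, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_stays_inside_arena(self, long_trajectory, geo):
        head, body = long_trajectory
        assert geo.contains(body).all()
        assert geo.contains(head).all()

    def test_covers_arena_in_40_minutes(self, long_trajectory, geo):
        _, body = long_trajectory
        grid = MapGrid(geo)
        occ = np.bincount(grid.bin_index(body), minlength=grid.n_bins)
        occ_s = occ.reshape(grid.n, grid.n) / 20.0
        frac = (occ_s[grid.inside] >= 0.5).mean()
        assert frac >= 0.9

    def test_contains_resting_and_running_bouts(self, long_trajectory):
        from remapflow.preprocess import compute_speed

        _, body = long_trajectory
        speed = compute_speed(body, 20.0)
        assert (speed < 2.0).mean() > 0.01
        assert (speed > 2.0).mean() > 0.5

    def test_negative_duration_rejected(self, geo):
        with pytest.raises(ValueError):
            synth.simulate_trajectory(geo, -1.0, seed=0)


class TestTrialSequence:
    def test_contexts_balanced_within_one(self, geo, long_trajectory):
        _, body = long_trajectory
        trials = synth.simulate_trial_sequence(geo, body, 24, seed=1)
        counts = {c: sum(t.context == c for t in trials) for c in "AB"}
        assert abs(counts["A"] - counts["B"]) <= 1

    def test_schedule_prefixes_balanced(self):
        rng = np.random.default_rng(0)
        sched = synth.balanced_context_schedule(["A", "B"], 31, rng)
        for i in range(1, 32):
            diff = abs(sched[:i].count("A") - sched[:i].count("B"))
            assert diff <= 1

    def test_perfect_agent_all_correct(self, geo, long_trajectory):
        _, body = long_trajectory
        trials = synth.simulate_trial_sequence(
            geo, body, 20, seed=2, policy=synth.AgentPolicy("perfect"))
        assert all(t.outcome == "correct" for t in trials)

    def test_random_port_agent_near_one_eighth(self, geo):
        # long trajectory so the binomial sample is big enough
        _, body = synth.simulate_trajectory(geo, 3600.0, seed=11)
        trials = synth.simulate_trial_sequence(
            geo, body, 200, seed=3, policy=synth.AgentPolicy("random-port"))
        n = len(trials)
        k = sum(t.outcome == "correct" for t in trials)
        lo = stats.binom.ppf(0.0005, n, 1 / 8)
        hi = stats.binom.ppf(0.9995, n, 1 / 8)
        assert lo <= k <= hi

    def test_trial_invariants(self, geo, long_trajectory):
        _, body = long_trajectory
        trials = synth.simulate_trial_sequence(geo, body, 30, seed=4)
        last_end = -1
        for t in trials:
            t.validate(20.0)
            assert t.start_frame >= last_end
            last_end = t.end_frame

    def test_truncation_warns(self, geo):
        _, body = synth.simulate_trajectory(geo, 120.0, seed=5)
        with pytest.warns(UserWarning, match="exhausted"):
            synth.simulate_trial_sequence(geo, body, 50, seed=6)


class TestEventTrains:
    def test_silent_truth_gives_no_events(self, small_session, geo):
        sess, _ = small_session
        truth = GroundTruth(neurons=[NeuronTruth("background", 0.0)])
        # amplitude must be positive, so a zero-rate cell has no fields at all
        ev = synth.simulate_event_trains(truth, geo, sess.head_xy, sess.trials,
                                         seed=0)
        assert len(ev[0]) == 0

    def test_baseline_rate_poisson_count(self, geo, long_trajectory):
        head, body = long_trajectory
        truth = GroundTruth(neurons=[NeuronTruth("background", 6.0)])
        ev = synth.simulate_event_trains(truth, geo, head, [], seed=12,
                                         body_xy=body)
        expected = 6.0 * 40.0
        assert abs(len(ev[0]) - expected) <= 3 * np.sqrt(expected)

    def test_zero_gain_silences_field_in_that_context(self, geo):
        truth = GroundTruth(neurons=[NeuronTruth(
            "place", 0.0,
            [FieldSpec(center=(0.0, 0.0), width=6.0, amplitude=30.0,
                       gain={"A": 1.0, "B": 0.0})])])
        sess = synth.simulate_session(truth, geo, duration_min=20.0,
                                      n_trials=60, seed=13)
        code = {t.trial_index: t.context for t in sess.trials}
        trial_of = sess.trial_of_frame()
        ev_trials = trial_of[sess.events[0]]
        in_b = sum(code[t] == "B" for t in ev_trials if t >= 0)
        in_a = sum(code[t] == "A" for t in ev_trials if t >= 0)
        assert in_a > 20
        assert in_b == 0  # baseline 0, gain 0: context B is silent


class TestCalciumTraces:
    def test_stable_noise_trace_passes_qc(self):
        dff, _ = synth.simulate_calcium_traces([np.array([], int)], 20 * 60 * 8,
                                               seed=1, stability_mode="stable")
        assert label_trace_stability(dff[0], 20.0) == "stable"

    def test_unstable_mode_fails_qc(self):
        dff, _ = synth.simulate_calcium_traces([np.array([], int)], 20 * 60 * 8,
                                               seed=1, stability_mode="unstable")
        assert label_trace_stability(dff[0], 20.0) == "unstable"

    def test_each_event_yields_one_deconvolved_peak(self):
        events = np.array([100, 340, 1000, 4000])
        _, deconv = synth.simulate_calcium_traces([events], 20 * 60 * 5, seed=2)
        detected = detect_events(deconv[0], min_prominence=0.5)
        assert len(detected) == len(events)
        assert np.all(np.abs(detected - events) <= 1)


class TestDatasetIO:
    def test_write_read_roundtrip(self, small_session, tmp_path):
        sess, truth = small_session
        write_dataset(sess, tmp_path / "d", truth=truth, config={"seed": 9})
        sess2, truth2, config = read_dataset(tmp_path / "d")
        np.testing.assert_allclose(sess2.head_xy, sess.head_xy, atol=1e-9)
        np.testing.assert_allclose(sess2.body_xy, sess.body_xy, atol=1e-9)
        assert len(sess2.trials) == len(sess.trials)
        for a, b in zip(sess.trials, sess2.trials):
            assert (a.context, a.start_frame, a.trigger_frame, a.end_frame,
                    a.outcome, a.visited_port) == \
                   (b.context, b.start_frame, b.trigger_frame, b.end_frame,
                    b.outcome, b.visited_port)
        for a, b in zip(sess.events, sess2.events):
            np.testing.assert_array_equal(a, b)
        assert config["seed"] == 9

    def test_truth_roundtrip_joins_by_neuron(self, small_session, tmp_path):
        sess, truth = small_session
        write_dataset(sess, tmp_path / "d", truth=truth)
        _, truth2, _ = read_dataset(tmp_path / "d")
        assert truth2.n_neurons == truth.n_neurons
        for a, b in zip(truth.neurons, truth2.neurons):
            assert a.cell_class == b.cell_class
            assert len(a.fields) == len(b.fields)
            for fa, fb in zip(a.fields, b.fields):
                np.testing.assert_allclose(fa.center, fb.center)
                assert fa.gain == fb.gain

    def test_empty_neuron_set(self, geo, tmp_path):
        head, body = synth.simulate_trajectory(geo, 30.0, seed=1)
        from remapflow.core import SessionData

        sess = SessionData(geometry=geo, frame_rate=20.0, head_xy=head,
                           body_xy=body, trials=[], events=[])
        write_dataset(sess, tmp_path / "d")
        sess2, truth2, _ = read_dataset(tmp_path / "d")
        assert sess2.n_neurons == 0 and truth2 is None
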