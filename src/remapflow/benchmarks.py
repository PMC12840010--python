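"""Calibration and parameter-recovery studies on synthetic sessions.

Each study simulates sessions with planted ground truth, runs the exact
analysis path used on real data, and reports recovery / calibration
statistics.  These are the package's validation experiments: the acceptance
tests and the acceptance script both call them.

Problem sizes are desk-scale (40-min sessions, populations of 50-200
cells) — large enough for stable percentages, small enough to run on one
CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .core import DirectionalSpec, FieldSpec, GroundTruth, NeuronTruth
from .decode import (
    build_decoder_frames,
    decode_by_subset,
    fit_context_decoder,
    label_shuffled_accuracy,
)
from .directional import DirectionalMapper, classify_directional_cell
from .fields import field_mean_rates, rate_overlap_score, segment_place_fields
from .geometry import default_geometry
from .pipeline import PooledMapper
from .preprocess import compute_speed, extract_analysis_frames
from .spatial import MapGrid, analyze_place_cells, remapping_correlation


def _prepare(truth, seed, duration_min=40.0, n_trials=100, motion=None):
    geo = default_geometry("discrimination")
    sess = synth.simulate_session(truth, geo, duration_min=duration_min,
                                  n_trials=n_trials, seed=seed, motion=motion)
    speed = compute_speed(sess.body_xy, sess.frame_rate)
    frames = extract_analysis_frames(sess, speed)
    return geo, sess, frames


# ---------------------------------------------------------------------------
# Null calibration: false-positive rates on homogeneous Poisson cells


def null_calibration(seed: int, n_cells: int = 200, n_shuffles: int = 500,
                     bin_cm: float = 4.0) -> dict:
    """Place-cell and DC screens applied to non-coding Poisson cells.

    Both false-positive rates should stay at or below 10 % (two contexts at
    the 5 % shuffle level, tightened further by the absolute 0.4 stability
    floor and, for DCs, the both-nulls and index rules).  Maps use the
    coarser 4-cm bins to keep 200 x 500 shuffles cheap.
    """
    geo = default_geometry("discrimination")
    truth = synth.make_ground_truth(geo, seed=seed, n_background=n_cells)
    _, sess, frames = _prepare(truth, seed + 1)
    grid = MapGrid(geo, bin_cm=bin_cm)
    results, _ = analyze_place_cells(sess, frames, grid=grid,
                                     n_shuffles=n_shuffles, seed=seed + 2)
    place_fp = sum(r.is_place_cell for r in results)
    dm = {c: DirectionalMapper(sess, frames, c, grid=grid) for c in sess.contexts}
    dc_fp = sum(
        classify_directional_cell(ni, dm, sess.events[ni],
                                  n_shuffles=n_shuffles,
                                  seed=seed + 3 + 31 * ni).is_dc
        for ni in range(n_cells)
    )
    return {
        "n_cells": n_cells,
        "place_fpr_pct": 100.0 * place_fp / n_cells,
        "dc_fpr_pct": 100.0 * dc_fp / n_cells,
    }


# ---------------------------------------------------------------------------
# Field-count and field-centre recovery


def field_recovery(seed: int, n_cells: int = 100, min_sep: float = 15.0) -> dict:
    """Segmentation recovery on cells with 1-3 planted fields >= 15 cm apart."""
    geo = default_geometry("discrimination")
    rng = np.random.default_rng(seed)

    def rand_center():
        while True:
            c = rng.uniform(-geo.radius, geo.radius, 2)
            if geo.contains(c, margin=4.0)[0]:
                return c

    neurons, ks = [], []
    for _ in range(n_cells):
        k = int(rng.integers(1, 4))
        centers = []
        while len(centers) < k:
            c = rand_center()
            if all(np.hypot(*(c - o)) >= min_sep for o in centers):
                centers.append(c)
        neurons.append(
            NeuronTruth(
                "place", 0.1,
                [FieldSpec(center=tuple(c), width=4.5, amplitude=20.0,
                           gain={"A": 1.0, "B": 1.0}) for c in centers],
            )
        )
        ks.append(k)
    truth = GroundTruth(neurons=neurons)
    _, sess, frames = _prepare(truth, seed + 1)
    pm = PooledMapper(sess, frames)
    n_count_ok = 0
    center_err = []
    for ni, k in enumerate(ks):
        rmap, counts = pm.rate_map_and_counts(sess.events[ni])
        flds = segment_place_fields(rmap, counts, neuron=ni)
        n_count_ok += len(flds) == k
        for f in neurons[ni].fields:
            if flds:
                center_err.append(
                    min(np.hypot(g.center[0] - f.center[0],
                                 g.center[1] - f.center[1]) for g in flds)
                )
    center_err = np.asarray(center_err)
    return {
        "n_cells": n_cells,
        "count_accuracy_pct": 100.0 * n_count_ok / n_cells,
        "center_within_3cm_pct": 100.0 * float((center_err <= 3.0).mean()),
        "median_center_error_cm": float(np.median(center_err)),
    }


# ---------------------------------------------------------------------------
# Remapping recovery: spatial correlation and rate overlap


def _population_median_r(truth, seed):
    _, sess, frames = _prepare(truth, seed)
    results, mappers = analyze_place_cells(sess, frames, n_shuffles=0, seed=seed)
    ctx = sess.contexts
    rs = []
    for r in results:
        ev = sess.events[r.neuron]
        ma = mappers[ctx[0]].rate_map(mappers[ctx[0]].event_positions(ev))
        mb = mappers[ctx[1]].rate_map(mappers[ctx[1]].event_positions(ev))
        rs.append(remapping_correlation(ma, mb))
    return float(np.nanmedian(rs))


def remapping_recovery(seed: int, n_cells: int = 60,
                       gains=(1.0, 0.5, 0.2)) -> dict:
    """Between-context map correlation and rate-overlap recovery.

    Stable populations (identical fields, gain 1) should show a high median
    spatial correlation; globally remapping populations (independent field
    locations per context) a near-zero one.  A planted per-context gain g
    should recover a field rate overlap of 1 - |1-g|/(1+g).
    """
    geo = default_geometry("discrimination")
    out = {"n_cells": n_cells}
    stable_truth = synth.make_ground_truth(geo, seed=seed, n_place=n_cells,
                                           remapping="none")
    out["stable_median_r"] = _population_median_r(stable_truth, seed + 1)
    global_truth = synth.make_ground_truth(geo, seed=seed + 100,
                                           n_place=n_cells, remapping="global")
    out["global_median_r"] = _population_median_r(global_truth, seed + 2)

    for g in gains:
        truth = synth.make_ground_truth(
            geo, seed=seed + 200, n_place=n_cells,
            remapping="rate-only", gain_b=g,
        )
        _, sess, frames = _prepare(truth, seed + 3)
        _, mappers = analyze_place_cells(sess, frames, n_shuffles=0, seed=seed)
        pm = PooledMapper(sess, frames)
        ctx = sess.contexts
        overlaps = []
        for ni in range(sess.n_neurons):
            ev = sess.events[ni]
            rmap, counts = pm.rate_map_and_counts(ev)
            maps = {c: mappers[c].rate_map(mappers[c].event_positions(ev))
                    for c in ctx}
            planted = truth.neurons[ni].fields[0].center
            for f in segment_place_fields(rmap, counts, neuron=ni):
                # join recovered to planted fields: gain recovery is defined
                # for the planted field, not for stray baseline clusters
                if np.hypot(f.center[0] - planted[0],
                            f.center[1] - planted[1]) > 5.0:
                    continue
                rates = field_mean_rates(f, maps)
                overlaps.append(rate_overlap_score(rates[ctx[0]], rates[ctx[1]]))
        key = f"overlap_g{g:g}".replace(".", "")
        out[key] = float(np.nanmedian(overlaps))
        out[key + "_expected"] = 1.0 - abs(1.0 - g) / (1.0 + g)
    return out


# ---------------------------------------------------------------------------
# Decoder calibration


def _balance_rows(m, seed):
    """Subsample the majority class so both contexts have equal row counts."""
    from .decode import DecoderFrameMatrix

    rng = np.random.default_rng(seed)
    labels, counts = np.unique(m.context, return_counts=True)
    n_min = counts.min()
    keep = np.sort(np.concatenate([
        rng.choice(np.flatnonzero(m.context == lab), size=n_min, replace=False)
        for lab in labels
    ]))
    return DecoderFrameMatrix(
        X=m.X[keep], context=m.context[keep], trial=m.trial[keep],
        correct=m.correct[keep], frames=m.frames[keep],
        neuron_ids=m.neuron_ids,
    )


def decoder_benchmark(seed: int, n_cells: int = 50,
                      n_shuffle_seeds: int = 20) -> dict:
    """Context decoding on a planted globally remapping population.

    The headline accuracy and the label-shuffled chance control use the
    standard frame-wise protocol on class-balanced rows; the place vs
    non-place subset contrast (only place cells carry context signal) uses
    trial-blocked splits, because duplicated window features would otherwise
    leak between training and test and lift the no-signal subset above
    chance.
    """
    geo = default_geometry("discrimination")
    truth = synth.make_ground_truth(geo, seed=seed, n_place=n_cells,
                                    remapping="global")
    _, sess, frames = _prepare(truth, seed + 1)
    m = build_decoder_frames(sess, frames)
    m = _balance_rows(m, seed)  # equal class counts: chance is exactly 0.5
    main = fit_context_decoder(m, seed=seed)
    shuffled = [label_shuffled_accuracy(m, seed=seed + 1000 + i)
                for i in range(n_shuffle_seeds)]

    # half place cells with context signal, half background without
    mixed = synth.make_ground_truth(geo, seed=seed + 7, n_place=n_cells // 2,
                                    remapping="global",
                                    n_background=n_cells - n_cells // 2)
    _, sess2, frames2 = _prepare(mixed, seed + 8)
    results2, _ = analyze_place_cells(sess2, frames2, n_shuffles=200,
                                      seed=seed + 9)
    flags = np.array([r.is_place_cell for r in results2])
    subset = {r.cell_subset: r.cv_accuracy
              for r in decode_by_subset(sess2, frames2, flags, seed=seed,
                                        trial_subsets=("all",),
                                        blocked=True)}
    return {
        "n_cells": n_cells,
        "n_rows": main.n_rows,
        "cv_accuracy": main.cv_accuracy,
        "holdout_accuracy": main.holdout_accuracy,
        "shuffled_mean": float(np.mean(shuffled)),
        "shuffled_accuracies": [float(s) for s in shuffled],
        "place_subset_accuracy": subset.get("place", float("nan")),
        "nonplace_subset_accuracy": subset.get("nonplace", float("nan")),
        "n_place_flagged": int(flags.sum()),
    }


# ---------------------------------------------------------------------------
# Directional disambiguation


def directional_disambiguation(seed: int, n_cells: int = 50) -> dict:
    """DC sensitivity on planted von Mises cells (kappa=2, depth=0.8) and
    specificity on pure place cells under wall-biased occupancy.

    The wall-biased trajectory makes place cells near the wall acquire a
    spurious directional curve; the reconstruction index is what keeps them
    out of the DC class.
    """
    geo = default_geometry("discrimination")
    rng = np.random.default_rng(seed)
    tuned = [
        NeuronTruth("directional", 15.0,
                    directional=DirectionalSpec(
                        mu=float(rng.uniform(-np.pi, np.pi)), kappa=2.0, depth=0.8))
        for _ in range(n_cells)
    ]
    place = []
    for _ in range(n_cells):
        ang = rng.uniform(-np.pi, np.pi)
        c = (15.0 * np.cos(ang), 15.0 * np.sin(ang))
        place.append(NeuronTruth("place", 0.1,
                                 [FieldSpec(center=c, width=4.5, amplitude=20.0,
                                            gain={"A": 1.0, "B": 1.0})]))
    truth = GroundTruth(neurons=tuned + place)
    motion = synth.MotionParams(wall_bias=0.15)
    _, sess, frames = _prepare(truth, seed + 1, motion=motion)
    dm = {c: DirectionalMapper(sess, frames, c) for c in sess.contexts}
    n_dc_tuned = 0
    angle_err = []
    for ni in range(n_cells):
        res = classify_directional_cell(ni, dm, sess.events[ni],
                                        seed=seed + 5 + 13 * ni)
        n_dc_tuned += res.is_dc
        mu = tuned[ni].directional.mu
        best = max(res.L, key=lambda c: res.L[c])
        if np.isfinite(res.angle[best]):
            d = (res.angle[best] - mu + np.pi) % (2 * np.pi) - np.pi
            angle_err.append(np.degrees(abs(d)))
    n_dc_place = sum(
        classify_directional_cell(ni, dm, sess.events[ni],
                                  seed=seed + 5 + 13 * ni).is_dc
        for ni in range(n_cells, 2 * n_cells)
    )
    return {
        "n_cells": n_cells,
        "dc_sensitivity_pct": 100.0 * n_dc_tuned / n_cells,
        "dc_false_rate_pct": 100.0 * n_dc_place / n_cells,
        "median_angle_error_deg": float(np.median(angle_err)) if angle_err else float("nan"),
    }


# ---------------------------------------------------------------------------
# End-to-end fixture


def make_fixture(directory, seed: int, duration_min: float = 12.0,
                 n_place: int = 6, n_directional: int = 3,
                 n_background: int = 3) -> None:
    """Small mixed-population dataset for end-to-end pipeline runs."""
    from .io import write_dataset

    geo = default_geometry("discrimination")
    truth = synth.make_ground_truth(
        geo, seed=seed, n_place=n_place, n_directional=n_directional,
        n_background=n_background, remapping="rate-only", gain_b=0.5,
    )
    sess = synth.simulate_session(
        truth, geo, duration_min=duration_min, n_trials=40, seed=seed + 1,
        policy=synth.AgentPolicy(kind="biased", p_correct=0.8, p_timeout=0.02),
    )
    write_dataset(sess, directory, truth=truth,
                  config={"seed": seed, "duration_min": duration_min})
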