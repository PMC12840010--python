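"""Orchestration: run every analysis stage on a dataset and write tables.

All thresholds live in :class:`RunConfig` with their standard defaults; the
config (and its hash plus the run seed) is embedded as a comment header in
every output table for provenance, and the whole run is deterministic for a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bh
from . import decode as dc
from . import directional as dr
from . import fields as fl
from . import io as rio
from . import preprocess as pp
from . import spatial as sp


@dataclass
class RunConfig:
    seed: int = 0
    bin_cm: float = 2.0
    sigma_cm: float = 3.0
    occ_min_s: float = 0.1
    running_speed_cms: float = 2.0
    speed_filter_ms: float = 167.0
    stability_floor: float = 0.4
    null_percentile: float = 95.0
    n_shuffles: int = 500
    shift_margin_s: float = 60.0
    min_place_events: int = 10
    qc_valley_dff: float = 0.1
    qc_minutes: int = 5
    field_min_prominence: float = 1.0
    field_peak_cutoff: float = 0.20
    reward_radius_cm: float = 10.0
    distance_bin_cm: float = 5.0
    preference_cutoff: float = 0.33
    n_direction_bins: int = 8
    window_frames: int = 60
    thin_every: int = 20
    test_fraction: float = 0.2
    cv_folds: int = 20
    criterion: float = 0.70

    def __post_init__(self):
        for name, val in asdict(self).items():
            if name != "seed" and not val > 0:
                raise ValueError(f"config field {name} must be positive")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# config_hash={config.hash()} seed={config.seed}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(dataset_dir, out_dir, config: RunConfig | None = None) -> dict:
    """preprocess -> spatial -> fields -> directional -> decode -> behavior.

    Writes ``place_cells.csv``, ``remapping.csv``, ``fields.csv``,
    ``directional.csv``, ``decoding.csv``, ``behavior.csv`` and
    ``summary.json`` under ``out_dir``; returns the result bundle.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session, truth, _ = rio.read_dataset(dataset_dir)
    contexts = session.contexts

    # --- preprocess
    speed = pp.compute_speed(session.body_xy, session.frame_rate)
    frames = pp.extract_analysis_frames(session, speed,
                                        running_threshold=config.running_speed_cms)
    _write_table(
        pd.DataFrame({
            "frame": np.arange(session.n_frames),
            "speed": np.round(speed, 6),
            "is_foraging": frames.is_foraging.astype(int),
            "is_running": frames.is_running.astype(int),
        }),
        out / "frames.csv", config,
    )

    # --- spatial
    grid = sp.MapGrid(session.geometry, bin_cm=config.bin_cm,
                      sigma_cm=config.sigma_cm)
    pc_results, mappers = sp.analyze_place_cells(
        session, frames, grid=grid, n_shuffles=config.n_shuffles, seed=config.seed
    )
    pc_rows = []
    remap_rows = []
    for r in pc_results:
        for ctx in contexts:
            pc_rows.append({
                "neuron": r.neuron, "context": ctx,
                "r_split": r.r_split[ctx], "r_evenodd": r.r_evenodd[ctx],
                "r_mean": r.r_mean[ctx], "null95": r.null95[ctx],
                "passes": int(r.passes[ctx]),
                "total_events": r.total_events,
                "is_place_cell": int(r.is_place_cell),
            })
    place_flags = np.array([r.is_place_cell for r in pc_results])
    ctx_maps = {}
    for r in pc_results:
        ev = session.events[r.neuron]
        ctx_maps[r.neuron] = {
            c: mappers[c].rate_map(mappers[c].event_positions(ev))
            for c in contexts
        }
        if r.is_place_cell and len(contexts) == 2:
            rr = sp.remapping_correlation(ctx_maps[r.neuron][contexts[0]],
                                          ctx_maps[r.neuron][contexts[1]])
            remap_rows.append({"neuron": r.neuron, "spatial_correlation": rr})
    _write_table(pd.DataFrame(pc_rows), out / "place_cells.csv", config)
    _write_table(pd.DataFrame(remap_rows), out / "remapping.csv", config)

    # --- fields (pooled maps for place cells)
    field_rows = []
    fields_by_neuron = {}
    pooled_engine = PooledMapper(session, frames, grid=grid,
                                 occ_min_s=config.occ_min_s)
    # firing preference of reward fields uses maps rebuilt from correct
    # non-cued trials only
    good = {t.trial_index for t in session.trials
            if t.outcome == "correct" and not t.cued}
    frames_correct = pp.AnalysisFrames(
        is_foraging=frames.is_foraging, is_running=frames.is_running,
        is_rest=frames.is_rest,
        segments=[s for s in frames.segments if s[0] in good],
    )
    correct_mappers = {c: sp.ContextMapper(session, frames_correct, c, grid=grid)
                       for c in contexts}
    # declarative replacement for manual field curation, keyed by neuron id
    overrides_path = Path(dataset_dir) / "field_overrides.json"
    overrides = (json.loads(overrides_path.read_text())
                 if overrides_path.exists() else {})
    for r in pc_results:
        if not r.is_place_cell:
            continue
        ev = session.events[r.neuron]
        fmap, counts = pooled_engine.rate_map_and_counts(ev)
        flds = fl.segment_place_fields(
            fmap, counts, neuron=r.neuron,
            min_prominence=config.field_min_prominence,
            cutoff_frac=config.field_peak_cutoff,
        )
        flds = fl.apply_field_overrides(flds, overrides.get(str(r.neuron)))
        fl.assign_reward_fields(flds, session.geometry,
                                reward_radius=config.reward_radius_cm,
                                bin_cm=config.distance_bin_cm)
        for f in flds:
            f.rate_by_context = fl.field_mean_rates(f, ctx_maps[r.neuron])
            rates = [f.rate_by_context[c] for c in contexts]
            overlap = fl.rate_overlap_score(*rates) if len(rates) == 2 else np.nan
            fp = np.nan
            if len(rates) == 2 and f.distance_class == "reward":
                cmaps = {c: correct_mappers[c].rate_map(
                    correct_mappers[c].event_positions(ev)) for c in contexts}
                crates = fl.field_mean_rates(f, cmaps)
                fp = fl.firing_preference(crates[contexts[0]],
                                          crates[contexts[1]], f.reward_index)
            field_rows.append({
                "neuron": r.neuron, "field_id": f.field_id,
                "center_x": f.center[0], "center_y": f.center[1],
                "size_cm2": f.size_cm2, "peak_rate": f.peak_rate,
                "rate1": rates[0], "rate2": rates[-1],
                "rate_overlap": overlap,
                "reward_distance": f.reward_distance,
                "distance_class": f.distance_class,
                "firing_preference": fp,
                "preference_category": fl.preference_category(fp)
                if np.isfinite(fp) else "",
            })
        fields_by_neuron[r.neuron] = flds
    _write_table(pd.DataFrame(field_rows), out / "fields.csv", config)

    # --- directional
    dmappers = {c: dr.DirectionalMapper(session, frames, c, grid=grid)
                for c in contexts}
    dir_results = []
    dir_rows = []
    for r in pc_results:
        res = dr.classify_directional_cell(
            r.neuron, dmappers, session.events[r.neuron],
            is_place_cell=r.is_place_cell,
            n_shuffles=config.n_shuffles, seed=config.seed + 104729 * (r.neuron + 1),
        )
        dir_results.append(res)
        for ctx in contexts:
            dir_rows.append({
                "neuron": r.neuron, "context": ctx,
                "L": res.L[ctx], "angle": res.angle[ctx],
                "stability": res.stability[ctx],
                "null95_event": res.null95_event[ctx],
                "null95_dir": res.null95_dir[ctx],
                "err_place": res.err_place[ctx], "err_dir": res.err_dir[ctx],
                "index": res.index[ctx],
                "is_dc": int(res.is_dc), "is_conjunctive": int(res.is_conjunctive),
                "selectivity": res.selectivity,
            })
    _write_table(pd.DataFrame(dir_rows), out / "directional.csv", config)
    landmark = dr.landmark_tuning_summary(dir_results, session.geometry,
                                          fields_by_neuron)

    # --- decoding
    decode_rows = []
    if len(contexts) == 2:
        try:
            results = dc.decode_by_subset(session, frames, place_flags,
                                          seed=config.seed)
            decode_rows = [asdict(r) for r in results]
        except ValueError:
            pass
    _write_table(pd.DataFrame(decode_rows), out / "decoding.csv", config)

    # --- behavior
    beh_rows = []
    for t in session.trials:
        outcome, etype = bh.classify_trial(t, session.geometry)
        beh_rows.append({"trial": t.trial_index, "context": t.context,
                         "outcome": outcome, "error_type": etype or ""})
    _write_table(pd.DataFrame(beh_rows), out / "behavior.csv", config)
    summary = bh.summarize_session(session.trials, session.geometry)

    bundle = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_neurons": session.n_neurons,
        "n_place_cells": int(place_flags.sum()),
        "n_dc": int(sum(r.is_dc for r in dir_results)),
        "n_conjunctive": int(sum(r.is_conjunctive for r in dir_results)),
        "n_fields": len(field_rows),
        "landmark": {k: v for k, v in landmark.items() if k != "reward_field_distances"},
        "behavior": {
            "n_trials": summary.n_trials,
            "fraction_correct": summary.fraction_correct,
            "error_counts": summary.error_counts,
            "n_timeout": summary.n_timeout,
        },
        "decoding": decode_rows,
    }
    (out / "summary.json").write_text(json.dumps(bundle, indent=1, default=float))
    return bundle


class PooledMapper:
    """Pooled-context rate maps (both contexts' events and occupancy)."""

    def __init__(self, session, frames, grid=None, occ_min_s: float = 0.1):
        self.grid = grid or sp.MapGrid(session.geometry)
        self.frame_rate = session.frame_rate
        seqs = [pp.context_frame_sequence(frames, c, mode="spatial")[0]
                for c in session.contexts]
        self.seq = np.concatenate(seqs) if seqs else np.zeros(0, int)
        self.binidx = (self.grid.bin_index(session.head_xy[self.seq])
                       if len(self.seq) else np.zeros(0, int))
        self._in_seq = np.zeros(session.n_frames, dtype=bool)
        self._in_seq[self.seq] = True
        occ = np.bincount(self.binidx, minlength=self.grid.n_bins)
        self.occ_s = occ.reshape(self.grid.n, self.grid.n) / self.frame_rate
        self.valid = (self.occ_s >= occ_min_s) & self.grid.inside
        self.sm_occ = self.grid.smooth(self.occ_s, self.valid)
        self._bin_of_frame = np.full(session.n_frames, -1, dtype=int)
        self._bin_of_frame[self.seq] = self.binidx

    def rate_map_and_counts(self, event_frames):
        ev = np.asarray(event_frames, dtype=int)
        ev = ev[self._in_seq[ev]] if len(ev) else ev
        cnt = np.bincount(self._bin_of_frame[ev], minlength=self.grid.n_bins) \
            if len(ev) else np.zeros(self.grid.n_bins)
        cnt = cnt.reshape(self.grid.n, self.grid.n).astype(float)
        sm_c = self.grid.smooth(cnt, self.valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.valid, sm_c / self.sm_occ * 60.0, np.nan)
        rmap = sp.RateMap(rate=rate, occupancy_s=self.occ_s, valid=self.valid,
                          context="pooled", grid=self.grid)
        return rmap, cnt


# ---------------------------------------------------------------------------
# Standard group comparisons (thin reporting wrappers)


def compare_groups(a, b, test: str = "ranksum", n_comparisons: int = 1) -> dict:
    """Named two-sample tests with optional Bonferroni correction.

    test: 'ranksum' (Wilcoxon rank-sum), 'ks' (two-sample
    Kolmogorov-Smirnov), 'paired_t', or 'chi2' (b = expected proportions).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    if test == "ranksum":
        r = stats.ranksums(a, b)
        stat, p = r.statistic, r.pvalue
    elif test == "ks":
        r = stats.ks_2samp(a, b)
        stat, p = r.statistic, r.pvalue
    elif test == "paired_t":
        if len(a) != len(b):
            raise ValueError("paired test needs equal lengths")
        r = stats.ttest_rel(a, b)
        stat, p = r.statistic, r.pvalue
    elif test == "chi2":
        chi2, p, _ = bh.error_composition(a, b)
        stat = chi2
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "statistic": float(stat),
            "p": float(min(1.0, p * n_comparisons))}


def repeated_measures(values, subject, factor_a, factor_b,
                      names=("factor_a", "factor_b")) -> pd.DataFrame:
    """Two-factor repeated-measures ANOVA (within-subject factors).

    Fits ``value ~ A + B + A:B`` with subject as the repeated-measures unit
    (each subject contributes one value per factor-level combination) and
    returns the ANOVA table.  Used for designs such as decoding accuracy by
    cell subset x paradigm measured in the same animals.
    """
    from statsmodels.stats.anova import AnovaRM

    df = pd.DataFrame({"value": values, "subject": subject,
                       names[0]: factor_a, names[1]: factor_b})
    return AnovaRM(df, depvar="value", subject="subject",
                   within=list(names)).fit().anova_table


def write_report(bundle_dir, fig_dir, config: RunConfig | None = None) -> list:
    """Figure panels (CDFs, histograms, polar tuning) from a pipeline run.

    Reads the stage tables under ``bundle_dir``; writes PNG figures under
    ``fig_dir`` and returns the written paths.  All figure data already
    exists as tables, so figures are presentation-only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle_dir = Path(bundle_dir)
    fig_dir = Path(fig_dir)
    fig_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _read(name):
        p = bundle_dir / name
        return pd.read_csv(p, comment="#") if p.exists() else pd.DataFrame()

    remap = _read("remapping.csv")
    fig, ax = plt.subplots(figsize=(4, 3))
    if len(remap):
        x = np.sort(remap["spatial_correlation"].dropna())
        ax.plot(x, np.arange(1, len(x) + 1) / len(x), drawstyle="steps-post")
    else:
        ax.text(0.5, 0.5, "no place cells", ha="center")
    ax.set_xlabel("spatial correlation (r)")
    ax.set_ylabel("cumulative fraction")
    fig.tight_layout()
    p = fig_dir / "spatial_correlation_cdf.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    flds = _read("fields.csv")
    fig, ax = plt.subplots(figsize=(4, 3))
    if len(flds):
        x = np.sort(flds["rate_overlap"].dropna())
        if len(x):
            ax.plot(x, np.arange(1, len(x) + 1) / len(x), drawstyle="steps-post")
        counts = flds["distance_class"].value_counts()
        if len(counts) == 0:
            ax.text(0.5, 0.5, "no fields", ha="center")
    else:
        ax.text(0.5, 0.5, "no fields", ha="center")
    ax.set_xlabel("rate overlap score")
    ax.set_ylabel("cumulative fraction")
    fig.tight_layout()
    p = fig_dir / "rate_overlap_cdf.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    dec = _read("decoding.csv")
    fig, ax = plt.subplots(figsize=(4, 3))
    if len(dec):
        labels = dec["cell_subset"] + "/" + dec["trial_subset"]
        ax.bar(labels, dec["cv_accuracy"])
        ax.axhline(0.5, ls="--", c="gray")
        ax.set_ylim(0, 1)
        ax.tick_params(axis="x", rotation=45)
    else:
        ax.text(0.5, 0.5, "no decoding", ha="center")
    ax.set_ylabel("mean CV accuracy")
    fig.tight_layout()
    p = fig_dir / "decoding_accuracy.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written
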