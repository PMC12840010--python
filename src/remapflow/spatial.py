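"""Context rate maps, split-half stability, circular-shuffle null, and
place-cell classification.

Maps are event-rate grids over the arena bounding box at 2x2 cm bins,
computed from running foraging frames of one context (segments concatenated
in trial order).  Counts and occupancy are each Gaussian-smoothed
(sigma = 3 cm) over valid bins and then divided; bins with < 0.1 s raw
occupancy, or outside the octagon, are invalid.

A neuron is a place cell if its stability r (mean of split-half and
even/odd map correlations) exceeds both the 95th percentile of a circular
event-shuffle null (500 shuffles, shifts at least 1 min away from the
original timing) and an absolute 0.4 floor, in at least one context, and it
fired at least 10 events in the session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import SessionData
from .geometry import ArenaGeometry
from .preprocess import AnalysisFrames, context_frame_sequence

BIN_CM = 2.0
SIGMA_CM = 3.0
OCC_MIN_S = 0.1
N_SHUFFLES = 500
SHIFT_MARGIN_S = 60.0
STABILITY_FLOOR = 0.4
MIN_EVENTS = 10


class MapGrid:
    """Square binning of the arena bounding box."""

    def __init__(self, geometry: ArenaGeometry, bin_cm: float = BIN_CM,
                 sigma_cm: float = SIGMA_CM):
        self.geometry = geometry
        self.bin_cm = float(bin_cm)
        self.sigma_bins = float(sigma_cm) / float(bin_cm)
        # pad the bounding box by 4 sigma so the smoothing kernel never
        # truncates at the array edge (count mass is conserved)
        r = geometry.radius + 4.0 * float(sigma_cm)
        self.n = int(np.ceil(2 * r / bin_cm))
        self.x0 = -r
        self.y0 = -r
        xs = self.x0 + (np.arange(self.n) + 0.5) * bin_cm
        cx, cy = np.meshgrid(xs, xs, indexing="xy")
        centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
        self.inside = geometry.contains(centers).reshape(self.n, self.n)

    @property
    def n_bins(self) -> int:
        return self.n * self.n

    def bin_index(self, xy: np.ndarray) -> np.ndarray:
        """Flat bin index (row-major, y-row) per position."""
        ix = np.clip(((xy[:, 0] - self.x0) / self.bin_cm).astype(int), 0, self.n - 1)
        iy = np.clip(((xy[:, 1] - self.y0) / self.bin_cm).astype(int), 0, self.n - 1)
        return iy * self.n + ix

    def bin_centers(self) -> np.ndarray:
        xs = self.x0 + (np.arange(self.n) + 0.5) * self.bin_cm
        cx, cy = np.meshgrid(xs, xs, indexing="xy")
        return np.stack([cx.ravel(), cy.ravel()], axis=1)

    def smooth(self, grid: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Gaussian smoothing restricted to valid bins (kernel support
        excludes invalid bins; total mass over valid bins is conserved)."""
        g = np.where(valid, grid, 0.0)
        if g.ndim == 2:
            return gaussian_filter(g, self.sigma_bins, mode="constant")
        return gaussian_filter(g, (0, self.sigma_bins, self.sigma_bins), mode="constant")


@dataclass
class RateMap:
    """Occupancy-normalized smoothed event-rate grid (events/min)."""

    rate: np.ndarray  # (n, n); NaN on invalid bins
    occupancy_s: np.ndarray  # raw per-bin occupancy, seconds
    valid: np.ndarray  # bool
    context: str
    grid: MapGrid

    @property
    def n_events(self) -> float:
        return float(np.nansum(self.rate))  # not a count; see counts in mapper

    def argmax_xy(self) -> tuple:
        flat = np.where(self.valid.ravel(), np.nan_to_num(self.rate.ravel(), nan=-1), -1)
        k = int(np.argmax(flat))
        return tuple(self.grid.bin_centers()[k])


def masked_pearson(a: np.ndarray, b: np.ndarray, valid: np.ndarray,
                   min_bins: int = 2) -> float:
    """Pearson r over bins valid in both maps; NaN when undefined."""
    x = a[valid]
    y = b[valid]
    if len(x) < min_bins:
        return float("nan")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def fisher_z(r):
    """Fisher transform (monotone; used when aggregating correlations)."""
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


# ---------------------------------------------------------------------------
# The map engine: precomputes everything that does not depend on events, so
# the 500-shuffle null costs one vectorized pass per neuron.


class ContextMapper:
    """Rate maps and split-half stability for one context of one session.

    Precomputes the concatenated running-foraging frame sequence, its bin
    index per position, and per-subset ('all', 'first', 'second', 'even',
    'odd') occupancy, validity, and smoothed occupancy.  Event trains are
    mapped to positions within the sequence; circular shuffles shift those
    positions modulo the sequence length.
    """

    SPLITS = (("first", "second"), ("even", "odd"))

    def __init__(self, session: SessionData, frames: AnalysisFrames, context: str,
                 grid: MapGrid | None = None, occ_min_s: float = OCC_MIN_S,
                 mode: str = "spatial"):
        self.context = context
        self.grid = grid or MapGrid(session.geometry)
        self.frame_rate = session.frame_rate
        seq, seg, trial = context_frame_sequence(frames, context, mode=mode)
        self.seq = seq
        self.T = len(seq)
        self.binidx = self.grid.bin_index(session.head_xy[seq]) if self.T else np.zeros(0, int)
        # frame -> sequence position lookup
        self._pos_of_frame = np.full(session.n_frames, -1, dtype=int)
        self._pos_of_frame[seq] = np.arange(self.T)

        ctx_trials = sorted({int(t) for t in trial})
        m = len(ctx_trials)
        first_set = set(ctx_trials[: (m + 1) // 2])
        even_set = {t for i, t in enumerate(ctx_trials) if i % 2 == 0}
        self.n_trials = m
        self.subsets = {
            "all": np.ones(self.T, dtype=bool),
            "first": np.isin(trial, list(first_set)),
            "even": np.isin(trial, list(even_set)),
        }
        self.subsets["second"] = ~self.subsets["first"]
        self.subsets["odd"] = ~self.subsets["even"]

        self.occ_s = {}
        self.valid = {}
        self.sm_occ = {}
        for name, memb in self.subsets.items():
            occ = np.bincount(self.binidx[memb], minlength=self.grid.n_bins)
            occ = occ.reshape(self.grid.n, self.grid.n) / self.frame_rate
            valid = (occ >= occ_min_s) & self.grid.inside
            self.occ_s[name] = occ
            self.valid[name] = valid
            self.sm_occ[name] = self.grid.smooth(occ, valid)
        self.shared_valid = {
            (a, b): self.valid[a] & self.valid[b] for a, b in self.SPLITS
        }

    # -- event mapping ----------------------------------------------------

    def event_positions(self, event_frames: np.ndarray) -> np.ndarray:
        """Sequence positions of the events that fall on analyzed frames."""
        if len(event_frames) == 0:
            return np.zeros(0, dtype=int)
        pos = self._pos_of_frame[np.asarray(event_frames, dtype=int)]
        return pos[pos >= 0]

    # -- maps -------------------------------------------------------------

    def rate_map(self, positions: np.ndarray, subset: str = "all") -> RateMap:
        memb = self.subsets[subset]
        valid = self.valid[subset]
        p = positions[memb[positions]] if len(positions) else positions
        counts = np.bincount(self.binidx[p], minlength=self.grid.n_bins)
        counts = counts.reshape(self.grid.n, self.grid.n).astype(float)
        sm_c = self.grid.smooth(counts, valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(valid, sm_c / self.sm_occ[subset] * 60.0, np.nan)
        return RateMap(rate=rate, occupancy_s=self.occ_s[subset], valid=valid,
                       context=self.context, grid=self.grid)

    def _subset_rates_batch(self, P: np.ndarray, subset: str) -> np.ndarray:
        """(S, n, n) smoothed rates for a batch of position sets."""
        S = P.shape[0]
        memb = self.subsets[subset]
        valid = self.valid[subset]
        counts = np.zeros((S, self.grid.n_bins))
        if P.size:
            sel = memb[P]
            rows = np.broadcast_to(np.arange(S)[:, None], P.shape)[sel]
            np.add.at(counts, (rows, self.binidx[P[sel]]), 1.0)
        counts = counts.reshape(S, self.grid.n, self.grid.n)
        counts[:, ~valid] = 0.0
        sm_c = gaussian_filter(counts, (0, self.grid.sigma_bins, self.grid.sigma_bins),
                               mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            return sm_c / self.sm_occ[subset][None] * 60.0

    # -- stability --------------------------------------------------------

    def stability(self, positions: np.ndarray) -> tuple:
        """(r_split, r_evenodd, r_mean) for an observed event train."""
        r = []
        for a, b in self.SPLITS:
            ra = self.rate_map(positions, a).rate
            rb = self.rate_map(positions, b).rate
            r.append(masked_pearson(ra, rb, self.shared_valid[(a, b)]))
        return r[0], r[1], float(np.mean(r))

    def stability_batch(self, P: np.ndarray) -> np.ndarray:
        """r_mean per row of a (S, E) matrix of position sets (vectorized)."""
        S = P.shape[0]
        out = np.zeros((S, len(self.SPLITS)))
        for j, (a, b) in enumerate(self.SPLITS):
            ra = self._subset_rates_batch(P, a)
            rb = self._subset_rates_batch(P, b)
            sv = self.shared_valid[(a, b)]
            x = ra[:, sv]
            y = rb[:, sv]
            if x.shape[1] < 2:
                out[:, j] = np.nan
                continue
            xm = x - x.mean(axis=1, keepdims=True)
            ym = y - y.mean(axis=1, keepdims=True)
            sx = x.std(axis=1)
            sy = y.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xm * ym).mean(axis=1) / (sx * sy)
            r[(sx == 0) | (sy == 0)] = np.nan
            out[:, j] = r
        return out.mean(axis=1)

    # -- circular shuffle null -------------------------------------------

    def shuffle_offsets(self, n: int, rng,
                        margin_s: float = SHIFT_MARGIN_S) -> np.ndarray:
        """Uniform circular offsets at least ``margin_s`` from 0 (mod T)."""
        lo = int(margin_s * self.frame_rate)
        hi = self.T - lo
        if hi <= lo:
            raise ValueError("analysis-frame span too short for the shuffle margin")
        return rng.integers(lo, hi, size=n)

    def shuffle_null(self, positions: np.ndarray, n: int = N_SHUFFLES,
                     seed: int = 0) -> np.ndarray:
        """Null distribution of r_mean under circular event shifts."""
        rng = np.random.default_rng(seed)
        offsets = self.shuffle_offsets(n, rng)
        if len(positions) == 0:
            return np.full(n, np.nan)
        P = (positions[None, :] + offsets[:, None]) % self.T
        return self.stability_batch(P)


# ---------------------------------------------------------------------------
# Classification and remapping


@dataclass
class PlaceCellResult:
    neuron: int
    contexts: list
    r_split: dict
    r_evenodd: dict
    r_mean: dict
    null95: dict
    passes: dict
    total_events: int
    is_place_cell: bool


def classify_place_cell(neuron: int, r_split: dict, r_evenodd: dict, r_mean: dict,
                        null95: dict, total_events: int,
                        floor: float = STABILITY_FLOOR,
                        min_events: int = MIN_EVENTS) -> PlaceCellResult:
    passes = {}
    for ctx, r in r_mean.items():
        n95 = null95.get(ctx, np.nan)
        passes[ctx] = bool(np.isfinite(r) and np.isfinite(n95)
                           and r > n95 and r > floor)
    is_pc = any(passes.values()) and total_events >= min_events
    return PlaceCellResult(
        neuron=neuron, contexts=sorted(r_mean), r_split=r_split,
        r_evenodd=r_evenodd, r_mean=r_mean, null95=null95, passes=passes,
        total_events=total_events, is_place_cell=bool(is_pc),
    )


def remapping_correlation(map_a: RateMap, map_b: RateMap,
                          min_shared: int = 10) -> float:
    """Pearson r between the two context maps over shared valid bins."""
    shared = map_a.valid & map_b.valid
    if shared.sum() < min_shared:
        return float("nan")
    return masked_pearson(map_a.rate, map_b.rate, shared)


def analyze_place_cells(
    session: SessionData,
    frames: AnalysisFrames,
    grid: MapGrid | None = None,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
    neurons: list | None = None,
) -> tuple:
    """Full place-cell screen for a session.

    Returns (results, mappers) where ``results`` is a list of
    :class:`PlaceCellResult` and ``mappers`` maps context -> ContextMapper
    (reusable for remapping correlations and downstream analyses).
    """
    grid = grid or MapGrid(session.geometry)
    contexts = session.contexts
    mappers = {c: ContextMapper(session, frames, c, grid=grid) for c in contexts}
    neuron_ids = range(session.n_neurons) if neurons is None else neurons
    results = []
    for ni in neuron_ids:
        ev = session.events[ni]
        r_split, r_eo, r_mean, null95 = {}, {}, {}, {}
        for ctx, mp in mappers.items():
            pos = mp.event_positions(ev)
            rs, re_, rm = mp.stability(pos)
            r_split[ctx], r_evenodd_val, r_mean[ctx] = rs, re_, rm
            r_eo[ctx] = r_evenodd_val
            null = mp.shuffle_null(pos, n=n_shuffles, seed=seed + 7919 * ni)
            null = null[np.isfinite(null)]
            null95[ctx] = float(np.percentile(null, 95)) if len(null) else np.nan
        results.append(
            classify_place_cell(ni, r_split, r_eo, r_mean, null95, len(ev))
        )
    return results, mappers
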