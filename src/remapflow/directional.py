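"""Egocentric directional tuning and its disambiguation from place tuning.

The relative running direction is ``H = wrap(phi - a)`` where ``phi`` is the
allocentric heading (from smoothed head displacement) and ``a`` the bearing
from the head to a chosen reference point; both use the quadrant-aware
arctangent and ``H`` lies in [-pi, pi).  Tuning curves are event rates in
eight 45-degree bins (one per arena wall); tuning strength and direction are
the length and angle of the Rayleigh vector of the curve.

A directionally modulated cell (DC) must, within at least one context, be
split-half stable (r > 0.4), exceed the 95th percentile of BOTH circular
shuffle nulls (event shift and direction-series shift), and have a
direction/place index > 1 — the index being the ratio of reconstruction
errors under a pure-place vs a pure-direction assumption, which guards
against spurious tuning from non-uniform occupancy.  Cells with fewer than
10 events are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .core import SessionData
from .geometry import N_WALLS, WALL_STEP, ArenaGeometry, angle_to_wall, wall_angle
from .preprocess import AnalysisFrames, context_frame_sequence, moving_average, \
    smoothing_window_frames
from .spatial import MapGrid, masked_pearson

N_DIR_BINS = 8
STABILITY_FLOOR = 0.4
MIN_EVENTS = 10
N_SHUFFLES = 500
SHIFT_MARGIN_S = 60.0

BIN_CENTERS = wall_angle(np.arange(N_DIR_BINS))  # bin k points at wall k


def wrap_angle(a):
    """Wrap to [-pi, pi)."""
    return np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi


def relative_running_direction(
    head_xy: np.ndarray,
    reference: tuple,
    frame_rate: float,
) -> tuple:
    """Per-frame (phi, a, H, defined) series over the whole session.

    phi: heading from frame-to-frame displacement of the 167-ms-smoothed
    head position; a: bearing from head to the reference; H = wrap(phi - a).
    Frames with zero displacement have undefined direction (``defined``
    False); the final frame inherits no displacement and is undefined.
    """
    head = moving_average(np.asarray(head_xy, float),
                          smoothing_window_frames(frame_rate))
    d = np.diff(head, axis=0)
    step = np.hypot(d[:, 0], d[:, 1])
    phi = np.arctan2(d[:, 1], d[:, 0])
    defined = step > 1e-9
    phi = np.append(phi, np.nan)
    defined = np.append(defined, False)
    rx, ry = reference
    a = np.arctan2(ry - head[:, 1], rx - head[:, 0])
    H = wrap_angle(phi - a)
    H[~defined] = np.nan
    return phi, a, H, defined


def direction_bin(H: np.ndarray) -> np.ndarray:
    """45-degree bin index (0..7), centres at the wall-normal angles."""
    return angle_to_wall(H)


def rayleigh_vector(curve: np.ndarray) -> tuple:
    """(length, angle) of the Rayleigh vector of an 8-bin tuning curve.

    Bins with NaN rate (zero occupancy) are excluded from the sum.  The
    length is invariant under rotation of all angles; the angle is
    equivariant.
    """
    curve = np.asarray(curve, dtype=float)
    ok = np.isfinite(curve)
    total = curve[ok].sum()
    if total <= 0:
        return 0.0, float("nan")
    z = np.sum(curve[ok] * np.exp(1j * BIN_CENTERS[ok])) / total
    return float(np.abs(z)), float(np.angle(z))


def reconstruct_tuning(joint: np.ndarray, r_xy: np.ndarray) -> np.ndarray:
    """r'(H) under the pure-place assumption.

    ``joint`` is the (n_spatial_bins, n_direction_bins) occupancy and
    ``r_xy`` the flat observed spatial rate map (NaN outside valid bins —
    those rows are excluded from the sums).
    """
    ok = np.isfinite(r_xy)
    p = np.where(ok[:, None], joint, 0.0)
    num = (p * np.nan_to_num(r_xy)[:, None]).sum(axis=0)
    den = p.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def reconstruct_map(joint: np.ndarray, r_H: np.ndarray) -> np.ndarray:
    """r'(x, y) under the pure-direction assumption (flat spatial map)."""
    ok = np.isfinite(r_H)
    p = np.where(ok[None, :], joint, 0.0)
    num = (p * np.nan_to_num(r_H)[None, :]).sum(axis=1)
    den = p.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def reconstruction_error(observed: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean squared difference of peak-normalized maps over the range of the
    normalized observed map; NaN when the observed map is flat (max = min)."""
    ok = np.isfinite(observed) & np.isfinite(reconstructed)
    if ok.sum() < 2:
        return float("nan")
    o = observed[ok]
    r = reconstructed[ok]
    if o.max() <= 0 or o.max() == o.min():
        return float("nan")
    o = o / o.max()
    if r.max() > 0:
        r = r / r.max()
    return float(np.mean((o - r) ** 2) / (o.max() - o.min()))


# ---------------------------------------------------------------------------
# Per-context engine


class DirectionalMapper:
    """Tuning curves, stability, nulls, and reconstruction for one context.

    Operates on the running-foraging frame sequence of the context,
    restricted to frames with defined running direction.
    """

    SPLITS = (("first", "second"), ("even", "odd"))

    def __init__(self, session: SessionData, frames: AnalysisFrames, context: str,
                 reference: tuple | None = None, grid: MapGrid | None = None):
        self.context = context
        self.frame_rate = session.frame_rate
        self.grid = grid or MapGrid(session.geometry)
        reference = reference if reference is not None else session.geometry.reference_point
        _, _, H, defined = relative_running_direction(
            session.head_xy, reference, session.frame_rate
        )
        seq, seg, trial = context_frame_sequence(frames, context, mode="spatial")
        keep = defined[seq]
        self.seq = seq[keep]
        trial = trial[keep]
        self.T = len(self.seq)
        self.dirbin = direction_bin(H[self.seq]) if self.T else np.zeros(0, int)
        self.spatbin = (self.grid.bin_index(session.head_xy[self.seq])
                        if self.T else np.zeros(0, int))
        self._pos_of_frame = np.full(session.n_frames, -1, dtype=int)
        self._pos_of_frame[self.seq] = np.arange(self.T)

        ctx_trials = sorted({int(t) for t in trial})
        m = len(ctx_trials)
        first = set(ctx_trials[: (m + 1) // 2])
        even = {t for i, t in enumerate(ctx_trials) if i % 2 == 0}
        self.subsets = {
            "all": np.ones(self.T, dtype=bool),
            "first": np.isin(trial, list(first)),
            "even": np.isin(trial, list(even)),
        }
        self.subsets["second"] = ~self.subsets["first"]
        self.subsets["odd"] = ~self.subsets["even"]
        self.time_in_bin = {
            name: np.bincount(self.dirbin[memb], minlength=N_DIR_BINS) / self.frame_rate
            for name, memb in self.subsets.items()
        }

    def event_positions(self, event_frames: np.ndarray) -> np.ndarray:
        if len(event_frames) == 0:
            return np.zeros(0, dtype=int)
        pos = self._pos_of_frame[np.asarray(event_frames, dtype=int)]
        return pos[pos >= 0]

    # -- tuning curves ----------------------------------------------------

    def tuning_curve(self, positions: np.ndarray, subset: str = "all") -> np.ndarray:
        """Event rate (events/min) per 45-degree bin; NaN on empty bins."""
        memb = self.subsets[subset]
        p = positions[memb[positions]] if len(positions) else positions
        counts = np.bincount(self.dirbin[p], minlength=N_DIR_BINS).astype(float)
        t = self.time_in_bin[subset]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, counts / (t / 60.0), np.nan)

    def tuning(self, positions: np.ndarray) -> tuple:
        """(curve, L, angle) for the observed events."""
        curve = self.tuning_curve(positions)
        L, ang = rayleigh_vector(curve)
        return curve, L, ang

    def stability(self, positions: np.ndarray) -> float:
        """Mean Pearson correlation of split tuning curves (first/second and
        even/odd); NaN if undefined (constant or empty curves)."""
        rs = []
        for a, b in self.SPLITS:
            ca = self.tuning_curve(positions, a)
            cb = self.tuning_curve(positions, b)
            ok = np.isfinite(ca) & np.isfinite(cb)
            rs.append(masked_pearson(ca, cb, ok))
        return float(np.mean(rs))

    # -- nulls ------------------------------------------------------------

    def _L_batch(self, P: np.ndarray) -> np.ndarray:
        S = P.shape[0]
        counts = np.zeros((S, N_DIR_BINS))
        if P.size:
            rows = np.broadcast_to(np.arange(S)[:, None], P.shape)
            np.add.at(counts, (rows.ravel(), self.dirbin[P].ravel()), 1.0)
        t = self.time_in_bin["all"]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(t > 0, counts / (t / 60.0), 0.0)
        tot = rate.sum(axis=1)
        z = (rate * np.exp(1j * BIN_CENTERS)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            L = np.abs(z) / tot
        L[tot <= 0] = 0.0
        return L

    def shuffle_offsets(self, n: int, rng, margin_s: float = SHIFT_MARGIN_S):
        lo = int(margin_s * self.frame_rate)
        hi = self.T - lo
        if hi <= lo:
            raise ValueError("context span too short for the shuffle margin")
        return rng.integers(lo, hi, size=n)

    def nulls(self, positions: np.ndarray, n: int = N_SHUFFLES, seed: int = 0) -> tuple:
        """(event-shift null, direction-shift null) distributions of L.

        Null 1 circularly shifts the event positions within the context
        sequence; null 2 circularly shifts the running-direction series
        relative to the events (preserving its autocorrelation).  Both use
        offsets at least 1 min from zero.
        """
        rng = np.random.default_rng(seed)
        if len(positions) == 0:
            return np.full(n, np.nan), np.full(n, np.nan)
        off1 = self.shuffle_offsets(n, rng)
        off2 = self.shuffle_offsets(n, rng)
        P1 = (positions[None, :] + off1[:, None]) % self.T
        # shifting H by +off is equivalent to sampling dirbin at (pos - off)
        P2 = (positions[None, :] - off2[:, None]) % self.T
        return self._L_batch(P1), self._L_batch(P2)

    # -- reconstruction ---------------------------------------------------

    def reconstruction(self, positions: np.ndarray) -> dict:
        """Occupancy-bias control: reconstruct each tuning from the other.

        r'(H) = sum_xy p(x,y,H) r(x,y) / sum_xy p(x,y,H) assumes a pure
        place cell; r'(x,y) = sum_H p(x,y,H) r(H) / sum_H p assumes pure
        directional tuning.  Errors are mean squared differences of
        peak-normalized observed vs reconstructed maps, divided by the range
        of the normalized observed map; the direction/place index is
        err_place_assumption / err_direction_assumption (> 1 favours genuine
        directional tuning).
        """
        nb = self.grid.n_bins
        # joint occupancy p(x, y, H): (n_spatial_bins, 8), in frames
        joint = np.zeros((nb, N_DIR_BINS))
        np.add.at(joint, (self.spatbin, self.dirbin), 1.0)

        # observed spatial rate map on the same frame set (smoothed)
        occ = np.bincount(self.spatbin, minlength=nb).reshape(self.grid.n, self.grid.n)
        occ_s = occ / self.frame_rate
        valid = (occ_s >= 0.1) & self.grid.inside
        cnt = np.bincount(self.spatbin[positions], minlength=nb) if len(positions) \
            else np.zeros(nb)
        cnt = cnt.reshape(self.grid.n, self.grid.n).astype(float)
        sm_occ = self.grid.smooth(occ_s, valid)
        sm_cnt = self.grid.smooth(cnt, valid)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_xy = np.where(valid, sm_cnt / sm_occ * 60.0, np.nan)

        r_H = self.tuning_curve(positions)
        r_xy_flat = r_xy.ravel()

        rprime_H = reconstruct_tuning(joint, r_xy_flat)
        rprime_xy = reconstruct_map(joint, r_H)

        err_place = reconstruction_error(r_H, rprime_H)
        err_dir = reconstruction_error(r_xy_flat, rprime_xy)
        with np.errstate(invalid="ignore", divide="ignore"):
            index = err_place / err_dir if (np.isfinite(err_place)
                                            and np.isfinite(err_dir)
                                            and err_dir > 0) else float("nan")
        return {
            "error_place_assumption": err_place,
            "error_direction_assumption": err_dir,
            "index": float(index) if np.isfinite(index) else float("nan"),
            "reconstructed_H": rprime_H,
        }


# ---------------------------------------------------------------------------
# Classification


@dataclass
class DirectionalResult:
    neuron: int
    curve: dict = dfield(default_factory=dict)  # context -> 8-bin curve
    L: dict = dfield(default_factory=dict)
    angle: dict = dfield(default_factory=dict)
    stability: dict = dfield(default_factory=dict)
    null95_event: dict = dfield(default_factory=dict)
    null95_dir: dict = dfield(default_factory=dict)
    err_place: dict = dfield(default_factory=dict)
    err_dir: dict = dfield(default_factory=dict)
    index: dict = dfield(default_factory=dict)
    passes: dict = dfield(default_factory=dict)  # context -> full conjunction
    tuned_contexts: list = dfield(default_factory=list)
    is_dc: bool = False
    is_conjunctive: bool = False
    selectivity: str = "none"  # context-1-only | context-2-only | both | none
    tuning_difference: float = float("nan")
    total_events: int = 0


def classify_directional_cell(
    neuron: int,
    mappers: dict,
    event_frames: np.ndarray,
    is_place_cell: bool = False,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
    floor: float = STABILITY_FLOOR,
    min_events: int = MIN_EVENTS,
) -> DirectionalResult:
    """Run the full DC screen for one neuron over all contexts.

    The DC conjunction (stable AND above both shuffle nulls AND index > 1)
    must hold within a single context, in at least one context.
    """
    res = DirectionalResult(neuron=neuron, total_events=len(event_frames))
    contexts = sorted(mappers)
    for ctx in contexts:
        mp = mappers[ctx]
        pos = mp.event_positions(event_frames)
        curve, L, ang = mp.tuning(pos)
        res.curve[ctx] = curve
        res.L[ctx] = L
        res.angle[ctx] = ang
        res.stability[ctx] = mp.stability(pos)
        n1, n2 = mp.nulls(pos, n=n_shuffles, seed=seed)
        n1 = n1[np.isfinite(n1)]
        n2 = n2[np.isfinite(n2)]
        res.null95_event[ctx] = float(np.percentile(n1, 95)) if len(n1) else np.nan
        res.null95_dir[ctx] = float(np.percentile(n2, 95)) if len(n2) else np.nan
        rec = mp.reconstruction(pos)
        res.err_place[ctx] = rec["error_place_assumption"]
        res.err_dir[ctx] = rec["error_direction_assumption"]
        res.index[ctx] = rec["index"]
        significant = (np.isfinite(L) and L > res.null95_event[ctx]
                       and L > res.null95_dir[ctx])
        stable = np.isfinite(res.stability[ctx]) and res.stability[ctx] > floor
        idx_ok = np.isfinite(res.index[ctx]) and res.index[ctx] > 1.0
        res.passes[ctx] = bool(significant and stable and idx_ok)
        if significant:
            res.tuned_contexts.append(ctx)
    if res.total_events < min_events:
        res.passes = {c: False for c in contexts}
        res.tuned_contexts = []
    res.is_dc = any(res.passes.values())
    res.is_conjunctive = bool(res.is_dc and is_place_cell)
    if len(res.tuned_contexts) == 2:
        res.selectivity = "both"
        d = wrap_angle(res.angle[contexts[0]] - res.angle[contexts[1]])
        res.tuning_difference = float(np.abs(d))
    elif len(res.tuned_contexts) == 1:
        res.selectivity = (
            "context-1-only" if res.tuned_contexts[0] == contexts[0]
            else "context-2-only"
        )
    return res


# ---------------------------------------------------------------------------
# Landmark tuning


def wall_categories(geometry: ArenaGeometry) -> tuple:
    """Per-wall landmark category for a paradigm, with the shared-bin rule.

    Walls rewarded in any context are 'reward'; light-cue walls are
    'light cue'; a wall that is both is excluded (None); the rest are
    'other'.
    """
    reward = set(geometry.reward_wall.values())
    cue = set().union(*geometry.lightcue_walls.values())
    cats = {}
    for w in range(N_WALLS):
        if w in reward and w in cue:
            cats[w] = None  # shared bin: excluded
        elif w in reward:
            cats[w] = "reward"
        elif w in cue:
            cats[w] = "light cue"
        else:
            cats[w] = "other"
    chance_counts = {}
    for c in cats.values():
        if c is not None:
            chance_counts[c] = chance_counts.get(c, 0) + 1
    total = sum(chance_counts.values())
    chance = {c: n / total for c, n in chance_counts.items()}
    return cats, chance


def landmark_tuning_summary(
    dc_results: list,
    geometry: ArenaGeometry,
    fields_by_neuron: dict | None = None,
) -> dict:
    """Categorize each DC's tuning as reward / light cue / other.

    Uses the Rayleigh angle of the most strongly tuned context.  For
    reward-tuned cells with place fields, reports the distance from the
    reward of the closest field centre.
    """
    cats, chance = wall_categories(geometry)
    composition = {"reward": 0, "light cue": 0, "other": 0, "excluded": 0}
    reward_field_distances = []
    rewards = list(geometry.reward_positions().values())
    for r in dc_results:
        if not r.is_dc or not r.tuned_contexts:
            continue
        best = max(r.tuned_contexts, key=lambda c: r.L[c])
        wall = int(angle_to_wall(r.angle[best]))
        cat = cats[wall]
        if cat is None:
            composition["excluded"] += 1
            continue
        composition[cat] += 1
        if cat == "reward" and fields_by_neuron:
            flds = fields_by_neuron.get(r.neuron, [])
            if flds:
                d = min(
                    min(np.hypot(f.center[0] - p[0], f.center[1] - p[1])
                        for p in rewards)
                    for f in flds
                )
                reward_field_distances.append(float(d))
    return {
        "composition": composition,
        "chance": chance,
        "reward_field_distances": reward_field_distances,
    }
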