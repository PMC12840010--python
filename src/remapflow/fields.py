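"""Place-field segmentation and per-field rate statistics.

Fields are segmented on the pooled-context ('full') rate map: 2D local
maxima with topographic prominence >= 1 event/min set the component count k,
a k-component Gaussian mixture is fitted to the rate surface (bins weighted
by rate, components initialized at the peaks), pixels are assigned by
maximal responsibility, and pixels below 20 % of the field peak are removed.
Fields with a peak below 1 event/min or fewer than two attributed events are
discarded.

Rate remapping per field is the rate overlap score
``1 - |rate1 - rate2| / (rate1 + rate2)`` of the mean field rate in the two
contexts; fields whose centre lies within 10 cm of a rewarded port are
'reward fields' and are classified match / neutral / mismatch by the signed
firing preference with cutoffs at +-0.33.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np

from .geometry import ArenaGeometry
from .spatial import RateMap

MIN_PROMINENCE = 1.0  # events/min
PEAK_CUTOFF_FRAC = 0.20
MIN_PEAK_RATE = 1.0  # events/min
MIN_FIELD_EVENTS = 2
REWARD_RADIUS_CM = 10.0
DISTANCE_BIN_CM = 5.0
PREFERENCE_CUTOFF = 0.33


# ---------------------------------------------------------------------------
# 2D peaks with topographic prominence (persistence via union-find)


def local_maxima_prominence(rate: np.ndarray, valid: np.ndarray) -> list:
    """Local maxima of a 2D surface with their topographic prominence.

    Prominence of a peak is its height above the highest saddle connecting
    it to a higher peak (the global maximum gets height-above-minimum).
    Pixels are processed in descending order with ties broken toward the
    earliest flat index, so plateau peaks collapse to their earliest bin.
    Returns a list of (flat_index, peak_value, prominence), highest first.
    """
    n, m = rate.shape
    vals = np.where(valid, np.nan_to_num(rate, nan=-np.inf), -np.inf).ravel()
    order = np.lexsort((np.arange(vals.size), -vals))
    order = order[np.isfinite(vals[order])]

    parent = {}
    comp_peak_val = {}
    comp_peak_idx = {}
    peaks = []  # (idx, val, prominence)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    processed = np.zeros(vals.size, dtype=bool)
    minval = vals[order[-1]] if len(order) else 0.0
    for idx in order:
        r, c = divmod(idx, m)
        neigh_roots = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n and 0 <= cc < m:
                    j = rr * m + cc
                    if processed[j]:
                        neigh_roots.add(find(j))
        processed[idx] = True
        if not neigh_roots:
            parent[idx] = idx
            comp_peak_val[idx] = vals[idx]
            comp_peak_idx[idx] = idx
            continue
        roots = sorted(neigh_roots, key=lambda rt: (-comp_peak_val[rt], comp_peak_idx[rt]))
        main = roots[0]
        parent[idx] = main
        for other in roots[1:]:
            # the lower peak dies here: its prominence is height above this saddle
            peaks.append((comp_peak_idx[other], comp_peak_val[other],
                          comp_peak_val[other] - vals[idx]))
            parent[other] = main
    # surviving roots (the global maximum of each connected region)
    for idx in set(find(i) for i in parent):
        peaks.append((comp_peak_idx[idx], comp_peak_val[idx],
                      comp_peak_val[idx] - minval))
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks


# ---------------------------------------------------------------------------
# Weighted Gaussian mixture (EM), initialized at the detected peaks


def weighted_gmm(
    X: np.ndarray,
    w: np.ndarray,
    means_init: np.ndarray,
    n_iter: int = 300,
    tol: float = 1e-9,
    reg: float = 0.05,
):
    """EM for a k-component 2D Gaussian mixture with per-sample weights.

    Returns (means, covs, mix, resp).  Weights enter every sufficient
    statistic; covariances are regularized by ``reg * I`` (cm^2).
    """
    k = len(means_init)
    npts = len(X)
    means = np.array(means_init, dtype=float)
    covs = np.tile(np.eye(2) * 9.0, (k, 1, 1))
    mix = np.full(k, 1.0 / k)
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    prev_ll = -np.inf
    resp = np.full((npts, k), 1.0 / k)
    for _ in range(n_iter):
        log_p = np.empty((npts, k))
        for j in range(k):
            diff = X - means[j]
            cov = covs[j]
            det = np.linalg.det(cov)
            inv = np.linalg.inv(cov)
            maha = np.einsum("ni,ij,nj->n", diff, inv, diff)
            log_p[:, j] = -0.5 * (maha + np.log(det) + 2 * np.log(2 * np.pi)) + np.log(
                max(mix[j], 1e-300)
            )
        mx = log_p.max(axis=1, keepdims=True)
        pe = np.exp(log_p - mx)
        norm = pe.sum(axis=1, keepdims=True)
        resp = pe / norm
        ll = float(np.sum(w * (np.log(norm[:, 0]) + mx[:, 0])))
        nk = (w[:, None] * resp).sum(axis=0)
        for j in range(k):
            if nk[j] < 1e-12:  # dead component: re-seed at its init peak
                means[j] = means_init[j]
                covs[j] = np.eye(2) * 9.0
                nk[j] = 1e-12
                continue
            wr = w * resp[:, j]
            means[j] = (wr[:, None] * X).sum(axis=0) / nk[j]
            diff = X - means[j]
            covs[j] = (wr[:, None, None] * np.einsum("ni,nj->nij", diff, diff)).sum(
                axis=0
            ) / nk[j] + reg * np.eye(2)
        mix = nk / max(wsum, 1e-300)
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            break
        prev_ll = ll
    return means, covs, mix, resp


# ---------------------------------------------------------------------------
# Place fields


@dataclass
class PlaceField:
    """A segmented place field of one neuron (pooled-context map)."""

    neuron: int
    field_id: int
    pixels: np.ndarray  # flat bin indices on the map grid
    center: tuple  # (x, y) cm — GMM component mean
    size_cm2: float
    peak_rate: float  # max pooled rate over member pixels, events/min
    rate_by_context: dict = dfield(default_factory=dict)
    reward_distance: Optional[float] = None
    distance_class: Optional[str] = None
    reward_index: Optional[int] = None  # k in {1, 2}: which reward port hosts it
    n_events: int = 0


def segment_place_fields(
    full_map: RateMap,
    event_counts: np.ndarray,
    neuron: int = 0,
    min_prominence: float = MIN_PROMINENCE,
    cutoff_frac: float = PEAK_CUTOFF_FRAC,
    min_peak: float = MIN_PEAK_RATE,
    min_events: int = MIN_FIELD_EVENTS,
) -> list:
    """Segment the pooled-context rate map of one neuron into place fields.

    ``event_counts`` is the per-bin raw event count grid used for the
    two-event floor.  Fields of one neuron are pixel-disjoint by
    construction (maximal-responsibility assignment).
    """
    rate = full_map.rate
    valid = full_map.valid
    peaks = [p for p in local_maxima_prominence(rate, valid)
             if p[2] >= min_prominence and p[1] >= min_peak]
    if not peaks:
        return []
    k = len(peaks)
    grid = full_map.grid
    centers = grid.bin_centers()
    sel = valid.ravel() & (np.nan_to_num(rate.ravel()) > 0)
    X = centers[sel]
    w = np.nan_to_num(rate.ravel())[sel]
    means_init = centers[[p[0] for p in peaks]]
    means, _, _, resp = weighted_gmm(X, w, means_init)
    assign = np.argmax(resp, axis=1)

    flat_idx = np.flatnonzero(sel)
    counts = np.asarray(event_counts).ravel()
    fields = []
    for j in range(k):
        pix = flat_idx[assign == j]
        if len(pix) == 0:
            continue
        pk = float(np.nanmax(rate.ravel()[pix]))
        pix = pix[np.nan_to_num(rate.ravel()[pix]) >= cutoff_frac * pk]
        if len(pix) == 0 or pk < min_peak:
            continue
        n_ev = int(counts[pix].sum())
        if n_ev < min_events:
            continue
        fields.append(
            PlaceField(
                neuron=neuron,
                field_id=len(fields),
                pixels=pix,
                center=tuple(means[j]),
                size_cm2=float(len(pix) * grid.bin_cm**2),
                peak_rate=pk,
                n_events=n_ev,
            )
        )
    return fields


def apply_field_overrides(fields: list, overrides: dict | None) -> list:
    """Declarative replacement for manual field curation.

    ``overrides`` maps a neuron's fields to operations:
    ``{"drop": [field_id, ...], "merge": [[id_a, id_b], ...]}``.  Applied
    after automatic segmentation; merge keeps the larger field's centre.
    """
    if not overrides:
        return fields
    out = {f.field_id: f for f in fields}
    for a, b in overrides.get("merge", []):
        if a in out and b in out:
            fa, fb = out[a], out[b]
            keep, gone = (fa, fb) if fa.size_cm2 >= fb.size_cm2 else (fb, fa)
            keep.pixels = np.union1d(keep.pixels, gone.pixels)
            keep.size_cm2 = float(len(keep.pixels)) * (keep.size_cm2 / max(len(keep.pixels), 1))
            keep.peak_rate = max(keep.peak_rate, gone.peak_rate)
            keep.n_events += gone.n_events
            del out[gone.field_id]
    for fid in overrides.get("drop", []):
        out.pop(fid, None)
    return sorted(out.values(), key=lambda f: f.field_id)


def field_mean_rates(field: PlaceField, maps: dict) -> dict:
    """Mean rate (events/min) over member pixels in each context map."""
    out = {}
    for ctx, m in maps.items():
        r = m.rate.ravel()[field.pixels]
        out[ctx] = float(np.nanmean(r)) if np.any(np.isfinite(r)) else np.nan
    return out


def rate_overlap_score(rate1: float, rate2: float) -> float:
    """1 - |rate1 - rate2| / (rate1 + rate2); 1 = identical, 0 = full remap."""
    s = rate1 + rate2
    if not np.isfinite(s) or s <= 0:
        return float("nan")
    return 1.0 - abs(rate1 - rate2) / s


def firing_preference(rate1: float, rate2: float, k: int) -> float:
    """Signed preference of a reward field for 'its' context.

    ``(rate1 - rate2) / (rate1 + rate2) * (-1)^(k+1)`` with k in {1, 2} the
    index of the reward location hosting the field: positive when the field
    fires more in the context in which its port is rewarded.
    """
    s = rate1 + rate2
    if not np.isfinite(s) or s <= 0:
        return float("nan")
    return (rate1 - rate2) / s * (-1.0) ** (k + 1)


def preference_category(fp: float, cutoff: float = PREFERENCE_CUTOFF) -> str:
    if not np.isfinite(fp):
        return "excluded"
    if fp > cutoff:
        return "match"
    if fp < -cutoff:
        return "mismatch"
    return "neutral"


def assign_reward_fields(fields: list, geometry: ArenaGeometry,
                         reward_radius: float = REWARD_RADIUS_CM,
                         bin_cm: float = DISTANCE_BIN_CM) -> list:
    """Distance classes: centre-to-nearest-reward-port distance.

    'reward' if <= 10 cm; otherwise the 5-cm bin '10-15', '15-20', ....
    With two rewarded ports (discrimination) the closer one counts, and the
    reward index k in {1, 2} follows the context order of the geometry.
    """
    rewards = geometry.reward_positions()
    ctx_order = geometry.contexts
    ports = [rewards[c] for c in ctx_order]
    for f in fields:
        dists = [float(np.hypot(f.center[0] - p[0], f.center[1] - p[1])) for p in ports]
        j = int(np.argmin(dists))
        f.reward_distance = dists[j]
        f.reward_index = 1 if len(set(map(tuple, ports))) == 1 else j + 1
        if f.reward_distance <= reward_radius:
            f.distance_class = "reward"
        else:
            b = int((f.reward_distance - reward_radius) // bin_cm)
            lo = reward_radius + b * bin_cm
            f.distance_class = f"{lo:.0f}-{lo + bin_cm:.0f}"
    return fields


def field_distance_histogram(fields: list) -> dict:
    """Field counts per distance class."""
    out = {}
    for f in fields:
        out[f.distance_class] = out.get(f.distance_class, 0) + 1
    return out
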