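"""Population decoding of context from binned calcium event activity.

Event trains (20 Hz clock) are summed over non-overlapping 60-frame windows
(each frame carries its window's sum), restricted to foraging frames
(running and resting), thinned to every 20th retained frame (1 sample/s),
z-scored, and fed to an RBF-kernel SVM.  80 % of the frames train the
decoder with the kernel scale tuned by 20-fold cross-validation over a
logarithmic grid around the median-pairwise-distance heuristic; the mean
cross-validated accuracy is the reported decoding performance, with the
held-out 20 % accuracy reported separately as an overfitting check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import (
    GridSearchCV,
    GroupKFold,
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

WINDOW_FRAMES = 60
THIN_EVERY = 20
TEST_FRACTION = 0.2
CV_FOLDS = 20
SVM_C = 1.0
GRID_POINTS = 9


@dataclass
class DecoderFrameMatrix:
    """Rows = retained foraging frames (1/s); columns = neurons."""

    X: np.ndarray  # (n_rows, n_neurons) windowed event sums
    context: np.ndarray  # per-row context label
    trial: np.ndarray  # per-row trial index
    correct: np.ndarray  # per-row bool
    frames: np.ndarray  # original frame index per row
    neuron_ids: np.ndarray


@dataclass
class DecodingResult:
    cv_accuracy: float
    holdout_accuracy: float
    kernel_scale: float
    n_rows: int
    n_cells: int
    seed: int
    cell_subset: str = "all"
    trial_subset: str = "all"


def build_decoder_frames(
    session,
    frames,
    neuron_subset=None,
    correct_only: bool = False,
    window: int = WINDOW_FRAMES,
    thin: int = THIN_EVERY,
) -> DecoderFrameMatrix:
    """Windowed, foraging-restricted, thinned population activity matrix.

    Windows are aligned to the session start; restriction to foraging
    frames happens after windowing, then every ``thin``-th remaining frame
    is kept.
    """
    n = session.n_frames
    ids = np.arange(session.n_neurons) if neuron_subset is None \
        else np.asarray(sorted(neuron_subset), dtype=int)
    if len(ids) == 0:
        raise ValueError("empty neuron subset")
    n_win = int(np.ceil(n / window))
    win_sums = np.zeros((n_win, len(ids)))
    for j, ni in enumerate(ids):
        ev = session.events[ni]
        if len(ev):
            win_sums[:, j] = np.bincount(ev // window, minlength=n_win)
    frame_win = np.arange(n) // window

    mask = frames.decoding_mask.copy()
    trial_of = session.trial_of_frame()
    outcome = {t.trial_index: t.outcome for t in session.trials}
    ctx_of = {t.trial_index: t.context for t in session.trials}
    if correct_only:
        ok_trials = {ti for ti, oc in outcome.items() if oc == "correct"}
        mask &= np.isin(trial_of, list(ok_trials))
    restricted = np.flatnonzero(mask)
    retained = restricted[::thin]
    if len(retained) < 40:
        raise ValueError("too few decoder rows for an 80/20 split with 20-fold CV")
    tr = trial_of[retained]
    return DecoderFrameMatrix(
        X=win_sums[frame_win[retained]][:, :],
        context=np.array([ctx_of[t] for t in tr]),
        trial=tr,
        correct=np.array([outcome[t] == "correct" for t in tr]),
        frames=retained,
        neuron_ids=ids,
    )


def _kernel_scale_grid(X: np.ndarray, rng) -> np.ndarray:
    """Logarithmic kernel-scale grid around the median pairwise distance."""
    m = min(len(X), 400)
    idx = rng.choice(len(X), size=m, replace=False)
    S = X[idx]
    d2 = np.sum((S[:, None, :] - S[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices(m, 1)]))
    if not np.isfinite(med) or med <= 0:
        med = 1.0
    return med * np.logspace(-2, 2, GRID_POINTS)


def fit_context_decoder(matrix: DecoderFrameMatrix, seed: int = 0,
                        cv_folds: int = CV_FOLDS,
                        test_fraction: float = TEST_FRACTION,
                        blocked: bool = False) -> DecodingResult:
    """Train the RBF SVM and report mean-CV and held-out accuracies.

    ``blocked=True`` groups the 80/20 split and the CV folds by trial.
    The default random-row split mirrors the standard frame-wise protocol,
    but because consecutive retained frames inside one 60-frame window carry
    identical feature vectors, random splitting lets near-duplicate rows
    leak between training and test and inflates accuracy; calibration
    studies on planted data should use the blocked variant.
    """
    X = matrix.X
    y = matrix.context
    if len(np.unique(y)) < 2:
        raise ValueError("need both context labels to decode")
    keep = X.std(axis=0) > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} constant columns", stacklevel=2)
        X = X[:, keep]
    rng = np.random.default_rng(seed)
    rs = seed % (2**32 - 1)
    if blocked:
        gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction,
                                random_state=rs)
        tr_idx, te_idx = next(gss.split(X, y, groups=matrix.trial))
        X_tr, X_te = X[tr_idx], X[te_idx]
        y_tr, y_te = y[tr_idx], y[te_idx]
        groups_tr = matrix.trial[tr_idx]
        if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError("blocked split left a single-class partition")
        cv = list(GroupKFold(n_splits=min(cv_folds, len(np.unique(groups_tr))))
                  .split(X_tr, y_tr, groups=groups_tr))
    else:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=rs
        )
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=(seed + 1) % (2**32 - 1))
    scaler = StandardScaler().fit(X_tr)
    X_tr = scaler.transform(X_tr)
    X_te = scaler.transform(X_te)
    scales = _kernel_scale_grid(X_tr, rng)
    gammas = 1.0 / scales**2  # K(x, x') = exp(-||x - x'||^2 / s^2)
    search = GridSearchCV(
        SVC(C=SVM_C, kernel="rbf"), {"gamma": list(gammas)}, cv=cv, n_jobs=1
    )
    search.fit(X_tr, y_tr)
    best_gamma = search.best_params_["gamma"]
    return DecodingResult(
        cv_accuracy=float(search.best_score_),
        holdout_accuracy=float(search.best_estimator_.score(X_te, y_te)),
        kernel_scale=float(1.0 / np.sqrt(best_gamma)),
        n_rows=len(matrix.X),
        n_cells=matrix.X.shape[1],
        seed=seed,
    )


def decode_by_subset(
    session,
    frames,
    place_flags: np.ndarray,
    seed: int = 0,
    trial_subsets=("all", "correct"),
    blocked: bool = False,
) -> list:
    """Decoding for {all, place, non-place} x {all trials, correct-only}."""
    place_ids = np.flatnonzero(place_flags)
    nonplace_ids = np.flatnonzero(~np.asarray(place_flags, dtype=bool))
    cell_sets = {
        "all": np.arange(session.n_neurons),
        "place": place_ids,
        "nonplace": nonplace_ids,
    }
    out = []
    for tsub in trial_subsets:
        for name, ids in cell_sets.items():
            if len(ids) == 0:
                continue
            try:
                m = build_decoder_frames(
                    session, frames, neuron_subset=ids,
                    correct_only=(tsub == "correct"),
                )
                r = fit_context_decoder(m, seed=seed, blocked=blocked)
            except ValueError:
                continue
            r.cell_subset = name
            r.trial_subset = tsub
            out.append(r)
    return out


def label_shuffled_accuracy(matrix: DecoderFrameMatrix, seed: int,
                            blocked: bool = False) -> float:
    """Chance-level control: decode with permuted context labels."""
    rng = np.random.default_rng(seed)
    shuffled = DecoderFrameMatrix(
        X=matrix.X,
        context=rng.permutation(matrix.context),
        trial=matrix.trial,
        correct=matrix.correct,
        frames=matrix.frames,
        neuron_ids=matrix.neuron_ids,
    )
    return fit_context_decoder(shuffled, seed=seed, blocked=blocked).cv_accuracy
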