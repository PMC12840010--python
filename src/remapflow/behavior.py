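"""Trial-outcome taxonomy and behavioral performance summaries.

Incorrect trials are typed as: context error (the visited port is the other
context's reward port), spatial precision error (the visited port is
adjacent, +-1 wall, to the correct port), or non-specific error (any other
port).  When a port satisfies both definitions the context label wins
(fixed precedence, so the taxonomy is exhaustive and exclusive).  Error
compositions are compared to a baseline with a Pearson chi-squared test;
learning is summarized as the first day reaching the 70 % criterion on
non-cued trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import TrialRecord
from .geometry import N_WALLS, ArenaGeometry

CRITERION = 0.70

ERROR_TYPES = ("context", "spatial_precision", "non_specific")


def adjacent_walls(wall: int) -> set:
    return {(wall - 1) % N_WALLS, (wall + 1) % N_WALLS}


def classify_trial(trial: TrialRecord, geometry: ArenaGeometry) -> tuple:
    """(outcome, error_type) for one trial; error_type is None unless the
    outcome is 'incorrect'."""
    reward = geometry.reward_wall[trial.context]
    if trial.visited_port is None:
        return "timeout", None
    if trial.visited_port == reward:
        return "correct", None
    other_rewards = {
        w for c, w in geometry.reward_wall.items() if c != trial.context
    } - {reward}
    if trial.visited_port in other_rewards:
        return "incorrect", "context"
    if trial.visited_port in adjacent_walls(reward):
        return "incorrect", "spatial_precision"
    return "incorrect", "non_specific"


@dataclass
class BehaviorSummary:
    n_trials: int
    n_correct: int
    n_timeout: int
    error_counts: dict
    fraction_correct: float


def summarize_session(trials: list, geometry: ArenaGeometry,
                      non_cued_only: bool = True) -> BehaviorSummary:
    """Outcome/error tally over (non-cued) trials of one session."""
    sel = [t for t in trials if not (non_cued_only and t.cued)]
    errors = {e: 0 for e in ERROR_TYPES}
    n_correct = n_timeout = 0
    for t in sel:
        outcome, etype = classify_trial(t, geometry)
        if outcome == "correct":
            n_correct += 1
        elif outcome == "timeout":
            n_timeout += 1
        else:
            errors[etype] += 1
    n = len(sel)
    return BehaviorSummary(
        n_trials=n,
        n_correct=n_correct,
        n_timeout=n_timeout,
        error_counts=errors,
        fraction_correct=n_correct / n if n else float("nan"),
    )


def error_composition(observed: np.ndarray, baseline_props: np.ndarray,
                      n_comparisons: int = 1) -> tuple:
    """Pearson chi-squared of observed counts vs a baseline composition.

    ``baseline_props`` are proportions over the same categories (3 error
    types, or 5 including correct and timeout).  Categories with zero
    expected count are pooled into their neighbour with a warning.  Returns
    (chi2, p_bonferroni_corrected, dof).
    """
    observed = np.asarray(observed, dtype=float)
    props = np.asarray(baseline_props, dtype=float)
    if len(observed) != len(props):
        raise ValueError("category count mismatch")
    props = props / props.sum()
    n = observed.sum()
    expected = n * props
    if np.any(expected == 0):
        import warnings

        warnings.warn("pooling zero-expectation categories", stacklevel=2)
        keep = expected > 0
        observed = np.append(observed[keep], observed[~keep].sum())
        expected = np.append(expected[keep], 0.0)
        expected[-1] = max(expected[-1], 1e-12)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    dof = len(observed) - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, min(1.0, p * n_comparisons), dof


def performance_summary(daily_sessions: list, geometry: ArenaGeometry,
                        criterion: float = CRITERION) -> dict:
    """Learning curve over ordered daily sessions of trial lists.

    Returns per-day fraction correct (non-cued trials) and the first day
    reaching the criterion (1-based; None if never reached).  Days without
    non-cued trials are skipped.
    """
    curve = []
    for day, trials in enumerate(daily_sessions, start=1):
        s = summarize_session(trials, geometry, non_cued_only=True)
        if s.n_trials == 0:
            continue
        curve.append((day, s.fraction_correct))
    days_to_criterion = next((d for d, f in curve if f >= criterion), None)
    return {"curve": curve, "days_to_criterion": days_to_criterion}
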