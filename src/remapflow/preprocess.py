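"""Trace QC, event detection, speed, and analysis-frame segmentation.

The analysis clock is the imaging clock (default 20 Hz).  Speed comes from
the body position smoothed with a 167 ms moving average (3 frames at
20 Hz); all spatial/directional analyses use head position and are
restricted to running (> 2 cm/s) frames of the per-trial foraging phase,
while population decoding keeps resting foraging frames too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import SessionData

SPEED_FILTER_MS = 167.0
RUNNING_SPEED_CMS = 2.0
QC_VALLEY_DFF = 0.1
QC_MINUTES = 5


def smoothing_window_frames(frame_rate: float, width_ms: float = SPEED_FILTER_MS) -> int:
    """Moving-average width in frames, rounded to the nearest odd count."""
    w = max(1, int(round(width_ms / 1000.0 * frame_rate)))
    return w if w % 2 == 1 else w + 1


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 0, edges averaged over the
    available samples (so the output has the input's length)."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window)
    if x.ndim == 1:
        num = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones(len(x)), kernel, mode="same")
        return num / den
    return np.stack([moving_average(x[:, j], window) for j in range(x.shape[1])], axis=1)


def compute_speed(body_xy: np.ndarray, frame_rate: float) -> np.ndarray:
    """Per-frame speed (cm/s) from smoothed body position.

    The last value is replicated so the series matches the tracking length.
    """
    body_xy = np.asarray(body_xy, dtype=float)
    if len(body_xy) < 2:
        raise ValueError("need at least 2 frames to compute speed")
    sm = moving_average(body_xy, smoothing_window_frames(frame_rate))
    disp = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    speed = disp * frame_rate
    return np.append(speed, speed[-1])


def label_trace_stability(
    trace: np.ndarray,
    frame_rate: float,
    valley_threshold: float = QC_VALLEY_DFF,
    minutes: int = QC_MINUTES,
) -> str:
    """Baseline-stability QC of a dF/F0 trace.

    The trace is cut into non-overlapping 1-min sections; the valley of a
    section is its minimum.  The trace is 'unstable' iff the valley exceeds
    ``valley_threshold`` in at least ``minutes`` sections; unstable traces
    are excluded from analysis.
    """
    sec = int(60 * frame_rate)
    n_sections = len(trace) // sec
    if n_sections == 0:
        warnings.warn("trace shorter than one 1-min section; labeled stable",
                      stacklevel=2)
        return "stable"
    valleys = np.asarray(trace[: n_sections * sec]).reshape(n_sections, sec).min(axis=1)
    return "unstable" if int(np.sum(valleys > valley_threshold)) >= minutes else "stable"


def detect_events(deconv: np.ndarray, min_prominence: float = 0.5) -> np.ndarray:
    """Peak detection on a deconvolved trace -> sorted event frame indices.

    Plateau peaks collapse to their earliest frame.
    """
    deconv = np.asarray(deconv, dtype=float)
    if not np.all(np.isfinite(deconv)):
        raise ValueError("deconvolved series contains non-finite values")
    peaks, props = find_peaks(deconv, prominence=min_prominence, plateau_size=(1, None))
    return props["left_edges"].astype(int)


# ---------------------------------------------------------------------------
# Analysis frames


@dataclass
class AnalysisFrames:
    """Per-frame masks and per-trial foraging segments.

    ``segments`` rows: (trial_index, context, forage_start, trigger_frame).
    The foraging phase of a trial starts at the first frame with speed
    > 2 cm/s after trial start and ends at the trigger (tone) frame.
    ``spatial_mask`` additionally requires running; ``decoding_mask`` keeps
    resting foraging frames.
    """

    is_foraging: np.ndarray
    is_running: np.ndarray
    is_rest: np.ndarray
    segments: list = field(default_factory=list)

    @property
    def spatial_mask(self) -> np.ndarray:
        return self.is_foraging & self.is_running

    @property
    def decoding_mask(self) -> np.ndarray:
        return self.is_foraging


def extract_analysis_frames(
    session: SessionData,
    speed: np.ndarray,
    running_threshold: float = RUNNING_SPEED_CMS,
) -> AnalysisFrames:
    """Segment a session into per-trial foraging frames."""
    if len(speed) != session.n_frames:
        raise ValueError("speed series not aligned with tracking")
    n = session.n_frames
    is_running = speed > running_threshold
    is_foraging = np.zeros(n, dtype=bool)
    segments = []
    for t in session.trials:
        moving = np.flatnonzero(is_running[t.start_frame : t.trigger_frame])
        if len(moving) == 0:
            # no locomotion before the tone: this trial contributes no frames
            segments.append((t.trial_index, t.context, t.trigger_frame, t.trigger_frame))
            continue
        forage_start = t.start_frame + int(moving[0])
        is_foraging[forage_start : t.trigger_frame] = True
        segments.append((t.trial_index, t.context, forage_start, t.trigger_frame))
    return AnalysisFrames(
        is_foraging=is_foraging,
        is_running=is_running,
        is_rest=~is_running,
        segments=segments,
    )


def context_frame_sequence(
    frames: AnalysisFrames,
    context: str,
    mode: str = "spatial",
) -> tuple:
    """Concatenated frame indices of one context's foraging segments.

    Returns (frame_indices, segment_id per position, trial_index per
    position).  ``mode='spatial'`` keeps running frames only; ``'decoding'``
    keeps all foraging frames.
    """
    run = frames.is_running
    seqs, seg_ids, trial_ids = [], [], []
    for si, (ti, ctx, a, b) in enumerate(frames.segments):
        if ctx != context or b <= a:
            continue
        idx = np.arange(a, b)
        if mode == "spatial":
            idx = idx[run[a:b]]
        seqs.append(idx)
        seg_ids.append(np.full(len(idx), si))
        trial_ids.append(np.full(len(idx), ti))
    if not seqs:
        z = np.zeros(0, dtype=int)
        return z, z.copy(), z.copy()
    return np.concatenate(seqs), np.concatenate(seg_ids), np.concatenate(trial_ids)
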