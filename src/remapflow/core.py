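"""Core data containers: trials, sessions, and planted ground truth.

A :class:`SessionData` is one recording session on a single master clock
(default 20 Hz): head/body tracking, a trial table, and per-neuron calcium
event trains given as sorted frame indices.  Real tracking acquired at a
different camera rate must be resampled to the imaging clock before being
loaded into a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import ArenaGeometry

DEFAULT_FRAME_RATE = 20.0

OUTCOMES = ("correct", "incorrect", "timeout")


@dataclass
class TrialRecord:
    """One behavioral trial.

    Frames: ``start_frame <= trigger_frame < end_frame``; the foraging phase
    is ``[start, trigger)`` and the reward-retrieval phase ``[trigger, end)``.
    The trigger zone is a hidden 7x7 cm square; its centre is stored.
    ``visited_port`` is ``None`` on timeout trials.
    """

    trial_index: int
    context: str
    start_frame: int
    trigger_frame: int
    end_frame: int
    cued: bool = False
    outcome: str = "correct"
    visited_port: Optional[int] = None
    trigger_zone: tuple = (0.0, 0.0)

    def validate(self, frame_rate: float = DEFAULT_FRAME_RATE) -> None:
        if not (self.start_frame <= self.trigger_frame <= self.end_frame):
            raise ValueError(f"trial {self.trial_index}: frames out of order")
        if self.trigger_frame - self.start_frame < int(10 * frame_rate):
            raise ValueError(
                f"trial {self.trial_index}: trigger earlier than 10 s after start"
            )
        if self.outcome not in OUTCOMES:
            raise ValueError(f"trial {self.trial_index}: bad outcome {self.outcome!r}")
        if self.outcome != "timeout" and self.visited_port is None:
            raise ValueError(f"trial {self.trial_index}: non-timeout trial lacks a port")


@dataclass
class SessionData:
    """One session: tracking, trials, and per-neuron event trains."""

    geometry: ArenaGeometry
    frame_rate: float
    head_xy: np.ndarray  # (n_frames, 2) cm
    body_xy: np.ndarray  # (n_frames, 2) cm
    trials: list  # list[TrialRecord]
    events: list  # list[np.ndarray] sorted frame indices per neuron
    paradigm: str = "discrimination"
    traces_dff: Optional[np.ndarray] = None  # (n_neurons, n_frames)
    traces_deconv: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return len(self.head_xy)

    @property
    def n_neurons(self) -> int:
        return len(self.events)

    @property
    def contexts(self) -> list:
        return sorted({t.context for t in self.trials})

    @property
    def duration_min(self) -> float:
        return self.n_frames / self.frame_rate / 60.0

    def trial_of_frame(self) -> np.ndarray:
        """Per-frame trial index (-1 outside all trials)."""
        out = np.full(self.n_frames, -1, dtype=int)
        for t in self.trials:
            out[t.start_frame : t.end_frame] = t.trial_index
        return out

    def validate(self) -> None:
        if self.head_xy.shape != self.body_xy.shape or self.head_xy.ndim != 2:
            raise ValueError("tracking arrays must be (n_frames, 2) and congruent")
        if not np.all(self.geometry.contains(self.body_xy)):
            raise ValueError("body positions outside the arena")
        last_end = -1
        for t in self.trials:
            t.validate(self.frame_rate)
            if t.start_frame < last_end:
                raise ValueError("trial intervals overlap or are unordered")
            last_end = t.end_frame
        for i, ev in enumerate(self.events):
            if len(ev) and (ev[-1] >= self.n_frames or ev[0] < 0):
                raise ValueError(f"neuron {i}: event frame out of range")
            if np.any(np.diff(ev) < 0):
                raise ValueError(f"neuron {i}: events not sorted")


# ---------------------------------------------------------------------------
# Planted ground truth for synthetic sessions


@dataclass
class FieldSpec:
    """A planted 2D Gaussian place field.

    ``gain`` maps context label -> multiplicative rate gain (rate remapping);
    ``center_by_context`` optionally relocates the field per context (global
    remapping).  ``amplitude`` is the peak rate contribution in events/min.
    """

    center: tuple  # (x, y) cm
    width: float  # isotropic sigma, cm
    amplitude: float  # events/min at field centre (before gain)
    gain: dict = field(default_factory=dict)
    center_by_context: Optional[dict] = None

    def __post_init__(self):
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("field width and amplitude must be positive")
        if any(g < 0 for g in self.gain.values()):
            raise ValueError("context gains must be nonnegative")

    def center_in(self, context: str) -> tuple:
        if self.center_by_context and context in self.center_by_context:
            return tuple(self.center_by_context[context])
        return tuple(self.center)


@dataclass
class DirectionalSpec:
    """Planted von Mises tuning of the event rate to relative running
    direction H: rate multiplier ``max(0, 1 + depth * vm(H))`` with ``vm``
    the von Mises kernel normalized to zero circular mean and unit peak.

    ``contexts`` restricts the modulation to a subset of contexts
    (context-selective tuning); empty means modulated in all contexts.
    """

    mu: float  # preferred relative direction, rad in [-pi, pi)
    kappa: float  # concentration
    depth: float  # modulation depth >= 0
    contexts: tuple = ()

    def __post_init__(self):
        if not (-np.pi <= self.mu < np.pi):
            raise ValueError("mu must lie in [-pi, pi)")
        if self.kappa < 0 or self.depth < 0:
            raise ValueError("kappa and depth must be nonnegative")


@dataclass
class NeuronTruth:
    """Planted tuning of one synthetic neuron."""

    cell_class: str  # place | directional | conjunctive | background
    baseline_rate: float = 0.2  # events/min
    fields: list = field(default_factory=list)  # list[FieldSpec]
    directional: Optional[DirectionalSpec] = None
    remapping: str = "none"  # none | rate-only | global


@dataclass
class GroundTruth:
    """Planted tuning parameters of a whole synthetic session."""

    neurons: list  # list[NeuronTruth]

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)
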