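"""Synthetic session generator.

Emulates the statistical structure the analysis assumes: a foraging mouse in
an octagonal two-context arena, pseudo-randomized balanced trial blocks with
a hidden 7x7 cm trigger zone, inhomogeneous-Poisson calcium event trains
driven by planted 2D Gaussian place fields (with per-context gain and
optional field relocation) and von Mises directional modulation relative to
a reference point, plus optional dF/F0 and deconvolved traces.

Everything is generated on one master clock (default 20 Hz) and is
deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_FRAME_RATE,
    DirectionalSpec,
    FieldSpec,
    GroundTruth,
    NeuronTruth,
    SessionData,
    TrialRecord,
)
from .geometry import ArenaGeometry, default_geometry

TRIGGER_ZONE_HALF = 3.5  # cm; hidden trigger zone is 7 x 7 cm
MIN_FORAGE_S = 10.0  # trigger cannot fire before 10 s into the trial
TIMEOUT_S = 60.0  # reward-retrieval phase times out after 1 min
ITI_S = 3.0  # inter-trial interval


@dataclass
class MotionParams:
    """Correlated-random-walk parameters for the foraging trajectory."""

    mean_speed: float = 9.0  # cm/s while running
    speed_tau: float = 1.0  # s, OU relaxation time of speed
    speed_sigma: float = 5.0  # cm/s/sqrt(s), OU noise
    turn_sigma: float = 2.2  # rad/sqrt(s), heading diffusion
    pause_prob: float = 0.0015  # per-frame probability of entering a rest bout
    pause_mean_s: float = 1.5  # mean rest-bout duration
    wall_bias: float = 0.0  # 0..1, tendency to run along the wall when near it
    head_offset: float = 1.5  # cm, head leads body along the heading


def simulate_trajectory(
    geometry: ArenaGeometry,
    duration_s: float,
    seed: int,
    motion: MotionParams | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
):
    """Confined correlated random walk; returns (head_xy, body_xy).

    The walk alternates running bouts (OU speed around ``mean_speed``,
    diffusing heading, specular reflection off the walls) and resting bouts
    (speed < 2 cm/s).  A 40-min default run covers > 90 % of the 2x2 cm bins
    inside the octagon.
    """
    if duration_s < 0:
        raise ValueError("duration must be nonnegative")
    motion = motion or MotionParams()
    n = int(round(duration_s * frame_rate))
    if n == 0:
        empty = np.zeros((0, 2))
        return empty, empty.copy()

    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    apo = geometry.apothem
    angles = np.arange(8) * np.pi / 4
    normals = np.stack([np.cos(angles), np.sin(angles)], axis=1)

    body = np.zeros((n, 2))
    pos = np.zeros(2)
    heading = rng.uniform(-np.pi, np.pi)
    speed = motion.mean_speed
    rest_left = 0

    sq_dt = np.sqrt(dt)
    for i in range(n):
        if rest_left > 0:
            rest_left -= 1
            step_speed = rng.uniform(0.0, 1.0)  # < 2 cm/s: resting
        else:
            if rng.random() < motion.pause_prob:
                rest_left = max(1, int(rng.exponential(motion.pause_mean_s) * frame_rate))
                step_speed = 0.0
            else:
                speed += (
                    (motion.mean_speed - speed) * dt / motion.speed_tau
                    + motion.speed_sigma * sq_dt * rng.standard_normal()
                )
                speed = float(np.clip(speed, 2.5, 4.0 * motion.mean_speed))
                heading += motion.turn_sigma * sq_dt * rng.standard_normal()
                step_speed = speed
                if motion.wall_bias > 0:
                    proj = pos @ normals.T
                    k = int(np.argmax(proj))
                    if proj[k] > apo - 3.0 and rng.random() < motion.wall_bias:
                        # steer along the nearest wall (tangent direction)
                        tangent = angles[k] + np.pi / 2
                        if np.cos(heading - tangent) < 0:
                            tangent += np.pi
                        heading = tangent + 0.15 * rng.standard_normal()
        vel = step_speed * np.array([np.cos(heading), np.sin(heading)])
        new = pos + vel * dt
        for _ in range(4):  # reflect off violated walls (corners need 2 passes)
            proj = new @ normals.T
            k = int(np.argmax(proj))
            if proj[k] <= apo:
                break
            nrm = normals[k]
            new = new - 2.0 * (new @ nrm - apo) * nrm
            vel = vel - 2.0 * (vel @ nrm) * nrm
            heading = float(np.arctan2(vel[1], vel[0]))
        if not geometry.contains(new)[0]:  # pathological corner: jump inward
            new = pos * 0.5
        pos = new
        body[i] = pos

    # head leads the body along the instantaneous heading, with jitter
    disp = np.diff(body, axis=0, prepend=body[:1])
    norms = np.linalg.norm(disp, axis=1, keepdims=True)
    unit = np.divide(disp, norms, out=np.zeros_like(disp), where=norms > 1e-9)
    # carry last heading through resting frames
    for i in range(1, n):
        if norms[i, 0] <= 1e-9:
            unit[i] = unit[i - 1]
    head = body + motion.head_offset * unit + 0.1 * rng.standard_normal((n, 2))
    # keep head inside the arena (iterate: a corner can violate two walls)
    for _ in range(3):
        proj = head @ normals.T
        over = proj - apo
        bad = over.max(axis=1) > 0
        if not np.any(bad):
            break
        k = np.argmax(proj[bad], axis=1)
        head[bad] -= (over[bad, k] + 1e-9)[:, None] * normals[k]
    return head, body


# ---------------------------------------------------------------------------
# Trial schedule


def balanced_context_schedule(contexts, n_trials: int, rng) -> list:
    """Pseudo-randomized schedule: shuffled context pairs, so every prefix is
    balanced within +-1 and identities are intermingled."""
    out = []
    while len(out) < n_trials:
        pair = list(contexts)
        rng.shuffle(pair)
        out.extend(pair)
    return out[:n_trials]


@dataclass
class AgentPolicy:
    """Which port the synthetic agent visits during reward retrieval.

    kind: 'perfect' (always the rewarded port), 'random-port' (uniform over
    the 8 ports), or 'biased' (correct with probability ``p_correct``).
    """

    kind: str = "perfect"
    p_correct: float = 0.8
    p_timeout: float = 0.0

    def visit(self, reward_wall: int, rng) -> int | None:
        if self.p_timeout > 0 and rng.random() < self.p_timeout:
            return None
        if self.kind == "perfect":
            return reward_wall
        if self.kind == "random-port":
            return int(rng.integers(8))
        if self.kind == "biased":
            if rng.random() < self.p_correct:
                return reward_wall
            others = [w for w in range(8) if w != reward_wall]
            return int(others[rng.integers(7)])
        raise ValueError(f"unknown policy {self.kind!r}")


def simulate_trial_sequence(
    geometry: ArenaGeometry,
    body_xy: np.ndarray,
    n_trials: int,
    seed: int,
    policy: AgentPolicy | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> list:
    """Lay a balanced trial sequence over a pre-generated trajectory.

    Each trial gets a random hidden 7x7 cm trigger zone; the trigger frame is
    the first body entry into the zone at least 10 s after trial start.  If
    the trajectory is exhausted before ``n_trials`` are placed, the sequence
    is truncated with a warning.
    """
    rng = np.random.default_rng(seed)
    policy = policy or AgentPolicy()
    contexts = geometry.contexts
    schedule = balanced_context_schedule(contexts, n_trials, rng)
    n_frames = len(body_xy)
    min_forage = int(MIN_FORAGE_S * frame_rate)
    iti = int(ITI_S * frame_rate)
    timeout = int(TIMEOUT_S * frame_rate)

    trials = []
    cursor = 0
    for ctx in schedule:
        start = cursor
        if start + min_forage >= n_frames:
            break
        # rejection-sample a zone centre whose square fits inside the octagon
        while True:
            zone = rng.uniform(-geometry.radius, geometry.radius, size=2)
            corners = zone + TRIGGER_ZONE_HALF * np.array(
                [[1, 1], [1, -1], [-1, 1], [-1, -1]]
            )
            if np.all(geometry.contains(corners)):
                break
        seg = body_xy[start + min_forage :]
        inzone = np.all(np.abs(seg - zone) <= TRIGGER_ZONE_HALF, axis=1)
        hits = np.flatnonzero(inzone)
        if len(hits) == 0:
            break
        trigger = start + min_forage + int(hits[0])
        visited = policy.visit(geometry.reward_wall[ctx], rng)
        if visited is None:
            outcome = "timeout"
            end = trigger + timeout
        else:
            outcome = "correct" if visited == geometry.reward_wall[ctx] else "incorrect"
            end = trigger + int(rng.uniform(2.0, 8.0) * frame_rate)
        end = min(end, n_frames)
        trials.append(
            TrialRecord(
                trial_index=len(trials),
                context=ctx,
                start_frame=start,
                trigger_frame=trigger,
                end_frame=end,
                cued=False,
                outcome=outcome,
                visited_port=visited,
                trigger_zone=tuple(zone),
            )
        )
        cursor = end + iti
        if cursor >= n_frames:
            break
    if len(trials) < n_trials:
        warnings.warn(
            f"trajectory exhausted: placed {len(trials)} of {n_trials} trials",
            stacklevel=2,
        )
    return trials


# ---------------------------------------------------------------------------
# Event trains


def _context_code_per_frame(trials, n_frames, contexts):
    """Per-frame context index into ``contexts`` (-1 outside trials)."""
    code = np.full(n_frames, -1, dtype=int)
    lut = {c: i for i, c in enumerate(contexts)}
    for t in trials:
        code[t.start_frame : t.end_frame] = lut[t.context]
    return code


def _heading_series(head_xy):
    """Per-frame allocentric heading from head displacement (NaN when still)."""
    d = np.diff(head_xy, axis=0)
    phi = np.arctan2(d[:, 1], d[:, 0])
    still = np.hypot(d[:, 0], d[:, 1]) < 1e-9
    phi[still] = np.nan
    return np.append(phi, np.nan)


def simulate_event_trains(
    truth: GroundTruth,
    geometry: ArenaGeometry,
    head_xy: np.ndarray,
    trials: list,
    seed: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
    body_xy: np.ndarray | None = None,
) -> list:
    """Inhomogeneous-Poisson event trains (Bernoulli thinning per frame).

    Per-frame rate:
    ``lambda(t) = [baseline + sum_fields amp * exp(-d^2/2w^2) * g_ctx(t)]
    * max(0, 1 + depth * vm(H_t))`` for directionally modulated cells, where
    ``vm`` is the von Mises kernel ``exp(kappa*(cos(H - mu) - 1))``
    normalized to zero circular mean and unit peak, so the rate is enhanced
    toward the preferred relative direction and suppressed away from it.
    Outside trials the context gain is the mean over contexts; on frames
    with undefined heading the directional factor is 1.
    """
    rng = np.random.default_rng(seed)
    n = len(head_xy)
    contexts = geometry.contexts
    code = _context_code_per_frame(trials, n, contexts)
    rx, ry = geometry.reference_point
    # true running direction comes from body motion (head carries tracker
    # jitter); the bearing to the reference uses the head like the analysis
    phi = _heading_series(body_xy if body_xy is not None else head_xy)
    bearing = np.arctan2(ry - head_xy[:, 1], rx - head_xy[:, 0])
    H = np.mod(phi - bearing + np.pi, 2 * np.pi) - np.pi  # NaN propagates

    dt_min = 1.0 / (frame_rate * 60.0)
    events = []
    for nt in truth.neurons:
        lam = np.full(n, nt.baseline_rate)
        for f in nt.fields:
            for ci, ctx in enumerate(contexts):
                sel = code == ci
                if not np.any(sel):
                    continue
                cx, cy = f.center_in(ctx)
                g = f.gain.get(ctx, 1.0)
                if g == 0:
                    continue
                d2 = (head_xy[sel, 0] - cx) ** 2 + (head_xy[sel, 1] - cy) ** 2
                lam[sel] += f.amplitude * g * np.exp(-d2 / (2 * f.width**2))
            out = code == -1
            if np.any(out):
                gbar = np.mean([f.gain.get(c, 1.0) for c in contexts])
                cx, cy = f.center
                d2 = (head_xy[out, 0] - cx) ** 2 + (head_xy[out, 1] - cy) ** 2
                lam[out] += f.amplitude * gbar * np.exp(-d2 / (2 * f.width**2))
        if nt.directional is not None and nt.directional.depth > 0:
            ds = nt.directional
            from scipy.special import i0

            vm = np.exp(ds.kappa * (np.cos(H - ds.mu) - 1.0))
            c = float(np.exp(-ds.kappa) * i0(ds.kappa))  # circular mean of vm
            vm = (vm - c) / (1.0 - c)
            factor = np.clip(1.0 + ds.depth * np.where(np.isnan(vm), 0.0, vm), 0.0, None)
            if ds.contexts:
                active = np.isin(code, [contexts.index(c) for c in ds.contexts])
                factor = np.where(active, factor, 1.0)
            lam = lam * factor
        assert np.all(lam >= 0)
        p = 1.0 - np.exp(-lam * dt_min)
        events.append(np.flatnonzero(rng.random(n) < p).astype(int))
    return events


# ---------------------------------------------------------------------------
# Calcium traces


def simulate_calcium_traces(
    events_per_neuron: list,
    n_frames: int,
    seed: int,
    stability_mode: str = "stable",
    frame_rate: float = DEFAULT_FRAME_RATE,
    noise_sd: float = 0.02,
):
    """dF/F0 + deconvolved traces from event trains.

    dF/F0 = events convolved with a fast-rise / exponential-decay (tau=0.5 s)
    kernel plus white noise.  ``stability_mode='unstable'`` adds a slow
    baseline plateau exceeding 0.1 dF/F0 for longer than 5 min, which the
    downstream QC rule flags.  The deconvolved series has a unit peak at each
    event frame.
    """
    rng = np.random.default_rng(seed)
    tau_frames = 0.5 * frame_rate
    t = np.arange(int(6 * tau_frames))
    kernel = np.exp(-t / tau_frames)
    kernel[0] = 0.6  # fast rise: first frame below peak

    dff = np.zeros((len(events_per_neuron), n_frames))
    deconv = np.zeros_like(dff)
    for i, ev in enumerate(events_per_neuron):
        impulse = np.zeros(n_frames)
        if len(ev):
            np.add.at(impulse, ev, 1.0)
        dff[i] = np.convolve(impulse, kernel)[:n_frames]
        deconv[i] = impulse + 0.001 * rng.random(n_frames)
        dff[i] += noise_sd * rng.standard_normal(n_frames)
        if stability_mode == "unstable":
            drift = np.zeros(n_frames)
            span = min(n_frames, int(6.5 * 60 * frame_rate))
            ramp = int(0.25 * 60 * frame_rate)
            drift[:span] = 0.18
            drift[:ramp] = np.linspace(0.0, 0.18, ramp)
            dff[i] += drift
    return dff, deconv


# ---------------------------------------------------------------------------
# Ground-truth factories and full-session convenience


def make_ground_truth(
    geometry: ArenaGeometry,
    seed: int,
    n_place: int = 0,
    n_directional: int = 0,
    n_conjunctive: int = 0,
    n_background: int = 0,
    remapping: str = "none",
    gain_b: float = 1.0,
    field_amplitude: float = 30.0,
    field_width: float = 5.0,
    place_baseline: float = 0.1,
    background_rate: float = 6.0,
    directional_rate: float = 15.0,
    kappa: float = 2.0,
    depth: float = 0.8,
    directional_contexts: tuple = (),
) -> GroundTruth:
    """Draw a population of planted neurons.

    ``remapping``: 'none' (identical fields and gains in both contexts),
    'rate-only' (same fields, context-2 gain = ``gain_b``), or 'global'
    (independent field centres per context).
    """
    rng = np.random.default_rng(seed)
    contexts = geometry.contexts

    def rand_center():
        while True:
            c = rng.uniform(-geometry.radius, geometry.radius, 2)
            if geometry.contains(c, margin=3.0)[0]:
                return tuple(c)

    def make_fields():
        f = FieldSpec(
            center=rand_center(),
            width=field_width,
            amplitude=field_amplitude,
            gain={c: 1.0 for c in contexts},
        )
        if remapping == "rate-only" and len(contexts) == 2:
            f.gain[contexts[1]] = gain_b
        elif remapping == "global":
            f.center_by_context = {c: rand_center() for c in contexts}
        return [f]

    neurons = []
    for _ in range(n_place):
        neurons.append(
            NeuronTruth("place", baseline_rate=place_baseline, fields=make_fields(),
                        remapping=remapping)
        )
    for _ in range(n_directional):
        neurons.append(
            NeuronTruth(
                "directional",
                baseline_rate=directional_rate,
                directional=DirectionalSpec(
                    mu=float(rng.uniform(-np.pi, np.pi)),
                    kappa=kappa,
                    depth=depth,
                    contexts=directional_contexts,
                ),
            )
        )
    for _ in range(n_conjunctive):
        neurons.append(
            NeuronTruth(
                "conjunctive",
                baseline_rate=place_baseline,
                fields=make_fields(),
                directional=DirectionalSpec(
                    mu=float(rng.uniform(-np.pi, np.pi)),
                    kappa=kappa,
                    depth=depth,
                    contexts=directional_contexts,
                ),
                remapping=remapping,
            )
        )
    for _ in range(n_background):
        neurons.append(NeuronTruth("background", baseline_rate=background_rate))
    return GroundTruth(neurons=neurons)


def simulate_session(
    truth: GroundTruth,
    geometry: ArenaGeometry | None = None,
    paradigm: str = "discrimination",
    duration_min: float = 40.0,
    n_trials: int = 100,
    seed: int = 0,
    policy: AgentPolicy | None = None,
    motion: MotionParams | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    with_traces: bool = False,
) -> SessionData:
    """Generate a complete synthetic session (trajectory, trials, events)."""
    geometry = geometry or default_geometry(paradigm)
    head, body = simulate_trajectory(
        geometry, duration_min * 60.0, seed=seed, motion=motion, frame_rate=frame_rate
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # truncation expected: trials fill the session
        trials = simulate_trial_sequence(
            geometry, body, n_trials, seed=seed + 1, policy=policy, frame_rate=frame_rate
        )
    events = simulate_event_trains(
        truth, geometry, head, trials, seed=seed + 2, frame_rate=frame_rate,
        body_xy=body,
    )
    dff = deconv = None
    if with_traces:
        dff, deconv = simulate_calcium_traces(
            events, len(head), seed=seed + 3, frame_rate=frame_rate
        )
    return SessionData(
        geometry=geometry,
        frame_rate=frame_rate,
        head_xy=head,
        body_xy=body,
        trials=trials,
        events=events,
        paradigm=paradigm,
        traces_dff=dff,
        traces_deconv=deconv,
    )
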