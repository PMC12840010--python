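"""Dataset layout on disk (plain-text, round-trip lossless).

    DIR/
      tracking.csv        frame, head_x, head_y, body_x, body_y
      trials.csv          one row per trial
      events/n<k>.csv     event frame indices, one per line
      geometry.json
      truth.json          planted ground truth (synthetic sessions only)
      config.json         generator / run configuration
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DirectionalSpec,
    FieldSpec,
    GroundTruth,
    NeuronTruth,
    SessionData,
    TrialRecord,
)
from .geometry import ArenaGeometry

_TRIAL_COLS = [
    "trial_index", "context", "start_frame", "trigger_frame", "end_frame",
    "cued", "outcome", "visited_port", "trigger_zone_x", "trigger_zone_y",
]


def neuron_id(i: int) -> str:
    return f"n{i:04d}"


def write_dataset(
    session: SessionData,
    directory,
    truth: GroundTruth | None = None,
    config: dict | None = None,
) -> Path:
    d = Path(directory)
    (d / "events").mkdir(parents=True, exist_ok=True)

    n = session.n_frames
    pd.DataFrame(
        {
            "frame": np.arange(n),
            "head_x": session.head_xy[:, 0],
            "head_y": session.head_xy[:, 1],
            "body_x": session.body_xy[:, 0],
            "body_y": session.body_xy[:, 1],
        }
    ).to_csv(d / "tracking.csv", index=False, float_format="%.10g")

    rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "context": t.context,
                "start_frame": t.start_frame,
                "trigger_frame": t.trigger_frame,
                "end_frame": t.end_frame,
                "cued": int(t.cued),
                "outcome": t.outcome,
                "visited_port": -1 if t.visited_port is None else t.visited_port,
                "trigger_zone_x": t.trigger_zone[0],
                "trigger_zone_y": t.trigger_zone[1],
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(
        d / "trials.csv", index=False, float_format="%.10g"
    )

    for i, ev in enumerate(session.events):
        np.savetxt(d / "events" / f"{neuron_id(i)}.csv", np.asarray(ev, dtype=int),
                   fmt="%d", header="frame", comments="")

    meta = {
        "frame_rate": session.frame_rate,
        "n_frames": n,
        "n_neurons": session.n_neurons,
        "paradigm": session.paradigm,
        "geometry": session.geometry.to_dict(),
    }
    (d / "geometry.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        (d / "truth.json").write_text(json.dumps(truth_to_dict(truth), indent=1))
    if config is not None:
        (d / "config.json").write_text(json.dumps(config, indent=1))
    return d


def read_dataset(directory) -> tuple:
    """Read a dataset directory; returns (session, truth_or_None, config_or_None)."""
    d = Path(directory)
    meta = json.loads((d / "geometry.json").read_text())
    if not (d / "trials.csv").exists():
        raise FileNotFoundError(f"missing trials table: {d / 'trials.csv'}")
    track = pd.read_csv(d / "tracking.csv")
    tdf = pd.read_csv(d / "trials.csv")
    trials = [
        TrialRecord(
            trial_index=int(r.trial_index),
            context=str(r.context),
            start_frame=int(r.start_frame),
            trigger_frame=int(r.trigger_frame),
            end_frame=int(r.end_frame),
            cued=bool(r.cued),
            outcome=str(r.outcome),
            visited_port=None if int(r.visited_port) < 0 else int(r.visited_port),
            trigger_zone=(float(r.trigger_zone_x), float(r.trigger_zone_y)),
        )
        for r in tdf.itertuples()
    ]
    events = []
    for i in range(int(meta["n_neurons"])):
        path = d / "events" / f"{neuron_id(i)}.csv"
        arr = np.loadtxt(path, skiprows=1, dtype=int, ndmin=1) if path.stat().st_size > 6 else np.array([], dtype=int)
        events.append(np.atleast_1d(arr))
    session = SessionData(
        geometry=ArenaGeometry.from_dict(meta["geometry"]),
        frame_rate=float(meta["frame_rate"]),
        head_xy=track[["head_x", "head_y"]].to_numpy(),
        body_xy=track[["body_x", "body_y"]].to_numpy(),
        trials=trials,
        events=events,
        paradigm=meta["paradigm"],
    )
    truth = None
    if (d / "truth.json").exists():
        truth = truth_from_dict(json.loads((d / "truth.json").read_text()))
    config = None
    if (d / "config.json").exists():
        config = json.loads((d / "config.json").read_text())
    return session, truth, config


# ---------------------------------------------------------------------------
# Ground-truth (de)serialization


def truth_to_dict(truth: GroundTruth) -> dict:
    neurons = []
    for i, nt in enumerate(truth.neurons):
        d = {
            "neuron_id": neuron_id(i),
            "cell_class": nt.cell_class,
            "baseline_rate": nt.baseline_rate,
            "remapping": nt.remapping,
            "fields": [
                {
                    "center": list(f.center),
                    "width": f.width,
                    "amplitude": f.amplitude,
                    "gain": dict(f.gain),
                    "center_by_context": (
                        None
                        if f.center_by_context is None
                        else {k: list(v) for k, v in f.center_by_context.items()}
                    ),
                }
                for f in nt.fields
            ],
            "directional": (
                None
                if nt.directional is None
                else dataclasses.asdict(nt.directional)
            ),
        }
        neurons.append(d)
    return {"neurons": neurons}


def truth_from_dict(d: dict) -> GroundTruth:
    neurons = []
    for nd in d["neurons"]:
        fields = [
            FieldSpec(
                center=tuple(fd["center"]),
                width=fd["width"],
                amplitude=fd["amplitude"],
                gain=dict(fd["gain"]),
                center_by_context=(
                    None
                    if fd["center_by_context"] is None
                    else {k: tuple(v) for k, v in fd["center_by_context"].items()}
                ),
            )
            for fd in nd["fields"]
        ]
        ds = nd["directional"]
        neurons.append(
            NeuronTruth(
                cell_class=nd["cell_class"],
                baseline_rate=nd["baseline_rate"],
                fields=fields,
                directional=None
                if ds is None
                else DirectionalSpec(
                    mu=ds["mu"], kappa=ds["kappa"], depth=ds["depth"],
                    contexts=tuple(ds["contexts"]),
                ),
                remapping=nd["remapping"],
            )
        )
    return GroundTruth(neurons=neurons)
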