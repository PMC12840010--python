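"""Generate the synthetic two-paradigm study.

One simulated mouse experiences a discrimination session (contexts A/B,
rewards at opposite walls) and a generalization session (contexts C/D, one
shared reward).  The planted population mixes place cells — remapping more
strongly between A and B (gain 0.4) than between C and D (gain 0.8) —
directional cells, and non-coding background cells, mimicking the study's
central manipulation: context relevance modulates remapping magnitude.

Datasets are written under scratch/data/<paradigm>/ (tracking, trials,
events, geometry, planted truth).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from remapflow import synth  # noqa: E402
from remapflow.geometry import default_geometry  # noqa: E402
from remapflow.io import write_dataset  # noqa: E402

SEED = 2026
POPULATION = dict(n_place=30, n_directional=6, n_background=14)
GAIN = {"discrimination": 0.4, "generalization": 0.8}

for paradigm in ("discrimination", "generalization"):
    geo = default_geometry(paradigm)
    truth = synth.make_ground_truth(
        geo, seed=SEED, remapping="rate-only", gain_b=GAIN[paradigm],
        **POPULATION,
    )
    sess = synth.simulate_session(
        truth, geo, paradigm=paradigm, duration_min=40.0, n_trials=100,
        seed=SEED + hash(paradigm) % 1000,
        policy=synth.AgentPolicy(kind="biased", p_correct=0.85, p_timeout=0.02),
    )
    out = ROOT / "scratch" / "data" / paradigm
    write_dataset(sess, out, truth=truth,
                  config={"seed": SEED, "paradigm": paradigm,
                          "gain_b": GAIN[paradigm], **POPULATION})
    n_ev = sum(len(e) for e in sess.events)
    print(f"{paradigm}: {sess.duration_min:.0f} min, {len(sess.trials)} trials, "
          f"{sess.n_neurons} neurons, {n_ev} events -> {out}")
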