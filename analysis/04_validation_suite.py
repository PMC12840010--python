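"""Run the calibration and recovery studies and tabulate the results.

These are the checks that justify trusting the pipeline on real data:
shuffle-null false-positive rates, field-segmentation recovery, remapping
and rate-gain recovery, decoder calibration, and directional
disambiguation.  Writes results/validation.json.  (The same studies back
tests/test_acceptance.py and scripts/acceptance.py.)
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from remapflow import benchmarks  # noqa: E402

SEED = 2026
out = {}
out["null_calibration"] = benchmarks.null_calibration(seed=SEED)
print("null calibration:", out["null_calibration"])
out["field_recovery"] = benchmarks.field_recovery(seed=SEED + 1)
print("field recovery:", out["field_recovery"])
out["remapping_recovery"] = benchmarks.remapping_recovery(seed=SEED + 2)
print("remapping recovery:", {k: round(v, 3) for k, v in
                              out["remapping_recovery"].items()})
out["directional"] = benchmarks.directional_disambiguation(seed=SEED + 4)
print("directional disambiguation:", out["directional"])
db = benchmarks.decoder_benchmark(seed=SEED + 3, n_shuffle_seeds=10)
out["decoder"] = db
print("decoder:", {k: (round(v, 3) if isinstance(v, float) else v)
                   for k, v in db.items() if k != "shuffled_accuracies"})

path = ROOT / "results" / "validation.json"
path.parent.mkdir(exist_ok=True)
path.write_text(json.dumps(out, indent=1))
print(f"wrote {path}")
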