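"""Compare remapping between the two paradigms.

Loads the per-neuron spatial correlations and per-field rate overlaps from
the two pipeline runs and asks the study's central question: is remapping
stronger (lower correlation / overlap) when context is behaviorally
relevant?  Wilcoxon rank-sum and Kolmogorov-Smirnov tests on the two
distributions; reward fields are compared separately.  Writes
results/paradigm_comparison.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from remapflow.pipeline import compare_groups  # noqa: E402

runs = {p: ROOT / "scratch" / "runs" / p
        for p in ("discrimination", "generalization")}
remap = {p: pd.read_csv(d / "remapping.csv", comment="#") for p, d in runs.items()}
fields = {p: pd.read_csv(d / "fields.csv", comment="#") for p, d in runs.items()}

rows = []
for measure, get in [
    ("spatial_correlation", lambda p: remap[p]["spatial_correlation"].dropna()),
    ("rate_overlap", lambda p: fields[p]["rate_overlap"].dropna()),
    ("reward_field_rate_overlap",
     lambda p: fields[p].query("distance_class == 'reward'")["rate_overlap"].dropna()),
]:
    a = get("discrimination")
    b = get("generalization")
    if len(a) < 3 or len(b) < 3:
        continue
    for test in ("ranksum", "ks"):
        res = compare_groups(a, b, test)
        rows.append({
            "measure": measure, "test": test,
            "discrimination_median": float(np.median(a)), "n_disc": len(a),
            "generalization_median": float(np.median(b)), "n_gen": len(b),
            "statistic": res["statistic"], "p": res["p"],
        })
    print(f"{measure}: discrimination median {np.median(a):.3f} (n={len(a)}) "
          f"vs generalization {np.median(b):.3f} (n={len(b)}); "
          f"rank-sum p = {rows[-2]['p']:.2g}")

out = ROOT / "results" / "paradigm_comparison.csv"
pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6g")
print(f"wrote {out}")
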