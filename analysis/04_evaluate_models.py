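"""Score every model against the single-subject judgment RDMs.

Computes Kendall tau-a between each model's fitted and unfitted
predictions and every subject's RDM, plus the noise ceiling, and writes
the evaluation table.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rsaweight import evaluate_model, noise_ceiling
from rsaweight.io import read_rdm_csv

ap = argparse.ArgumentParser()
ap.add_argument("--fits", type=Path, default=Path("results/fits"))
ap.add_argument("--subject-rdms", type=Path, default=Path("results/subject_rdms"))
ap.add_argument("--out", type=Path, default=Path("results/evaluation"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

subjects = [read_rdm_csv(p) for p in sorted(args.subject_rdms.glob("subject_*_rdm.csv"))]
rows = []
for pred_path in sorted(args.fits.glob("*_predicted.csv")) + \
        sorted(args.fits.glob("*_unfitted.csv")):
    variant = "fitted" if pred_path.stem.endswith("_predicted") else "unfitted"
    model = pred_path.stem.rsplit("_", 1)[0].replace("_plus_", "+")
    taus = evaluate_model(read_rdm_csv(pred_path, "predicted"), subjects)
    for s, t in enumerate(taus):
        rows.append({"model": model, "variant": variant, "subject": f"s{s:02d}",
                     "tau_a": float(t)})

df = pd.DataFrame(rows)
df.to_csv(args.out / "evaluation.tsv", sep="\t", index=False)
lower, upper = noise_ceiling(subjects)
with open(args.out / "ceiling.json", "w") as f:
    json.dump({"lower": lower, "upper": upper}, f, indent=2)

summary = (df.groupby(["model", "variant"])["tau_a"]
           .agg(mean_tau="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
           .reset_index().sort_values("mean_tau", ascending=False))
summary.to_csv(args.out / "summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\nnoise ceiling: [{lower:.3f}, {upper:.3f}]")
print(f"wrote evaluation tables to {args.out}")
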