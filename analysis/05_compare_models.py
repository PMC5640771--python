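"""Random-effects inference: which models differ, and from zero.

Runs one-sided Wilcoxon tests of each model against zero and two-sided
pairwise comparisons across subjects, FDR-corrected per family, plus the
model-model correlation matrix of the fitted predicted RDMs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rsaweight import compare_models_pairwise, rdm_correlation_matrix
from rsaweight.io import read_rdm_csv

ap = argparse.ArgumentParser()
ap.add_argument("--fits", type=Path, default=Path("results/fits"))
ap.add_argument("--evaluation", type=Path, default=Path("results/evaluation"))
ap.add_argument("--q", type=float, default=0.05)
ap.add_argument("--out", type=Path, default=Path("results/comparisons"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

df = pd.read_csv(args.evaluation / "evaluation.tsv", sep="\t")
df["column"] = df["model"] + " (" + df["variant"] + ")"
wide = df.pivot(index="subject", columns="column", values="tau_a")
cm = compare_models_pairwise(wide.to_numpy(), list(wide.columns), q=args.q)

pd.DataFrame(cm.p_values, index=cm.model_names, columns=cm.model_names).to_csv(
    args.out / "comparisons_p.tsv", sep="\t")
pd.DataFrame(cm.significant_at_q, index=cm.model_names,
             columns=cm.model_names).to_csv(
    args.out / "comparisons_significant.tsv", sep="\t")
with open(args.out / "model_vs_zero.json", "w") as f:
    json.dump({m: {"p": float(p), "significant": bool(s)}
               for m, p, s in zip(cm.model_names, cm.per_model_p,
                                  cm.per_model_significant)}, f, indent=2)

predicted = {p.stem.rsplit("_", 1)[0].replace("_plus_", "+"):
             read_rdm_csv(p, "predicted")
             for p in sorted(args.fits.glob("*_predicted.csv"))}
corr = rdm_correlation_matrix(list(predicted.values()))
names = list(predicted)
pd.DataFrame(corr, index=names, columns=names).to_csv(
    args.out / "model_correlations.tsv", sep="\t", float_format="%.4f")

n_sig = int(cm.significant_at_q.sum() // 2)
n_pairs = len(cm.model_names) * (len(cm.model_names) - 1) // 2
print(f"{int(cm.per_model_significant.sum())}/{len(cm.model_names)} models "
      f"significantly above zero (one-sided Wilcoxon, FDR q={args.q})")
print(f"{n_sig}/{n_pairs} pairwise differences significant "
      f"(two-sided Wilcoxon, FDR q={args.q})")
print(f"wrote comparison matrices to {args.out}")
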