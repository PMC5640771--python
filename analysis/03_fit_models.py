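"""Fit every candidate model to the participant-average RDM.

Builds single-dimension predictor sets for the conceptual models
(feature groups, category levels, combined sets), each activation layer,
and the combined category+late-layer model, then fits non-negative
ridge weights under image-level cross-validation and writes the
cross-validated predicted RDMs and the fit reports.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from rsaweight import CrossValidationSpec, crossval_predict_rdm
from rsaweight.fit import audit_fold_log
from rsaweight.io import (
    read_activations_h5,
    read_conceptual_csv,
    read_rdm_csv,
    write_rdm_csv,
)
from rsaweight.pipeline import _build_roster_sets, _default_roster
from rsaweight.predictors import merge_correlated_dimensions

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--subject-rdms", type=Path, default=Path("results/subject_rdms"))
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/fits"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

conceptual = merge_correlated_dimensions(
    read_conceptual_csv(args.study / "conceptual_model.csv"), 0.9)
layers = read_activations_h5(args.study / "activations.h5")
target = read_rdm_csv(args.subject_rdms / "average_rdm.csv")

roster = _default_roster(conceptual, layers, True, True)
sets = _build_roster_sets(roster, conceptual, layers)
reports = {}
for k, name in enumerate(roster):
    seed = int(np.random.SeedSequence([args.seed, 100 + k]).generate_state(1)[0]
               % 2**31)
    cv = CrossValidationSpec(n_heldout_images=8, seed=seed)
    fit = crossval_predict_rdm(sets[name], target, cv, model_name=name)
    audit_fold_log(fit)
    safe = name.replace("+", "_plus_")
    write_rdm_csv(fit.predicted_rdm, args.out / f"{safe}_predicted.csv")
    write_rdm_csv(sets[name].unfitted_prediction(),
                  args.out / f"{safe}_unfitted.csv")
    reports[name] = {
        "weights": dict(zip(fit.column_ids, fit.weights.tolist())),
        "lambda_median": float(np.median(fit.lambda_chosen)),
        "n_folds": len(fit.fold_log),
        "seed": seed,
    }
    print(f"{name:28s} K={len(fit.column_ids):3d} folds={len(fit.fold_log):4d} "
          f"median lambda={reports[name]['lambda_median']:.3g}")

with open(args.out / "fit_reports.json", "w") as f:
    json.dump(reports, f, indent=2)
print(f"\nwrote cross-validated predictions for {len(roster)} models to {args.out}")
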