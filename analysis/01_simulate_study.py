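"""Simulate the full synthetic study and write its raw inputs.

Generates the study-scale scenario (92 images, 16 subjects): binary
feature/category labels, layered activation sources, per-subject
judgment RDMs, and multi-arrangement sessions, writing everything under
results/study/ in the package's text formats.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from rsaweight.io import (
    write_activations_h5,
    write_conceptual_csv,
    write_rdm_csv,
    write_session_tsv,
)
from rsaweight.synthetic import (
    default_scenario,
    generate_conceptual_model,
    generate_layer_activations,
    generate_multiarrangement_session,
    generate_subject_judgments,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/study"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

sc = default_scenario(args.seed)
conceptual = generate_conceptual_model(sc)
layers = generate_layer_activations(sc, conceptual)
subjects, truth, weights = generate_subject_judgments(sc, conceptual)

write_conceptual_csv(conceptual, args.out / "conceptual_model.csv")
write_activations_h5(layers, args.out / "activations.h5")
write_rdm_csv(truth, args.out / "true_rdm.csv")
sessions = []
for s, subj in enumerate(subjects):
    seed = int(np.random.SeedSequence([sc.seed, 4, s]).generate_state(1)[0] % 2**31)
    sessions.append(generate_multiarrangement_session(
        subj, sc.trial_spec, seed, subject_id=f"s{s:02d}"))
write_session_tsv(sessions, args.out / "sessions.tsv")
with open(args.out / "generating_weights.json", "w") as f:
    json.dump(weights, f, indent=2)

n_feat = sum(d[1] in ("parts", "colors", "textures", "contours")
             for d in conceptual.dimensions)
n_cat = len(conceptual.dimensions) - n_feat
print(f"simulated study: {sc.n_images} images, {sc.n_subjects} subjects, "
      f"{n_feat} feature + {n_cat} category dimensions, "
      f"{len(layers)} activation layers, "
      f"{sum(len(s.trials) for s in sessions)} arrangement trials")
print(f"wrote raw study inputs to {args.out}")
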