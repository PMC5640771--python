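"""Synthetic study generator: images, labels, layers, judgments, trials.

Emulates the statistical structure of the similarity-judgment study the
package analyzes: 92 object images judged by 16 subjects, described by
binary visual-feature dimensions (parts, colors, textures, contours) and
a hierarchically nested set of category labels (subordinate within basic
within superordinate), plus layered activation sources whose early
"layers" mix feature information and late layers category information —
mirroring the feature-to-category progression of deep network
hierarchies.  Subject judgments are a non-negative weighted sum of
single-dimension RDMs plus subject-specific noise, delivered either as
ready RDMs or as multi-arrangement sessions with arbitrary per-trial
scale.

Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import kendall_tau_a
from .fit import WeightedModelFit
from .multiarrangement import MultiArrangementSession, Trial
from .predictors import FEATURE_GROUPS, ConceptualModel
from .rdm import RDM, FeatureActivationSet, InvalidInputError, single_dimension_rdm

__all__ = [
    "LayerSpec",
    "TrialSpec",
    "SyntheticScenario",
    "default_scenario",
    "toy_scenario",
    "recovery_scenario",
    "generate_conceptual_model",
    "generate_layer_activations",
    "generate_subject_judgments",
    "true_rdm",
    "generate_multiarrangement_session",
    "recovery_report",
    "predicted_vs_true_tau",
]


@dataclass
class LayerSpec:
    """One synthetic activation source (a network-layer stand-in)."""

    name: str
    n_dimensions: int
    units_per_dimension: int           # >= 2: feature-map-like; 1: unit-like
    mixing: dict                        # group_tag -> probability mass
    noise_sd: float = 0.5

    def __post_init__(self):
        total = sum(self.mixing.values())
        if total <= 0:
            raise InvalidInputError(f"layer {self.name}: empty mixing profile")
        self.mixing = {k: v / total for k, v in self.mixing.items() if v > 0}


@dataclass
class TrialSpec:
    """Multi-arrangement session shape: trial count, subset sizes, scales."""

    n_trials: int = 22                 # observed average session length
    subset_size_mean: float = 16.0     # average objects per later trial
    subset_size_sd: float = 3.4
    scale_range: tuple[float, float] = (0.5, 2.0)
    arrangement_noise_sd: float = 0.1  # fraction of true-distance RMS


@dataclass
class SyntheticScenario:
    """Full description of a simulated similarity-judgment study."""

    n_images: int = 92
    n_subjects: int = 16
    # conceptual spec: dimensions per feature group
    features_per_group: dict = field(default_factory=lambda: {
        "parts": 8, "colors": 4, "textures": 4, "contours": 4})
    feature_prevalence: float = 0.3
    # category nesting: superordinate -> basic -> subordinate counts
    n_superordinate: int = 2
    n_basic: int = 4
    n_subordinate: int = 8
    # ground-truth generating weights by group tag (categories dominate,
    # as subjects overwhelmingly report arranging by category)
    group_weights: dict = field(default_factory=lambda: {
        "parts": 0.25, "colors": 0.25, "textures": 0.25, "contours": 0.25,
        "subordinate": 0.6, "basic": 1.0, "superordinate": 1.0})
    # optional per-dimension multiplier range: each generating dimension's
    # weight = group weight x Uniform(lo, hi), drawn once under the seed.
    # None keeps weights identical within a group.
    weight_spread: tuple[float, float] | None = None
    subject_noise_sd: float = 0.3      # fraction of true-RDM RMS
    layers: list = field(default_factory=lambda: [
        LayerSpec("conv_early", 12, 6,
                  {"parts": 1, "colors": 1, "textures": 1, "contours": 1}, 0.5),
        LayerSpec("conv_late", 12, 6,
                  {"parts": 2, "colors": 1, "textures": 1, "contours": 1,
                   "basic": 2, "superordinate": 1}, 0.5),
        LayerSpec("fc_late", 14, 1,
                  {"subordinate": 1, "basic": 3, "superordinate": 3,
                   "parts": 1}, 0.5),
    ])
    trial_spec: TrialSpec = field(default_factory=TrialSpec)
    seed: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.group_weights.values()):
            raise InvalidInputError("ground-truth weights must be non-negative")
        if not (0 < self.feature_prevalence < 1):
            raise InvalidInputError("feature prevalence must be in (0, 1)")
        if self.n_subordinate > self.n_images:
            raise InvalidInputError("more subordinate categories than images")
        if not (self.n_superordinate <= self.n_basic <= self.n_subordinate):
            raise InvalidInputError("category counts must nest: super <= basic <= sub")

    @property
    def image_ids(self) -> tuple[str, ...]:
        return tuple(f"img{i:03d}" for i in range(self.n_images))


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """Study-scale conditions: 92 images, 16 subjects, 20 + 14 dimensions."""
    return SyntheticScenario(seed=seed)


def toy_scenario(seed: int = 0) -> SyntheticScenario:
    """Small scenario for fast end-to-end runs."""
    return SyntheticScenario(
        n_images=24, n_subjects=8,
        features_per_group={"parts": 3, "colors": 2, "textures": 2, "contours": 2},
        n_superordinate=2, n_basic=3, n_subordinate=6,
        layers=[
            LayerSpec("conv_early", 6, 4,
                      {"parts": 1, "colors": 1, "textures": 1, "contours": 1}, 0.5),
            LayerSpec("fc_late", 6, 1,
                      {"subordinate": 1, "basic": 3, "superordinate": 3}, 0.5),
        ],
        trial_spec=TrialSpec(n_trials=10, subset_size_mean=10, subset_size_sd=2),
        seed=seed,
    )


def recovery_scenario(seed: int = 0) -> SyntheticScenario:
    """Parameter-recovery conditions: 20 generating feature dimensions with
    heterogeneous non-negative weights, moderate subject noise."""
    return SyntheticScenario(
        features_per_group={"parts": 8, "colors": 4, "textures": 4, "contours": 4},
        group_weights={"parts": 1.0, "colors": 1.0, "textures": 1.0, "contours": 1.0,
                       "subordinate": 0.0, "basic": 0.0, "superordinate": 0.0},
        weight_spread=(0.1, 1.0),
        seed=seed,
    )


def generate_conceptual_model(scenario: SyntheticScenario) -> ConceptualModel:
    """Binary feature dimensions plus hierarchically nested category labels.

    Feature dimensions are independent Bernoulli(prevalence) indicators.
    Categories nest: every image belongs to exactly one subordinate
    category, each subordinate to one basic, each basic to one
    superordinate; each label contributes one binary indicator dimension.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    n = scenario.n_images
    dims = []
    for tag in FEATURE_GROUPS:
        for k in range(scenario.features_per_group.get(tag, 0)):
            vals = (rng.random(n) < scenario.feature_prevalence).astype(float)
            dims.append((f"{tag}_{k:02d}", tag, vals))
    # nested assignment: subordinate -> basic -> superordinate
    sub_of_image = rng.integers(0, scenario.n_subordinate, size=n)
    # guarantee every subordinate category non-empty
    sub_of_image[: scenario.n_subordinate] = np.arange(scenario.n_subordinate)
    rng.shuffle(sub_of_image)
    basic_of_sub = np.r_[np.arange(scenario.n_basic),
                         rng.integers(0, scenario.n_basic,
                                      size=scenario.n_subordinate - scenario.n_basic)]
    super_of_basic = np.r_[np.arange(scenario.n_superordinate),
                           rng.integers(0, scenario.n_superordinate,
                                        size=scenario.n_basic - scenario.n_superordinate)]
    basic_of_image = basic_of_sub[sub_of_image]
    super_of_image = super_of_basic[basic_of_image]
    for tag, labels, count in (
        ("subordinate", sub_of_image, scenario.n_subordinate),
        ("basic", basic_of_image, scenario.n_basic),
        ("superordinate", super_of_image, scenario.n_superordinate),
    ):
        for k in range(count):
            dims.append((f"{tag}_{k:02d}", tag, (labels == k).astype(float)))
    return ConceptualModel(scenario.image_ids, dims)


def generate_layer_activations(scenario: SyntheticScenario,
                               conceptual: ConceptualModel) -> list[FeatureActivationSet]:
    """Layered activation sources mixing conceptual structure with noise.

    Each layer dimension copies one conceptual dimension (drawn from a
    group according to the layer's mixing profile), broadcasts it over
    the dimension's units with random positive loadings, and adds
    Gaussian noise — so early layers carry feature information and late
    layers category information.
    """
    if not scenario.layers:
        raise InvalidInputError("scenario has no layers")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    by_group: dict[str, list] = {}
    for dim_id, tag, vals in conceptual.dimensions:
        by_group.setdefault(tag, []).append((dim_id, vals))
    out = []
    for layer in scenario.layers:
        groups = [g for g in layer.mixing if g in by_group]
        if not groups:
            raise InvalidInputError(
                f"layer {layer.name}: mixing groups absent from conceptual model"
            )
        probs = np.array([layer.mixing[g] for g in groups])
        probs = probs / probs.sum()
        dims = []
        for d in range(layer.n_dimensions):
            g = groups[int(rng.choice(len(groups), p=probs))]
            src_id, src_vals = by_group[g][int(rng.integers(len(by_group[g])))]
            loadings = rng.uniform(0.5, 1.5, size=layer.units_per_dimension)
            mat = np.outer(src_vals, loadings)
            if layer.noise_sd > 0:
                mat = mat + rng.normal(0, layer.noise_sd, size=mat.shape)
            dims.append((f"{layer.name}_d{d:02d}", g, mat))
        out.append(FeatureActivationSet(scenario.image_ids, dims, name=layer.name))
    return out


def _generating_weights(scenario: SyntheticScenario,
                        conceptual: ConceptualModel) -> dict[str, float]:
    base = {dim_id: float(scenario.group_weights.get(tag, 0.0))
            for dim_id, tag, _ in conceptual.dimensions}
    if scenario.weight_spread is not None:
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 5]))
        lo, hi = scenario.weight_spread
        for dim_id in base:
            base[dim_id] *= float(rng.uniform(lo, hi))
    return base


def true_rdm(scenario: SyntheticScenario, conceptual: ConceptualModel,
             weights: dict[str, float] | None = None) -> tuple[RDM, dict[str, float]]:
    """Ground-truth RDM: weighted sum of single-dimension RDMs."""
    weights = weights or _generating_weights(scenario, conceptual)
    vals = np.zeros(len(scenario.image_ids) * (len(scenario.image_ids) - 1) // 2)
    for dim_id, _, v in conceptual.dimensions:
        w = weights.get(dim_id, 0.0)
        if w < 0:
            raise InvalidInputError("generating weights must be non-negative")
        if w > 0:
            vals += w * single_dimension_rdm(v, scenario.image_ids).values
    return RDM(scenario.image_ids, vals, "judged_distance"), weights


def generate_subject_judgments(scenario: SyntheticScenario,
                               conceptual: ConceptualModel,
                               weights: dict[str, float] | None = None
                               ) -> tuple[list[RDM], RDM, dict[str, float]]:
    """Per-subject judgment RDMs: truth plus truncated Gaussian noise.

    Noise sd is ``subject_noise_sd`` times the RMS of the true RDM;
    negative dissimilarities are truncated at zero.
    Returns ``(subject_rdms, true_rdm, generating_weights)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    truth, weights = true_rdm(scenario, conceptual, weights)
    rms = float(np.sqrt(np.mean(truth.values ** 2)))
    sd = scenario.subject_noise_sd * rms
    subjects = []
    for _ in range(scenario.n_subjects):
        noisy = truth.values + rng.normal(0, sd, size=truth.values.size) if sd > 0 \
            else truth.values.copy()
        subjects.append(RDM(truth.condition_ids, np.maximum(noisy, 0.0),
                            "judged_distance"))
    return subjects, truth, weights


def generate_multiarrangement_session(true: RDM, trial_spec: TrialSpec, seed: int,
                                      subject_id: str = "s00") -> MultiArrangementSession:
    """Simulated arrangement session for one subject.

    The first trial shows all images; later trials show random subsets.
    Each trial's distances are the true distances restricted to the
    subset, multiplied by a random positive per-trial scale, plus
    truncated Gaussian noise.  (The adaptive weak-evidence subset
    selection of the real task is replaced by uniform random subsets.)
    """
    rng = np.random.default_rng(seed)
    n = true.n_conditions
    sq = true.to_square()
    rms = float(np.sqrt(np.mean(true.values ** 2)))
    trials = []
    for t in range(trial_spec.n_trials):
        if t == 0:
            members = np.arange(n)
        else:
            size = int(np.clip(round(rng.normal(trial_spec.subset_size_mean,
                                                trial_spec.subset_size_sd)), 3, n))
            members = np.sort(rng.choice(n, size=size, replace=False))
        sub = sq[np.ix_(members, members)]
        iu = np.triu_indices(members.size, k=1)
        d = sub[iu]
        scale = rng.uniform(*trial_spec.scale_range)
        noise_sd = trial_spec.arrangement_noise_sd * rms * scale
        if noise_sd > 0:
            d = d * scale + rng.normal(0, noise_sd, size=d.size)
        else:
            d = d * scale
        trials.append(Trial(t, tuple(true.condition_ids[m] for m in members),
                            np.maximum(d, 0.0)))
    return MultiArrangementSession(subject_id, true.condition_ids, trials)


def recovery_report(fit: WeightedModelFit, generating_weights: dict[str, float]) -> dict:
    """Compare fitted weights and predictions with the generating truth.

    Reports Pearson and Spearman rank correlation between the fitted
    weights and the ground-truth weights over the generating dimensions
    present in the predictor set, the unmatched dimensions, and — via
    the caller supplying a true RDM — leaves prediction comparison to
    :func:`rsaweight.evaluation.kendall_tau_a`.
    """
    from scipy.stats import pearsonr, spearmanr

    matched = [cid for cid in fit.column_ids if cid in generating_weights]
    unmatched_fit = [cid for cid in fit.column_ids if cid not in generating_weights]
    unmatched_truth = [d for d in generating_weights if d not in fit.column_ids]
    if not matched:
        raise InvalidInputError("no fitted column matches a generating dimension")
    w_fit = np.array([fit.weights[fit.column_ids.index(c)] for c in matched])
    w_true = np.array([generating_weights[c] for c in matched])
    if np.std(w_fit) == 0 or np.std(w_true) == 0:
        pear = spear = float("nan")
    else:
        pear = float(pearsonr(w_fit, w_true)[0])
        spear = float(spearmanr(w_fit, w_true)[0])
    return {
        "n_matched": len(matched),
        "unmatched_fit_columns": unmatched_fit,
        "unmatched_generating_dimensions": unmatched_truth,
        "weight_pearson": pear,
        "weight_spearman": spear,
        "weights_fitted": dict(zip(matched, w_fit.tolist())),
        "weights_true": dict(zip(matched, w_true.tolist())),
    }


def predicted_vs_true_tau(fit: WeightedModelFit, truth: RDM) -> float:
    """Tau-a between the cross-validated prediction and the true RDM."""
    t = truth if truth.condition_ids == fit.predicted_rdm.condition_ids \
        else truth.reorder(fit.predicted_rdm.condition_ids)
    return kendall_tau_a(fit.predicted_rdm.values, t.values)
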