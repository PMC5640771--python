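"""The synthetic study generator and its recovery harness."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

from rsaweight import (
    average_rdms,
    build_predictor_set,
    kendall_tau_a,
    noise_ceiling,
    squared_euclidean_rdm,
)
from rsaweight.predictors import CATEGORY_GROUPS, FEATURE_GROUPS
from rsaweight.rdm import InvalidInputError
from rsaweight.synthetic import (
    LayerSpec,
    SyntheticScenario,
    default_scenario,
    generate_conceptual_model,
    generate_layer_activations,
    generate_subject_judgments,
    recovery_report,
    recovery_scenario,
    toy_scenario,
    true_rdm,
)


class TestConceptualGeneration:
    def test_category_nesting_holds(self):
        sc = default_scenario(3)
        cm = generate_conceptual_model(sc)
        subs = {d[0]: d[2] for d in cm.dimensions if d[1] == "subordinate"}
        basics = {d[0]: d[2] for d in cm.dimensions if d[1] == "basic"}
        supers = {d[0]: d[2] for d in cm.dimensions if d[1] == "superordinate"}
        # each image carries exactly one label per category level
        for level in (subs, basics, supers):
            np.testing.assert_array_equal(
                np.sum(list(level.values()), axis=0), 1.0)
        # each subordinate set is contained in exactly one basic set, etc.
        for s in subs.values():
            assert any(np.all(s <= b) for b in basics.values())
        for b in basics.values():
            assert any(np.all(b <= u) for u in supers.values())
        # no subordinate category is empty
        assert all(s.sum() >= 1 for s in subs.values())

    def test_prevalence_matches_binomial(self):
        sc = SyntheticScenario(
            n_images=1000, n_subjects=2,
            features_per_group={"parts": 1, "colors": 0, "textures": 0, "contours": 0},
            n_superordinate=2, n_basic=2, n_subordinate=2,
            feature_prevalence=0.5, seed=9)
        cm = generate_conceptual_model(sc)
        count = cm.dimensions[0][2].sum()
        lo, hi = binom.ppf([0.0005, 0.9995], 1000, 0.5)
        assert lo <= count <= hi

    def test_deterministic_under_seed(self):
        sc = toy_scenario(5)
        a = generate_conceptual_model(sc)
        b = generate_conceptual_model(sc)
        np.testing.assert_array_equal(a.value_matrix(), b.value_matrix())
        c = generate_conceptual_model(toy_scenario(6))
        assert not np.array_equal(a.value_matrix(), c.value_matrix())

    def test_infeasible_nesting_rejected(self):
        with pytest.raises(InvalidInputError):
            SyntheticScenario(n_images=5, n_subordinate=8, n_basic=4,
                              n_superordinate=2)


class TestLayerGeneration:
    def test_pure_superordinate_layer_matches_superordinate_rdm(self):
        sc = dataclasses.replace(
            toy_scenario(2),
            layers=[LayerSpec("pure", 4, 1, {"superordinate": 1.0}, noise_sd=0.0)])
        cm = generate_conceptual_model(sc)
        layer = generate_layer_activations(sc, cm)[0]
        layer_rdm = squared_euclidean_rdm(
            np.hstack([d[2] for d in layer.dimensions]), sc.image_ids)
        model_rdm = build_predictor_set(
            cm.subset("superordinate")).unfitted_prediction()
        assert spearmanr(layer_rdm.values, model_rdm.values)[0] == pytest.approx(1.0)

    def test_pure_noise_layer_uncorrelated_with_models(self):
        taus = []
        for seed in range(20):
            sc = dataclasses.replace(
                toy_scenario(seed),
                layers=[LayerSpec("noise", 4, 2, {"parts": 1.0}, noise_sd=1.0)])
            cm = generate_conceptual_model(sc)
            # overwrite activations with pure noise
            rng = np.random.default_rng(seed)
            layer = generate_layer_activations(sc, cm)[0]
            noise_dims = [(d[0], d[1], rng.normal(size=d[2].shape))
                          for d in layer.dimensions]
            from rsaweight.rdm import FeatureActivationSet
            noise_layer = FeatureActivationSet(sc.image_ids, noise_dims)
            layer_rdm = build_predictor_set(noise_layer).unfitted_prediction()
            model_rdm = build_predictor_set(
                cm.subset(FEATURE_GROUPS)).unfitted_prediction()
            taus.append(kendall_tau_a(layer_rdm.values, model_rdm.values))
        assert np.mean(np.abs(taus)) < 0.1

    def test_early_layers_track_features_late_layers_categories(self):
        wins_early = wins_late = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sc = default_scenario(seed)
            cm = generate_conceptual_model(sc)
            layers = generate_layer_activations(sc, cm)
            feat = build_predictor_set(cm.subset(FEATURE_GROUPS)).unfitted_prediction()
            cat = build_predictor_set(cm.subset(CATEGORY_GROUPS)).unfitted_prediction()
            early = build_predictor_set(layers[0]).unfitted_prediction()
            late = build_predictor_set(layers[-1]).unfitted_prediction()
            wins_early += (kendall_tau_a(early.values, feat.values)
                           > kendall_tau_a(early.values, cat.values))
            wins_late += (kendall_tau_a(late.values, cat.values)
                          > kendall_tau_a(late.values, feat.values))
        assert wins_early > n_seeds / 2
        assert wins_late > n_seeds / 2


class TestSubjectJudgments:
    def test_zero_noise_gives_identical_subjects_and_tight_ceiling(self):
        sc = dataclasses.replace(toy_scenario(1), subject_noise_sd=0.0)
        cm = generate_conceptual_model(sc)
        subs, truth, _ = generate_subject_judgments(sc, cm)
        for s in subs:
            np.testing.assert_array_equal(s.values, truth.values)
        # identical subjects: both bounds collapse to the self-tau-a, which
        # for a tied RDM falls below 1 by exactly the tie fraction
        lower, upper = noise_ceiling(subs)
        self_tau = kendall_tau_a(truth.values, truth.values)
        assert lower == upper == pytest.approx(self_tau)
        assert self_tau < 1.0  # binary dimensions induce ties

    def test_zero_weights_give_flat_rdm(self):
        sc = dataclasses.replace(
            toy_scenario(1),
            group_weights={g: 0.0 for g in FEATURE_GROUPS + CATEGORY_GROUPS})
        cm = generate_conceptual_model(sc)
        truth, _ = true_rdm(sc, cm)
        np.testing.assert_array_equal(truth.values, 0.0)

    def test_noise_magnitude_matches_nominal(self):
        sc = dataclasses.replace(default_scenario(7), subject_noise_sd=0.5,
                                 n_subjects=200)
        cm = generate_conceptual_model(sc)
        subs, truth, _ = generate_subject_judgments(sc, cm)
        rms = np.sqrt(np.mean(truth.values ** 2))
        stack = np.array([s.values for s in subs])
        # use pairs where truncation at zero rarely binds
        big = truth.values > 1.0 * rms
        emp_sd = stack[:, big].std(axis=0).mean()
        assert emp_sd == pytest.approx(0.5 * rms, rel=0.1)

    def test_subject_average_converges_to_truth(self):
        sc8 = dataclasses.replace(toy_scenario(3), n_subjects=8)
        sc64 = dataclasses.replace(toy_scenario(3), n_subjects=64)
        cm = generate_conceptual_model(sc8)
        err = []
        for sc in (sc8, sc64):
            subs, truth, _ = generate_subject_judgments(sc, cm)
            avg = average_rdms(subs)
            err.append(np.sqrt(np.mean((avg.values - truth.values) ** 2)))
        assert err[1] < err[0]

    def test_negative_weights_rejected(self):
        sc = toy_scenario(1)
        cm = generate_conceptual_model(sc)
        with pytest.raises(InvalidInputError):
            true_rdm(sc, cm, {d[0]: -1.0 for d in cm.dimensions})

    def test_recovery_scenario_weights_heterogeneous(self):
        sc = recovery_scenario(0)
        cm = generate_conceptual_model(sc)
        _, w = true_rdm(sc, cm)
        active = [v for v in w.values() if v > 0]
        assert len(active) == 20
        assert np.std(active) > 0


class TestRecoveryReport:
    def test_flags_unmatched_dimensions(self, rng):
        from rsaweight import CrossValidationSpec, crossval_predict_rdm

        sc = toy_scenario(4)
        cm = generate_conceptual_model(sc)
        subs, truth, w = generate_subject_judgments(sc, cm)
        # drop one generating dimension from the predictors
        partial = dataclasses.replace(sc)
        ps = build_predictor_set(cm.subset(CATEGORY_GROUPS))
        fit = crossval_predict_rdm(
            ps, average_rdms(subs),
            CrossValidationSpec(n_heldout_images=3, n_inner_folds=3, seed=1))
        rep = recovery_report(fit, w)
        missing = [d[0] for d in cm.dimensions if d[1] in FEATURE_GROUPS]
        assert set(missing) <= set(rep["unmatched_generating_dimensions"])
        assert rep["n_matched"] == len(fit.column_ids)

    def test_no_overlap_rejected(self, rng):
        from rsaweight import CrossValidationSpec, crossval_predict_rdm

        sc = toy_scenario(4)
        cm = generate_conceptual_model(sc)
        subs, _, _ = generate_subject_judgments(sc, cm)
        ps = build_predictor_set(cm.subset("basic"))
        fit = crossval_predict_rdm(
            ps, average_rdms(subs),
            CrossValidationSpec(n_heldout_images=3, n_inner_folds=3, seed=1))
        with pytest.raises(InvalidInputError):
            recovery_report(fit, {"unrelated": 1.0})
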