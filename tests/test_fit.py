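"""Non-negative ridge solver and image-level cross-validation."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import nnls

from rsaweight import (
    ConceptualModel,
    CrossValidationSpec,
    build_predictor_set,
    crossval_predict_rdm,
    kendall_tau_a,
    nonneg_ridge_fit,
    standardize_predictors,
)
from rsaweight.fit import (
    audit_fold_log,
    default_lambda_grid,
    ridge_objective,
    select_lambda_nested,
)
from rsaweight.rdm import RDM, InvalidInputError, pair_indices


def qp_oracle(Z, y, lam):
    """Solve the same objective via augmented NNLS (independent of the CD path)."""
    n, k = Z.shape
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    A = np.vstack([Zc / np.sqrt(n), np.sqrt(lam) * np.eye(k)])
    rhs = np.concatenate([yc / np.sqrt(n), np.zeros(k)])
    w, _ = nnls(A, rhs)
    return w, float(y.mean() - Z.mean(axis=0) @ w)


class TestStandardize:
    def test_centering_and_unit_population_sd(self):
        Z, _, means, sds, flags = standardize_predictors(
            np.array([[1.0], [2.0], [3.0]]))
        assert means[0] == 2.0
        assert sds[0] == pytest.approx(np.sqrt(2 / 3))  # population sd
        assert Z.sum() == pytest.approx(0.0)
        assert Z.std() == pytest.approx(1.0)
        assert not flags[0]

    def test_constant_column_zeroed_and_flagged(self):
        Z, Zt, _, _, flags = standardize_predictors(
            np.full((4, 1), 3.0), np.full((2, 1), 9.0))
        assert flags[0]
        assert np.all(Z == 0) and np.all(Zt == 0)

    def test_test_rows_use_training_statistics(self, rng):
        X, Xt = rng.normal(size=(30, 4)), rng.normal(size=(10, 4))
        _, Zt, means, sds, _ = standardize_predictors(X, Xt)
        np.testing.assert_allclose(Zt, (Xt - X.mean(0)) / X.std(0))
        np.testing.assert_allclose(means, X.mean(0))
        np.testing.assert_allclose(sds, X.std(0))


class TestNonnegRidge:
    def test_exact_linear_target_recovered(self, rng):
        Z = rng.normal(size=(50, 4))
        y = 2.0 * Z[:, 0]
        w, b = nonneg_ridge_fit(Z, y, 1e-8)
        assert w[0] == pytest.approx(2.0, abs=1e-4)
        np.testing.assert_allclose(w[1:], 0.0, atol=1e-4)

    def test_huge_penalty_shrinks_to_intercept_only(self, rng):
        Z = rng.normal(size=(40, 3))
        y = rng.normal(size=40) + 5
        w, b = nonneg_ridge_fit(Z, y, 1e12)
        np.testing.assert_allclose(w, 0.0, atol=1e-9)
        assert b == pytest.approx(y.mean(), abs=1e-6)

    def test_anticorrelated_predictor_pinned_at_zero_with_kkt(self, rng):
        z = rng.normal(size=60)
        Z = z[:, None]
        y = -z  # negatively correlated
        lam = 0.1
        w, b = nonneg_ridge_fit(Z, y, lam)
        assert w[0] == 0.0
        # KKT at an active bound: objective gradient at w=0 must be >= 0
        n = y.size
        Zc = Z - Z.mean(0)
        yc = y - y.mean()
        grad = (-(Zc.T @ yc) / n + lam * w)[0]
        assert grad >= 0

    def test_matches_qp_oracle_in_objective(self, rng):
        for _ in range(15):
            n = int(rng.integers(10, 61))
            k = int(rng.integers(1, 11))
            Z = rng.normal(size=(n, k))
            y = Z @ np.abs(rng.normal(size=k)) + rng.normal(size=n) * 0.3
            lam = 10.0 ** rng.uniform(-6, 2)
            w, b = nonneg_ridge_fit(Z, y, lam)
            w_o, b_o = qp_oracle(Z, y, lam)
            assert w.min() >= 0
            assert ridge_objective(Z, y, w, b, lam) == pytest.approx(
                ridge_objective(Z, y, w_o, b_o, lam), abs=1e-6)

    def test_monotone_shrinkage(self, rng):
        Z = rng.normal(size=(60, 5))
        y = Z @ np.abs(rng.normal(size=5)) + rng.normal(size=60) * 0.2
        norms = [np.linalg.norm(nonneg_ridge_fit(Z, y, lam)[0])
                 for lam in (1e-4, 1e-2, 1.0, 100.0)]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            nonneg_ridge_fit(np.array([[np.inf]]), np.array([1.0]), 0.1)


def _toy_problem(rng, n_images=12, k=5, noise=0.05, seed_weights=None):
    ids = tuple(f"i{q:02d}" for q in range(n_images))
    dims = [(f"d{j}", "parts", (rng.random(n_images) < 0.5).astype(float))
            for j in range(k)]
    model = ConceptualModel(ids, dims)
    ps = build_predictor_set(model)
    w_true = seed_weights if seed_weights is not None else rng.uniform(0.2, 1, k)
    y = ps.matrix[:, ps.predictor_indices] @ w_true
    y = np.maximum(y + rng.normal(0, noise * y.std(), y.size), 0)
    return ps, RDM(ids, y, "judged_distance"), w_true


class TestLambdaSelection:
    def test_single_value_grid_forced_choice(self, rng):
        ps, target, _ = _toy_problem(rng)
        n = len(ps.condition_ids)
        I, J = pair_indices(n)
        spec = CrossValidationSpec(n_heldout_images=2, lambda_grid=[0.37],
                                   n_inner_folds=3)
        lam = select_lambda_nested(ps.matrix[:, ps.predictor_indices], target.values,
                                   I, J, np.arange(n - 2), n, spec,
                                   np.random.default_rng(0))
        assert lam == 0.37

    def test_noiseless_target_selects_weak_penalty(self, rng):
        ps, target, _ = _toy_problem(rng, n_images=14, noise=0.0)
        n = len(ps.condition_ids)
        I, J = pair_indices(n)
        X = ps.matrix[:, ps.predictor_indices]
        grid = default_lambda_grid(X, target.values)
        spec = CrossValidationSpec(n_heldout_images=2, lambda_grid=grid,
                                   n_inner_folds=4)
        lam = select_lambda_nested(X, target.values, I, J, np.arange(n), n, spec,
                                   np.random.default_rng(1))
        assert lam <= np.sort(grid)[2]  # among the smallest grid values

    def test_pure_noise_target_selects_strong_penalty(self, rng):
        # on pure noise the validation-MSE curve favors heavy shrinkage, but
        # its minimum fluctuates with the small validation sets; simulation
        # shows the selected penalty sits above the grid median on the large
        # majority of seeds with its median in the top decile of the grid
        above_median = 0
        ranks = []
        n_seeds = 25
        for s in range(n_seeds):
            local = np.random.default_rng(s)
            ps, _, _ = _toy_problem(local, n_images=24, k=20)
            n = len(ps.condition_ids)
            I, J = pair_indices(n)
            X = ps.matrix[:, ps.predictor_indices]
            y = local.normal(size=X.shape[0])
            grid = default_lambda_grid(X, y)
            spec = CrossValidationSpec(n_heldout_images=2, lambda_grid=grid,
                                       n_inner_folds=3)
            lam = select_lambda_nested(X, y, I, J, np.arange(n), n, spec,
                                       np.random.default_rng(100 + s))
            above_median += lam >= np.median(grid)
            ranks.append(int(np.searchsorted(np.sort(grid), lam)))
        assert above_median >= 0.8 * n_seeds
        assert np.median(ranks) >= 27  # top decile of the 30-value grid

    def test_grid_is_positive_descending(self, rng):
        ps, target, _ = _toy_problem(rng)
        grid = default_lambda_grid(ps.matrix[:, ps.predictor_indices], target.values)
        assert np.all(grid > 0)
        assert np.all(np.diff(grid) < 0)


class TestCrossValidation:
    def test_six_images_heldout_two_structure(self, rng):
        ps, target, _ = _toy_problem(rng, n_images=6, k=3)
        spec = CrossValidationSpec(n_heldout_images=2, n_inner_folds=2, seed=3)
        fit = crossval_predict_rdm(ps, target, spec)
        # each fold predicts exactly one pair; coverage needs >= 15 folds
        assert all(len(rec.predicted_pair_indices) == 1 for rec in fit.fold_log)
        assert len(fit.fold_log) >= 15
        assert fit.coverage_counts.min() >= 1

    def test_no_leakage_in_fold_log(self, rng):
        ps, target, _ = _toy_problem(rng, n_images=10)
        spec = CrossValidationSpec(n_heldout_images=3, n_inner_folds=3, seed=7)
        fit = crossval_predict_rdm(ps, target, spec)
        assert audit_fold_log(fit)
        # explicit structural re-check
        I, J = pair_indices(10)
        for rec in fit.fold_log:
            held = set(rec.heldout_image_ids)
            for p in rec.predicted_pair_indices:
                assert ps.condition_ids[I[p]] in held
                assert ps.condition_ids[J[p]] in held

    def test_reproducible_under_fixed_seed(self, rng):
        ps, target, _ = _toy_problem(rng, n_images=9)
        spec = CrossValidationSpec(n_heldout_images=2, n_inner_folds=3, seed=11)
        a = crossval_predict_rdm(ps, target, spec)
        b = crossval_predict_rdm(ps, target, spec)
        np.testing.assert_array_equal(a.predicted_rdm.values, b.predicted_rdm.values)
        assert a.lambda_chosen == b.lambda_chosen
        for ra, rb in zip(a.fold_log, b.fold_log):
            assert ra.heldout_image_ids == rb.heldout_image_ids
            np.testing.assert_array_equal(ra.predicted_pair_indices,
                                          rb.predicted_pair_indices)

    def test_weights_nonnegative_and_fit_beats_unfitted(self, rng):
        # target built from unequal weights: reweighting must outrank equal weights
        ps, target, w_true = _toy_problem(
            rng, n_images=14, k=5, noise=0.05,
            seed_weights=np.array([2.0, 1.0, 0.1, 0.1, 0.1]))
        spec = CrossValidationSpec(n_heldout_images=3, n_inner_folds=3, seed=5)
        fit = crossval_predict_rdm(ps, target, spec)
        assert fit.weights.min() >= 0
        tau_fit = kendall_tau_a(fit.predicted_rdm.values, target.values)
        tau_unfit = kendall_tau_a(ps.unfitted_prediction().values, target.values)
        assert tau_fit > tau_unfit

    def test_any_heldout_mode_covers_faster(self, rng):
        ps, target, _ = _toy_problem(rng, n_images=10)
        both = crossval_predict_rdm(
            ps, target, CrossValidationSpec(n_heldout_images=3, n_inner_folds=3, seed=2))
        any_ = crossval_predict_rdm(
            ps, target, dataclasses.replace(
                CrossValidationSpec(n_heldout_images=3, n_inner_folds=3, seed=2),
                cv_pairs="any-heldout"))
        assert len(any_.fold_log) < len(both.fold_log)
        assert any_.coverage_counts.min() >= 1

    def test_condition_set_mismatch_rejected(self, rng):
        ps, target, _ = _toy_problem(rng, n_images=6, k=3)
        other = RDM(tuple("uvwxyz"), target.values, "judged_distance")
        with pytest.raises(InvalidInputError):
            crossval_predict_rdm(ps, other, CrossValidationSpec(n_heldout_images=2))
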