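"""Non-negative L2-regularized reweighting of single-dimension RDMs.

The weighted model predicts a target RDM as a non-negative combination
of predictor RDM columns plus an unpenalized intercept (the
confound-mean predictor).  The objective is

    (1/2N) * ||y - b - Z w||^2 + (lambda/2) * ||w||^2,   w >= 0,

solved by cyclical coordinate descent with non-negative clipping.
Predictors are standardized (training statistics only) before fitting.

Generalization performance is estimated by image-level cross-validation:
each outer fold holds out a set of images, fits on the pairs whose
images are both in the training set, and predicts the dissimilarities of
held-out pairs; the regularization penalty is chosen per fold by nested
cross-validation to held-out images within the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .predictors import PredictorRDMSet
from .rdm import RDM, InvalidInputError, pair_indices

__all__ = [
    "CrossValidationSpec",
    "WeightedModelFit",
    "FoldRecord",
    "PairCoverageError",
    "standardize_predictors",
    "nonneg_ridge_fit",
    "ridge_objective",
    "default_lambda_grid",
    "select_lambda_nested",
    "crossval_predict_rdm",
    "unfitted_prediction",
    "audit_fold_log",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=False, fastmath=False)(f)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def _jit(f):
        return f

    _HAVE_NUMBA = False


@_jit
def _cd_gram(G, c, lam, w, tol, max_sweeps):  # pragma: no cover - numba kernel
    """Cyclical coordinate descent on the Gram form of the ridge objective.

    Minimizes 0.5 w'Gw - c'w + 0.5*lam*||w||^2 subject to w >= 0, where
    G = Z'Z/N and c = Z'y/N for centered Z, y.  ``w`` is updated in
    place; returns the number of sweeps used.
    """
    K = c.size
    for sweep in range(max_sweeps):
        maxd = 0.0
        for j in range(K):
            gjj = G[j, j]
            if gjj <= 0.0:
                if w[j] != 0.0:
                    w[j] = 0.0
                continue
            s = 0.0
            for k in range(K):
                s += G[j, k] * w[k]
            wj = (c[j] - s + gjj * w[j]) / (gjj + lam)
            if wj < 0.0:
                wj = 0.0
            d = wj - w[j]
            if d < 0.0:
                d = -d
            if d > maxd:
                maxd = d
            w[j] = wj
        if maxd < tol:
            return sweep + 1
    return max_sweeps


class PairCoverageError(RuntimeError):
    """Cross-validation ended with pairs never predicted."""

    def __init__(self, uncovered_pairs):
        self.uncovered_pairs = list(uncovered_pairs)
        super().__init__(
            f"{len(self.uncovered_pairs)} pair(s) never predicted, "
            f"e.g. {self.uncovered_pairs[:5]}"
        )


@dataclass
class CrossValidationSpec:
    """Configuration of the image-level cross-validation procedure."""

    n_heldout_images: int = 8          # paper-scale default: 8 of 92
    lambda_grid: np.ndarray | None = None  # descending; None -> automatic
    n_lambda: int = 30
    n_inner_folds: int = 5
    seed: int = 0
    max_outer_folds: int = 2000
    cv_pairs: str = "both-heldout"     # or "any-heldout"
    tol: float = 1e-8
    max_sweeps: int = 10000

    def __post_init__(self):
        if self.n_heldout_images < 2:
            raise InvalidInputError("n_heldout_images must be >= 2")
        if self.cv_pairs not in ("both-heldout", "any-heldout"):
            raise InvalidInputError(f"unknown cv_pairs mode {self.cv_pairs!r}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid <= 0):
                raise InvalidInputError("lambda_grid must be positive")
            self.lambda_grid = np.sort(grid)[::-1]


@dataclass
class FoldRecord:
    fold_index: int
    heldout_image_ids: tuple[str, ...]
    predicted_pair_indices: np.ndarray
    lambda_chosen: float
    weights_raw: np.ndarray  # on the original predictor scale


@dataclass
class WeightedModelFit:
    """Result of a completed cross-validated weighted model fit."""

    model_name: str
    column_ids: list[str]           # non-confound predictor columns
    weights: np.ndarray             # fold-averaged, original scale, >= 0
    intercept: float
    lambda_chosen: list[float]      # per outer fold
    fold_log: list[FoldRecord]
    predicted_rdm: RDM
    coverage_counts: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size and self.weights.min() < -1e-12:
            raise InvalidInputError("fitted weights must be non-negative")
        if self.coverage_counts.min() < 1:
            raise InvalidInputError("completed fit must cover every pair")


def standardize_predictors(train_X: np.ndarray, test_X: np.ndarray | None = None):
    """Center/scale columns to zero mean, unit sd using training rows only.

    Uses the population standard deviation (divide by N).  Zero-variance
    training columns map to all-zero and are flagged.

    Returns ``(train_Z, test_Z, means, sds, degenerate_flags)``; ``test_Z``
    is None when no test rows are given.
    """
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if X.shape[0] < 2:
        raise InvalidInputError("need >= 2 training rows to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population (ddof=0)
    flags = sds <= 0
    safe = np.where(flags, 1.0, sds)
    Z = (X - means) / safe
    Z[:, flags] = 0.0
    Zt = None
    if test_X is not None:
        Xt = np.atleast_2d(np.asarray(test_X, dtype=float))
        Zt = (Xt - means) / safe
        Zt[:, flags] = 0.0
    return Z, Zt, means, sds, flags


def ridge_objective(Z: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: float,
                    lam: float) -> float:
    """(1/2N)||y - b - Zw||^2 + (lam/2)||w||^2."""
    r = y - intercept - Z @ w
    return float(0.5 * np.mean(r ** 2) + 0.5 * lam * np.sum(w ** 2))


def nonneg_ridge_fit(Z: np.ndarray, y: np.ndarray, lam: float,
                     w0: np.ndarray | None = None, tol: float = 1e-8,
                     max_sweeps: int = 10000) -> tuple[np.ndarray, float]:
    """Fit non-negative ridge weights with an unpenalized intercept.

    The intercept is profiled out exactly (for any w the optimal
    intercept is ``mean(y - Zw)``), so the solver runs on centered data.
    Returns ``(weights, intercept)``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    if Z.shape[0] != y.size:
        raise InvalidInputError("Z rows must match y length")
    if lam < 0:
        raise InvalidInputError("lambda must be >= 0")
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite inputs")
    n = y.size
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    ybar = float(y.mean())
    yc = y - ybar
    G = (Zc.T @ Zc) / n
    c = (Zc.T @ yc) / n
    w = np.zeros(Z.shape[1]) if w0 is None else np.array(w0, dtype=float)
    _cd_gram(G, c, float(lam), w, float(tol), int(max_sweeps))
    intercept = ybar - float(zbar @ w)
    return w, intercept


def default_lambda_grid(Z: np.ndarray, y: np.ndarray, n_lambda: int = 30) -> np.ndarray:
    """Descending log-spaced penalty grid spanning [1e-4, 1] x lambda_max.

    A pure L2 penalty only reaches the all-zero solution in the
    lambda -> infinity limit, so lambda_max follows glmnet's practical
    convention: the largest gradient magnitude max_j |z_j.y|/N scaled up
    (here by 1e3) so the solution at lambda_max is numerically zero.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    gmax = float(np.max(np.abs(Zc.T @ yc)) / y.size) if Z.size else 0.0
    lam_max = 1e3 * gmax if gmax > 0 else 1.0
    return np.logspace(np.log10(lam_max), np.log10(1e-4 * lam_max), n_lambda)


def _pair_masks(in_held: np.ndarray, I: np.ndarray, J: np.ndarray, cv_pairs: str):
    """(train_mask, predict_mask) over pairs for a held-out image mask."""
    train = ~in_held[I] & ~in_held[J]
    if cv_pairs == "both-heldout":
        predict = in_held[I] & in_held[J]
    else:
        predict = in_held[I] | in_held[J]
    return train, predict


def select_lambda_nested(X: np.ndarray, y: np.ndarray, I: np.ndarray, J: np.ndarray,
                         train_images: np.ndarray, n_images: int,
                         spec: CrossValidationSpec, rng: np.random.Generator) -> float:
    """Choose the ridge penalty by image-level nested cross-validation.

    The training images are partitioned into inner folds; for each fold
    and each grid value the model is fit on inner-training pairs and its
    squared prediction error measured on inner-held-out pairs.  The
    penalty with minimum mean squared error is returned, ties broken
    toward stronger regularization.
    """
    in_train = np.zeros(n_images, dtype=bool)
    in_train[train_images] = True
    train_rows = np.flatnonzero(in_train[I] & in_train[J])
    grid = (spec.lambda_grid if spec.lambda_grid is not None
            else default_lambda_grid(X[train_rows], y[train_rows], spec.n_lambda))
    if grid.size == 1:
        return float(grid[0])
    if train_images.size < 2 * spec.n_inner_folds:
        warnings.warn("too few training images for nested folds; using largest lambda")
        return float(grid[0])
    perm = rng.permutation(train_images)
    folds = np.array_split(perm, spec.n_inner_folds)
    sse = np.zeros(grid.size)
    cnt = 0
    for fold in folds:
        in_held = np.zeros(n_images, dtype=bool)
        in_held[fold] = True
        inner_train = in_train & ~in_held
        tr = np.flatnonzero(inner_train[I] & inner_train[J])
        # validation pairs stay inside the outer training set; both images
        # (both-heldout) or at least one (any-heldout) fall in the inner fold
        if spec.cv_pairs == "both-heldout":
            va = np.flatnonzero(in_held[I] & in_held[J])
        else:
            va = np.flatnonzero(in_train[I] & in_train[J] & (in_held[I] | in_held[J]))
        if tr.size < 2 or va.size == 0:
            continue
        Ztr, Zva, _, _, _ = standardize_predictors(X[tr], X[va])
        ytr = y[tr]
        n = ytr.size
        ybar = float(ytr.mean())
        yc = ytr - ybar
        G = (Ztr.T @ Ztr) / n
        cvec = (Ztr.T @ yc) / n
        w = np.zeros(X.shape[1])
        for li, lam in enumerate(grid):
            _cd_gram(G, cvec, float(lam), w, spec.tol, spec.max_sweeps)
            yhat = ybar + Zva @ w
            sse[li] += float(np.sum((yhat - y[va]) ** 2))
        cnt += va.size
    if cnt == 0:
        warnings.warn("no usable inner validation pairs; using largest lambda")
        return float(grid[0])
    # grid is descending: first index attaining the minimum = largest lambda
    return float(grid[int(np.argmin(sse / cnt))])


def crossval_predict_rdm(predictors: PredictorRDMSet, target: RDM,
                         spec: CrossValidationSpec,
                         model_name: str | None = None) -> WeightedModelFit:
    """Cross-validated weighted model fit and predicted RDM.

    Outer folds repeatedly hold out ``spec.n_heldout_images`` images, fit
    the non-negative ridge model (penalty chosen by nested CV) on the
    pairs of the remaining images, and predict the dissimilarities of
    held-out pairs.  Folds repeat until every pair has been predicted at
    least once; each fold's held-out set is seeded with one uncovered
    pair so the coverage loop terminates.  Per-pair predictions are
    averaged over the folds that produced them.
    """
    if set(predictors.condition_ids) != set(target.condition_ids):
        raise InvalidInputError("predictors and target have different condition sets")
    if target.condition_ids != predictors.condition_ids:
        target = target.reorder(predictors.condition_ids)
    n = len(predictors.condition_ids)
    if not (2 <= spec.n_heldout_images < n):
        raise InvalidInputError("n_heldout_images must be in [2, n_images)")
    keep = predictors.predictor_indices
    X = predictors.matrix[:, keep]
    col_ids = [predictors.column_ids[k] for k in keep]
    y = target.values
    I, J = pair_indices(n)
    npair = y.size
    rng = np.random.default_rng(spec.seed)

    pred_sum = np.zeros(npair)
    pred_cnt = np.zeros(npair, dtype=np.int64)
    fold_log: list[FoldRecord] = []
    lambdas: list[float] = []
    w_sum = np.zeros(X.shape[1])
    b_sum = 0.0
    all_images = np.arange(n)

    fold_idx = 0
    while True:
        uncovered = np.flatnonzero(pred_cnt == 0)
        if uncovered.size == 0:
            break
        if fold_idx >= spec.max_outer_folds:
            ids = predictors.condition_ids
            raise PairCoverageError([(ids[I[p]], ids[J[p]]) for p in uncovered])
        # held-out set: one uncovered pair plus random further images
        p = int(rng.choice(uncovered))
        held = {int(I[p]), int(J[p])}
        pool = np.setdiff1d(all_images, list(held), assume_unique=False)
        extra = rng.choice(pool, size=spec.n_heldout_images - 2, replace=False)
        held.update(int(e) for e in extra)
        in_held = np.zeros(n, dtype=bool)
        in_held[list(held)] = True
        train_rows_mask, predict_mask = _pair_masks(in_held, I, J, spec.cv_pairs)
        tr = np.flatnonzero(train_rows_mask)
        te = np.flatnonzero(predict_mask)
        train_images = np.flatnonzero(~in_held)

        lam = select_lambda_nested(X, y, I, J, train_images, n, spec, rng)
        Ztr, Zte, means, sds, flags = standardize_predictors(X[tr], X[te])
        ytr = y[tr]
        ybar = float(ytr.mean())
        ncase = ytr.size
        G = (Ztr.T @ Ztr) / ncase
        cvec = (Ztr.T @ (ytr - ybar)) / ncase
        w = np.zeros(X.shape[1])
        _cd_gram(G, cvec, float(lam), w, spec.tol, spec.max_sweeps)

        # predictions are combined across folds without the fold-specific
        # intercept: each fold's training mean reflects which images were
        # held out, and mixing those means across folds would inject
        # training-set-composition noise into the predicted RDM (biasing
        # rank correlations downward under the null).  A single global
        # intercept (the average of fold intercepts) is restored at the end.
        pred_sum[te] += Zte @ w
        pred_cnt[te] += 1
        w_raw = np.where(flags, 0.0, w / np.where(flags, 1.0, sds))
        w_sum += w_raw
        b_sum += ybar
        lambdas.append(lam)
        fold_log.append(FoldRecord(
            fold_idx,
            tuple(predictors.condition_ids[k] for k in sorted(held)),
            te,
            lam,
            w_raw,
        ))
        fold_idx += 1

    n_folds = len(fold_log)
    predicted = RDM(predictors.condition_ids,
                    pred_sum / pred_cnt + b_sum / n_folds, "predicted")
    return WeightedModelFit(
        model_name or predictors.name,
        col_ids,
        w_sum / n_folds,
        b_sum / n_folds,
        lambdas,
        fold_log,
        predicted,
        pred_cnt,
        seed=spec.seed,
    )


def unfitted_prediction(predictors: PredictorRDMSet) -> RDM:
    """Equal-weights model: plain sum of the non-confound columns."""
    if predictors.predictor_indices.size < 1:
        raise InvalidInputError("need at least one non-confound column")
    return predictors.unfitted_prediction()


def audit_fold_log(fit: WeightedModelFit, n_images: int | None = None) -> bool:
    """Structurally verify that no fold leaked held-out images into training.

    For every fold, every predicted pair must involve only held-out
    images (both-held-out mode) or at least one held-out image; training
    images (the complement of the held-out set) must never include both
    members of a predicted pair.  Raises on violation, returns True.
    """
    cond = fit.predicted_rdm.condition_ids
    n = n_images or len(cond)
    I, J = pair_indices(n)
    for rec in fit.fold_log:
        held = set(rec.heldout_image_ids)
        for p in rec.predicted_pair_indices:
            a, b = cond[I[p]], cond[J[p]]
            if a not in held and b not in held:
                raise AssertionError(
                    f"fold {rec.fold_index}: predicted pair ({a}, {b}) fully inside "
                    "the training set"
                )
    return True
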