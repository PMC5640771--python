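"""Random-effects inference on model performance across subjects.

Each model's per-subject tau-a values are tested against zero with a
one-sided Wilcoxon signed-rank test; differences in performance between
models use the two-sided test.  For the small subject counts typical of
this design (n = 16) the exact null distribution is computed by dynamic
programming over signed mid-ranks; larger samples use the tie-corrected
normal approximation.  Multiple comparisons are controlled by the
Benjamini-Hochberg step-up procedure at an expected false discovery rate
of 0.05, with the model-vs-zero tests and the pairwise-difference tests
corrected as separate families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .rdm import InvalidInputError

__all__ = [
    "wilcoxon_signed_rank",
    "fdr_bh",
    "compare_models_pairwise",
    "ComparisonMatrix",
    "EXACT_MAX_N",
]

#: sample sizes up to this use exact enumeration of sign assignments
EXACT_MAX_N = 25


@lru_cache(maxsize=4096)
def _signed_rank_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of each achievable doubled rank-sum over all sign patterns.

    Mid-ranks are multiples of 1/2, so doubling makes them integers;
    entry ``s`` holds the number of the 2^n sign assignments whose
    positive-rank sum equals ``s/2``.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] = counts[r:] + counts[:-r or None]
    return counts


def wilcoxon_signed_rank(values: np.ndarray, null_location: float = 0.0,
                         sided: str = "two") -> float:
    """Wilcoxon signed-rank p-value against a location shift.

    Zeros (values equal to ``null_location``) are dropped; ties among
    absolute differences are mid-ranked.  The one-sided alternative is
    H1: location > ``null_location``.  Exact enumeration for n <= 25,
    tie-corrected normal approximation (with continuity correction)
    above.
    """
    if sided not in ("one", "two"):
        raise InvalidInputError(f"sided must be 'one' or 'two', got {sided!r}")
    v = np.asarray(values, dtype=float).reshape(-1) - null_location
    if v.size < 1:
        raise InvalidInputError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("values must be finite")
    v = v[v != 0]
    if v.size == 0:
        warnings.warn("all values equal the null location; p = 1")
        return 1.0
    n = v.size
    ranks = rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())
    if n <= EXACT_MAX_N:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        counts = _signed_rank_counts(doubled)
        denom = 2.0 ** n
        s = int(round(2 * w_plus))
        p_ge = counts[s:].sum() / denom
        p_le = counts[: s + 1].sum() / denom
        if sided == "one":
            return float(min(1.0, p_ge))
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(t ** 3 - t) / 48.0
    sd = np.sqrt(var)
    if sided == "one":
        z = (w_plus - mu - 0.5) / sd
        return float(norm.sf(z))
    z = (abs(w_plus - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * norm.sf(z)))


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at expected FDR q."""
    p = np.asarray(p_values, dtype=float).reshape(-1)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class ComparisonMatrix:
    """Pairwise model-comparison tests plus per-model tests against zero."""

    model_names: list[str]
    p_values: np.ndarray            # models x models, two-sided; diagonal 1
    significant_at_q: np.ndarray    # boolean, FDR-corrected over all pairs
    per_model_p: np.ndarray         # one-sided vs zero
    per_model_significant: np.ndarray
    q: float = 0.05

    def __post_init__(self):
        m = len(self.model_names)
        if self.p_values.shape != (m, m):
            raise InvalidInputError("p_values must be models x models")
        if not np.allclose(self.p_values, self.p_values.T):
            raise InvalidInputError("p-value matrix must be symmetric")


def compare_models_pairwise(per_subject_tau: np.ndarray, model_names: list[str],
                            q: float = 0.05) -> ComparisonMatrix:
    """Test all pairwise performance differences and each model vs zero.

    ``per_subject_tau`` is subjects x models.  Pairwise differences use
    the two-sided Wilcoxon signed-rank test across subjects; the
    model-vs-zero tests are one-sided.  Each family is FDR-corrected at
    ``q`` across all of its comparisons.
    """
    tau = np.atleast_2d(np.asarray(per_subject_tau, dtype=float))
    n_subj, n_mod = tau.shape
    if n_mod != len(model_names):
        raise InvalidInputError("columns must match model_names")
    if n_mod < 2:
        raise InvalidInputError("need at least 2 models")
    if n_subj < 2:
        raise InvalidInputError("degenerate test: need at least 2 subjects")

    pmat = np.ones((n_mod, n_mod))
    pairs = [(a, b) for a in range(n_mod) for b in range(a + 1, n_mod)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identical columns legitimately give p = 1
        pair_p = np.array([
            wilcoxon_signed_rank(tau[:, a] - tau[:, b], sided="two") for a, b in pairs
        ])
        model_p = np.array([
            wilcoxon_signed_rank(tau[:, m], sided="one") for m in range(n_mod)
        ])
    for (a, b), p in zip(pairs, pair_p):
        pmat[a, b] = pmat[b, a] = p
    sig = np.zeros((n_mod, n_mod), dtype=bool)
    pair_sig = fdr_bh(pair_p, q)
    for (a, b), s in zip(pairs, pair_sig):
        sig[a, b] = sig[b, a] = bool(s)
    model_sig = fdr_bh(model_p, q)
    return ComparisonMatrix(list(model_names), pmat, sig, model_p, model_sig, q)
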