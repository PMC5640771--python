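"""Scoring model-predicted RDMs against per-subject judgment RDMs.

Model performance is quantified with Kendall's tau-a, the rank
correlation whose denominator is the total number of item pairs
regardless of ties.  Tau-a is the appropriate choice when candidate
models predict tied dissimilarities (e.g. binary category models), where
tau-b or Spearman would inflate the score of the coarser model.

The noise ceiling bounds the performance any true model could achieve
given inter-subject variability: the upper bound correlates each subject
with the all-subject average, the lower bound with the leave-one-out
average (computed on rank-transformed RDMs, since the evaluation
statistic is a rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .rdm import RDM, InvalidInputError

__all__ = ["kendall_tau_a", "evaluate_model", "noise_ceiling", "EvaluationResult"]

# vectors at or below this length use exact O(n^2) pair enumeration;
# longer vectors use the O(n log n) counter.  Both paths must agree.
_BRUTE_FORCE_MAX_N = 1024


def _tau_a_enumerate(x: np.ndarray, y: np.ndarray) -> float:
    """Exact pair enumeration: S = sum_{i<j} sign(x_i-x_j)*sign(y_i-y_j)."""
    n = x.size
    sx = np.sign(x[:, None] - x[None, :]).astype(np.int8)
    sy = np.sign(y[:, None] - y[None, :]).astype(np.int8)
    s = int(np.sum(np.triu(sx.astype(np.int64) * sy, k=1)))
    return s / (n * (n - 1) // 2)


def _merge_count(a: np.ndarray) -> tuple[np.ndarray, int]:
    """Sorted copy of ``a`` and its number of strict inversions."""
    n = a.size
    if n <= 1:
        return a, 0
    left, cl = _merge_count(a[: n // 2])
    right, cr = _merge_count(a[n // 2:])
    # pairs (l, r) with l > r; both halves sorted
    cross = int(np.sum(left.size - np.searchsorted(left, right, side="right")))
    return np.sort(np.concatenate([left, right]), kind="mergesort"), cl + cr + cross


def _tie_count(sorted_vals: np.ndarray) -> int:
    """sum t(t-1)/2 over runs of equal values in a sorted array."""
    if sorted_vals.size == 0:
        return 0
    change = np.r_[True, np.diff(sorted_vals) != 0]
    runs = np.diff(np.r_[np.flatnonzero(change), sorted_vals.size])
    return int(np.sum(runs * (runs - 1) // 2))


def _tau_a_fast(x: np.ndarray, y: np.ndarray) -> float:
    """Knight-style concordance count: lexsort + mergesort inversions.

    With ties: S = n0 - n1 - n2 + n3 - 2Q where n1/n2 count pairs tied
    in x/y, n3 pairs tied in both, Q the strict inversions of y after
    sorting by (x, y).
    """
    n = x.size
    n0 = n * (n - 1) // 2
    perm = np.lexsort((y, x))
    ys = y[perm]
    xs = x[perm]
    n1 = _tie_count(xs)
    n2 = _tie_count(np.sort(y, kind="mergesort"))
    # pairs tied in both: runs of equal (x, y) in lexicographic order
    both_change = np.r_[True, (np.diff(xs) != 0) | (np.diff(ys) != 0)]
    runs = np.diff(np.r_[np.flatnonzero(both_change), n])
    n3 = int(np.sum(runs * (runs - 1) // 2))
    _, q = _merge_count(ys)
    s = n0 - n1 - n2 + n3 - 2 * q
    return s / n0


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2).

    Ties in either argument count as neither concordant nor discordant;
    the denominator is always the total pair count.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise InvalidInputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise InvalidInputError("need at least 2 items")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("inputs must be finite")
    if x.size <= _BRUTE_FORCE_MAX_N:
        return _tau_a_enumerate(x, y)
    return _tau_a_fast(x, y)


@dataclass
class EvaluationResult:
    """Per-subject tau-a of one or more models plus the noise ceiling."""

    model_names: list[str]
    per_subject_tau: np.ndarray  # subjects x models
    ceiling_lower: float
    ceiling_upper: float

    def __post_init__(self):
        self.per_subject_tau = np.atleast_2d(np.asarray(self.per_subject_tau, dtype=float))
        if self.per_subject_tau.shape[1] != len(self.model_names):
            raise InvalidInputError("tau matrix columns must match model_names")
        if self.ceiling_lower > self.ceiling_upper + 1e-12:
            raise InvalidInputError("ceiling_lower exceeds ceiling_upper")

    @property
    def n_subjects(self) -> int:
        return self.per_subject_tau.shape[0]

    @property
    def mean_tau(self) -> np.ndarray:
        return self.per_subject_tau.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        """Standard error of the mean over single-subject correlations."""
        return self.per_subject_tau.std(axis=0, ddof=1) / np.sqrt(self.n_subjects)


def evaluate_model(predicted: RDM, subject_rdms: list[RDM]) -> np.ndarray:
    """Tau-a of a predicted RDM against each subject's judgment RDM."""
    taus = np.empty(len(subject_rdms))
    for i, subj in enumerate(subject_rdms):
        if set(subj.condition_ids) != set(predicted.condition_ids):
            raise InvalidInputError("condition mismatch between predicted and subject RDM")
        if subj.condition_ids != predicted.condition_ids:
            subj = subj.reorder(predicted.condition_ids)
        taus[i] = kendall_tau_a(predicted.values, subj.values)
    return taus


def noise_ceiling(subject_rdms: list[RDM]) -> tuple[float, float]:
    """(lower, upper) noise-ceiling estimate from inter-subject variability.

    Each subject RDM is rank-transformed; the upper bound averages each
    subject's tau-a with the mean rank RDM of all subjects, the lower
    bound with the mean rank RDM of the remaining subjects.
    """
    if len(subject_rdms) < 2:
        raise InvalidInputError("noise ceiling needs at least 2 subjects")
    ref = subject_rdms[0].condition_ids
    aligned = [r if r.condition_ids == ref else r.reorder(ref) for r in subject_rdms]
    ranks = np.array([rankdata(r.values) for r in aligned])
    total = ranks.sum(axis=0)
    n = ranks.shape[0]
    upper = np.mean([kendall_tau_a(ranks[i], total / n) for i in range(n)])
    lower = np.mean(
        [kendall_tau_a(ranks[i], (total - ranks[i]) / (n - 1)) for i in range(n)]
    )
    return float(min(lower, upper)), float(upper)
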