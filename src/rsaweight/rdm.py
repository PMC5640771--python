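"""Representational dissimilarity matrices (RDMs) and their core operations.

An RDM stores, for ``n`` conditions (here: object images), the
``n(n-1)/2`` pairwise dissimilarities between them.  Only the vector form
is stored, in the canonical pair order shared by every module in this
package: upper triangle, row-major over the condition order — i.e. the
order produced by :func:`itertools.combinations` and by
:func:`scipy.spatial.distance.pdist`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "RDM",
    "FeatureActivationSet",
    "n_pairs",
    "pair_indices",
    "squared_euclidean_rdm",
    "single_dimension_rdm",
    "average_rdms",
    "percentile_transform",
    "rdm_correlation_matrix",
]

#: allowed dissimilarity metrics
METRIC_TAGS = ("squared_euclidean", "judged_distance", "predicted", "rank_percentile")

#: metrics whose values must be non-negative
_NONNEG_TAGS = ("squared_euclidean", "judged_distance", "rank_percentile")


class InvalidInputError(ValueError):
    """Raised when an operation's input violates its contract."""


def n_pairs(n_conditions: int) -> int:
    """Number of unordered condition pairs."""
    return n_conditions * (n_conditions - 1) // 2


def pair_indices(n_conditions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column condition indices of each pair, in canonical order.

    Returns arrays ``(i, j)`` with ``i < j``, such that pair ``p`` of the
    vector form relates conditions ``i[p]`` and ``j[p]``.
    """
    iu = np.triu_indices(n_conditions, k=1)
    return iu[0], iu[1]


@dataclass(frozen=True)
class RDM:
    """A representational dissimilarity matrix in vector form.

    Parameters
    ----------
    condition_ids
        Ordered, unique identifiers of the ``n`` conditions.
    values
        Length ``n(n-1)/2`` vector of pairwise dissimilarities in the
        canonical pair order (upper triangle, row-major).
    metric_tag
        One of ``squared_euclidean``, ``judged_distance``, ``predicted``,
        ``rank_percentile``.
    """

    condition_ids: tuple[str, ...]
    values: np.ndarray
    metric_tag: str = "squared_euclidean"

    def __post_init__(self):
        object.__setattr__(self, "condition_ids", tuple(str(c) for c in self.condition_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.condition_ids)
        if len(set(self.condition_ids)) != n:
            raise InvalidInputError("condition_ids must be unique")
        if vals.ndim != 1 or vals.size != n_pairs(n):
            raise InvalidInputError(
                f"values must have length n(n-1)/2 = {n_pairs(n)}, got {vals.size}"
            )
        if self.metric_tag not in METRIC_TAGS:
            raise InvalidInputError(f"unknown metric_tag {self.metric_tag!r}")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("RDM values must be finite")
        if self.metric_tag in _NONNEG_TAGS and vals.size and vals.min() < 0:
            raise InvalidInputError(
                f"RDM values must be non-negative for metric {self.metric_tag!r}"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def n_pairs(self) -> int:
        return self.values.size

    def to_square(self) -> np.ndarray:
        """Square symmetric matrix with zero diagonal."""
        return squareform(self.values, checks=False)

    @classmethod
    def from_square(cls, matrix: np.ndarray, condition_ids: Sequence[str],
                    metric_tag: str = "squared_euclidean", atol: float = 1e-9) -> "RDM":
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("square-form RDM must be a square matrix")
        if not np.allclose(m, m.T, atol=atol, rtol=0):
            raise InvalidInputError("square-form RDM is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=atol):
            raise InvalidInputError("square-form RDM has a non-zero diagonal")
        sym = 0.5 * (m + m.T)
        np.fill_diagonal(sym, 0.0)
        return cls(tuple(condition_ids), squareform(sym, checks=False), metric_tag)

    def pair_ids(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.condition_ids, 2))

    def reorder(self, condition_ids: Sequence[str]) -> "RDM":
        """Return this RDM expressed in another condition order."""
        if set(condition_ids) != set(self.condition_ids):
            raise InvalidInputError("condition sets differ")
        sq = self.to_square()
        idx = [self.condition_ids.index(str(c)) for c in condition_ids]
        sq = sq[np.ix_(idx, idx)]
        return RDM(tuple(condition_ids), squareform(sq, checks=False), self.metric_tag)


@dataclass
class FeatureActivationSet:
    """Per-image activations for one source (e.g. one network layer).

    Each *dimension* is either a feature map (activation vector of
    ``units >= 2`` per image) or a single model unit (``units == 1``).
    """

    image_ids: tuple[str, ...]
    dimensions: list = field(default_factory=list)  # (dimension_id, group_tag, images x units)
    name: str = "layer"

    def __post_init__(self):
        self.image_ids = tuple(str(i) for i in self.image_ids)
        checked = []
        for dim_id, tag, mat in self.dimensions:
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            if mat.shape[0] != len(self.image_ids):
                raise InvalidInputError(
                    f"dimension {dim_id!r}: {mat.shape[0]} rows for "
                    f"{len(self.image_ids)} images"
                )
            if not np.all(np.isfinite(mat)):
                raise InvalidInputError(f"dimension {dim_id!r}: non-finite activations")
            checked.append((str(dim_id), str(tag), mat))
        self.dimensions = checked

    @property
    def dimension_ids(self) -> list[str]:
        return [d[0] for d in self.dimensions]


def squared_euclidean_rdm(activations: np.ndarray, condition_ids: Sequence[str],
                          metric_tag: str = "squared_euclidean") -> RDM:
    """RDM of squared Euclidean distances between per-image activation vectors.

    ``activations`` is images x units; pair (i, j) gets
    ``sum_u (a_iu - a_ju)^2``.
    """
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    if a.shape[0] < 2:
        raise InvalidInputError("need at least 2 images")
    if a.shape[0] != len(condition_ids):
        raise InvalidInputError("activations rows must match condition_ids")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("activations must be finite")
    vals = pdist(a, metric="sqeuclidean")
    # guard tiny negative rounding
    np.maximum(vals, 0.0, out=vals)
    return RDM(tuple(condition_ids), vals, metric_tag)


def single_dimension_rdm(values: np.ndarray, condition_ids: Sequence[str]) -> RDM:
    """RDM induced by a single scalar dimension: pairwise squared differences.

    For binary (present/absent) dimensions the dissimilarities are 0/1:
    one exactly when the feature or category is present in one image of
    the pair but absent in the other.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size != len(condition_ids):
        raise InvalidInputError(
            f"got {v.size} values for {len(condition_ids)} conditions"
        )
    return squared_euclidean_rdm(v[:, None], condition_ids)


def _check_aligned(rdms: Iterable[RDM]) -> list[RDM]:
    rdms = list(rdms)
    if not rdms:
        raise InvalidInputError("empty RDM list")
    ref = rdms[0].condition_ids
    for r in rdms[1:]:
        if r.condition_ids != ref:
            raise InvalidInputError("RDMs have mismatched condition_ids/order")
    return rdms


def average_rdms(rdms: Sequence[RDM], metric_tag: str | None = None) -> RDM:
    """Element-wise mean of aligned RDMs (e.g. across participants)."""
    rdms = _check_aligned(rdms)
    mean = np.mean([r.values for r in rdms], axis=0)
    tag = metric_tag or rdms[0].metric_tag
    return RDM(rdms[0].condition_ids, mean, tag)


def percentile_transform(rdm: RDM) -> RDM:
    """Replace each dissimilarity by its mid-rank percentile (0, 100].

    Used for display: 100 * rank / n_pairs with ties mid-ranked, so the
    largest untied value maps to 100 and rank order is preserved.
    """
    ranks = rankdata(rdm.values, method="average")
    vals = 100.0 * ranks / rdm.n_pairs
    return RDM(rdm.condition_ids, vals, "rank_percentile")


def rdm_correlation_matrix(rdms: Sequence[RDM]) -> np.ndarray:
    """Pairwise Kendall tau-a between aligned RDMs; diagonal = 1."""
    from .evaluation import kendall_tau_a  # local import avoids cycle

    rdms = _check_aligned(rdms)
    if len(rdms) < 2:
        raise InvalidInputError("need at least 2 RDMs")
    k = len(rdms)
    m = np.eye(k)
    for p in range(k):
        for q in range(p + 1, k):
            m[p, q] = m[q, p] = kendall_tau_a(rdms[p].values, rdms[q].values)
    return m
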