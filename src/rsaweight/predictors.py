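"""Predictor RDM sets: the design matrices of weighted representational modeling.

A predictor set stacks single-dimension RDMs as columns of a
``n_pairs x K`` matrix — one column per conceptual dimension (binary
feature/category label), per feature map (convolutional-layer-like
source) or per model unit (fully-connected-like source) — plus a
constant confound-mean column that plays the role of an unpenalized
intercept.  Because squared Euclidean distances sum across dimensions,
the unfitted ("equal weights") model prediction is simply the sum of the
non-confound columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rdm import (
    RDM,
    FeatureActivationSet,
    InvalidInputError,
    n_pairs,
    single_dimension_rdm,
    squared_euclidean_rdm,
)

__all__ = [
    "ConceptualModel",
    "PredictorRDMSet",
    "FEATURE_GROUPS",
    "CATEGORY_GROUPS",
    "merge_correlated_dimensions",
    "build_predictor_set",
    "combine_predictor_sets",
]

FEATURE_GROUPS = ("parts", "colors", "textures", "contours")
CATEGORY_GROUPS = ("subordinate", "basic", "superordinate")
GROUP_TAGS = FEATURE_GROUPS + CATEGORY_GROUPS

CONFOUND_ID = "confound_mean"


@dataclass
class ConceptualModel:
    """Images x labeled dimensions, values in [0, 1] (binary pre-merge)."""

    image_ids: tuple[str, ...]
    dimensions: list = field(default_factory=list)  # (dimension_id, group_tag, values)

    def __post_init__(self):
        self.image_ids = tuple(str(i) for i in self.image_ids)
        seen = set()
        checked = []
        for dim_id, tag, vals in self.dimensions:
            vals = np.asarray(vals, dtype=float).reshape(-1)
            if vals.size != len(self.image_ids):
                raise InvalidInputError(f"dimension {dim_id!r}: wrong length")
            if vals.min() < 0 or vals.max() > 1:
                raise InvalidInputError(f"dimension {dim_id!r}: values outside [0, 1]")
            if tag not in GROUP_TAGS:
                raise InvalidInputError(f"dimension {dim_id!r}: unknown group_tag {tag!r}")
            if dim_id in seen:
                raise InvalidInputError(f"duplicate dimension_id {dim_id!r}")
            seen.add(dim_id)
            checked.append((str(dim_id), str(tag), vals))
        self.dimensions = checked

    @property
    def dimension_ids(self) -> list[str]:
        return [d[0] for d in self.dimensions]

    def subset(self, group_tags) -> "ConceptualModel":
        tags = set([group_tags] if isinstance(group_tags, str) else group_tags)
        dims = [d for d in self.dimensions if d[1] in tags]
        return ConceptualModel(self.image_ids, dims)

    def value_matrix(self) -> np.ndarray:
        return np.column_stack([d[2] for d in self.dimensions])


@dataclass
class PredictorRDMSet:
    """Stack of single-dimension RDM columns plus the confound-mean column."""

    name: str
    condition_ids: tuple[str, ...]
    matrix: np.ndarray            # n_pairs x K
    column_ids: list[str]
    includes_confound_mean: bool = True

    def __post_init__(self):
        self.condition_ids = tuple(str(c) for c in self.condition_ids)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != n_pairs(len(self.condition_ids)):
            raise InvalidInputError("matrix rows must equal n_pairs(condition_ids)")
        if self.matrix.shape[1] != len(self.column_ids):
            raise InvalidInputError("column_ids must match matrix columns")
        if self.matrix.shape[1] < 1:
            raise InvalidInputError("predictor set needs K >= 1 columns")
        if self.matrix.size and self.matrix.min() < 0:
            raise InvalidInputError("predictor columns must be non-negative")
        n_conf = sum(c == CONFOUND_ID for c in self.column_ids)
        if self.includes_confound_mean != (n_conf == 1):
            raise InvalidInputError(
                f"confound-mean flag inconsistent with {n_conf} confound column(s)"
            )

    @property
    def confound_index(self) -> int | None:
        return self.column_ids.index(CONFOUND_ID) if self.includes_confound_mean else None

    @property
    def predictor_indices(self) -> np.ndarray:
        """Indices of the non-confound columns."""
        ci = self.confound_index
        return np.array([k for k in range(self.matrix.shape[1]) if k != ci])

    def unfitted_prediction(self) -> RDM:
        """Equal-weights model: plain sum of the non-confound columns."""
        vals = self.matrix[:, self.predictor_indices].sum(axis=1)
        return RDM(self.condition_ids, vals, "predicted")


def merge_correlated_dimensions(model: ConceptualModel, threshold: float = 0.9) -> ConceptualModel:
    """Merge highly-correlated dimensions by averaging their image values.

    Within each group_tag, dimensions whose pairwise Pearson correlation
    of image values is >= ``threshold`` are grouped by single linkage and
    each group is replaced by the mean of its members.  Merging
    stabilizes the subsequent regularized fit.  Zero-variance dimensions
    are excluded with a warning (their correlation is undefined).
    """
    if not model.dimensions:
        raise InvalidInputError("model has no dimensions")
    if not (0 < threshold <= 1):
        raise InvalidInputError("threshold must be in (0, 1]")
    out = []
    for tag in GROUP_TAGS:
        dims = [d for d in model.dimensions if d[1] == tag]
        if not dims:
            continue
        kept = []
        for dim_id, _, vals in dims:
            if np.std(vals) == 0:
                warnings.warn(f"dimension {dim_id!r}: zero variance, excluded from model")
            else:
                kept.append((dim_id, vals))
        if not kept:
            continue
        vmat = np.column_stack([v for _, v in kept])
        corr = np.corrcoef(vmat, rowvar=False)
        corr = np.atleast_2d(corr)
        # single-linkage grouping on corr >= threshold (union-find)
        k = len(kept)
        parent = list(range(k))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(k):
            for j in range(i + 1, k):
                if corr[i, j] >= threshold - 1e-12:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(k):
            groups.setdefault(find(i), []).append(i)
        for members in sorted(groups.values(), key=lambda m: m[0]):
            if len(members) == 1:
                dim_id, vals = kept[members[0]]
            else:
                dim_id = "+".join(kept[m][0] for m in members)
                vals = vmat[:, members].mean(axis=1)
            out.append((dim_id, tag, vals))
    return ConceptualModel(model.image_ids, out)


def _confound_column(npair: int) -> np.ndarray:
    return np.ones(npair)


def build_predictor_set(
    source: ConceptualModel | FeatureActivationSet,
    name: str | None = None,
    include_confound: bool = True,
) -> PredictorRDMSet:
    """Build the regression design from a conceptual model or activation set.

    One column per dimension: squared pairwise differences for scalar
    dimensions (conceptual values, single model units) and squared
    Euclidean distances per feature map for multi-unit dimensions.  The
    constant confound-mean column is appended last.
    """
    if isinstance(source, ConceptualModel):
        if not source.dimensions:
            raise InvalidInputError("empty conceptual model")
        ids = source.image_ids
        cols = [single_dimension_rdm(vals, ids).values for _, _, vals in source.dimensions]
        col_ids = [d[0] for d in source.dimensions]
        default_name = "conceptual"
    elif isinstance(source, FeatureActivationSet):
        if not source.dimensions:
            raise InvalidInputError("empty activation set")
        ids = source.image_ids
        cols = [squared_euclidean_rdm(mat, ids).values for _, _, mat in source.dimensions]
        col_ids = [d[0] for d in source.dimensions]
        default_name = source.name
    else:
        raise InvalidInputError(f"unsupported source type {type(source).__name__}")
    mat = np.column_stack(cols)
    if include_confound:
        mat = np.column_stack([mat, _confound_column(mat.shape[0])])
        col_ids = col_ids + [CONFOUND_ID]
    return PredictorRDMSet(
        name or default_name, ids, mat, col_ids, includes_confound_mean=include_confound
    )


def combine_predictor_sets(a: PredictorRDMSet, b: PredictorRDMSet,
                           name: str | None = None) -> PredictorRDMSet:
    """Horizontally concatenate two predictor sets over the same pairs.

    Column ids are namespaced by source set; exactly one confound-mean
    column is retained.  Duplicated predictor columns are flagged with a
    warning but kept (the ridge penalty handles collinearity).
    """
    if a.condition_ids != b.condition_ids:
        raise InvalidInputError("predictor sets have mismatched condition_ids/pair order")
    cols, ids = [], []
    for src in (a, b):
        keep = src.predictor_indices
        cols.append(src.matrix[:, keep])
        ids.extend(f"{src.name}:{src.column_ids[k]}" for k in keep)
    mat = np.column_stack(cols)
    # detect exact duplicates across the two sources
    _, first_idx = np.unique(mat.round(12), axis=1, return_index=True)
    if first_idx.size < mat.shape[1]:
        warnings.warn(
            f"{mat.shape[1] - first_idx.size} duplicated predictor column(s) "
            "in combined set; ridge regularization will handle collinearity"
        )
    include_conf = a.includes_confound_mean or b.includes_confound_mean
    if include_conf:
        mat = np.column_stack([mat, _confound_column(mat.shape[0])])
        ids.append(CONFOUND_ID)
    return PredictorRDMSet(
        name or f"{a.name}+{b.name}", a.condition_ids, mat, ids,
        includes_confound_mean=include_conf,
    )
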