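"""Readers and writers for the package's on-disk formats.

Formats are deliberately plain: square-form RDM CSV (validated for
symmetry and zero diagonal), long-form RDM TSV, multi-arrangement
session TSV, conceptual-model CSV with a two-row header (dimension ids,
group tags), and an HDF5 activation container with one group per source
layer and one dataset per dimension.
"""

from __future__ import annotations



import h5py
import numpy as np
import pandas as pd

from .multiarrangement import MultiArrangementSession, Trial
from .predictors import ConceptualModel
from .rdm import RDM, FeatureActivationSet, InvalidInputError, n_pairs

__all__ = [
    "write_rdm_csv", "read_rdm_csv",
    "write_rdm_tsv", "read_rdm_tsv",
    "write_session_tsv", "read_session_tsv",
    "write_conceptual_csv", "read_conceptual_csv",
    "write_activations_h5", "read_activations_h5",
]


class ParseError(InvalidInputError):
    """A file does not conform to its declared format."""


def write_rdm_csv(rdm: RDM, path) -> None:
    """Square-form CSV: first row/column are condition ids."""
    sq = rdm.to_square()
    df = pd.DataFrame(sq, index=rdm.condition_ids, columns=rdm.condition_ids)
    df.to_csv(path, float_format="%.17g")


def read_rdm_csv(path, metric_tag: str = "judged_distance") -> RDM:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ParseError(f"{path}: row and column condition ids differ")
    try:
        return RDM.from_square(df.to_numpy(dtype=float), list(df.columns.astype(str)),
                               metric_tag)
    except InvalidInputError as e:
        raise ParseError(f"{path}: {e}") from e


def write_rdm_tsv(rdm: RDM, path) -> None:
    """Long-form TSV with columns image_i, image_j, dissimilarity."""
    pairs = rdm.pair_ids()
    df = pd.DataFrame({
        "image_i": [a for a, _ in pairs],
        "image_j": [b for _, b in pairs],
        "dissimilarity": rdm.values,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_rdm_tsv(path, metric_tag: str = "judged_distance") -> RDM:
    df = pd.read_csv(path, sep="\t")
    for col in ("image_i", "image_j", "dissimilarity"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ids: list[str] = []
    for col in ("image_i", "image_j"):
        for v in df[col].astype(str):
            if v not in ids:
                ids.append(v)
    n = len(ids)
    if len(df) != n_pairs(n):
        raise ParseError(f"{path}: {len(df)} rows is not n(n-1)/2 for {n} conditions")
    pos = {c: k for k, c in enumerate(ids)}
    sq = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    for line, (a, b, d) in enumerate(zip(df["image_i"].astype(str),
                                         df["image_j"].astype(str),
                                         df["dissimilarity"]), start=2):
        i, j = pos[a], pos[b]
        if i == j or seen[i, j]:
            raise ParseError(f"{path}: line {line}: duplicate or self pair ({a}, {b})")
        sq[i, j] = sq[j, i] = float(d)
        seen[i, j] = seen[j, i] = True
    return RDM.from_square(sq, ids, metric_tag)


def write_session_tsv(sessions, path) -> None:
    """Session TSV: subject_id, trial_index, image_i, image_j, distance."""
    if isinstance(sessions, MultiArrangementSession):
        sessions = [sessions]
    rows = []
    for s in sessions:
        for t in s.trials:
            pairs = [(a, b) for k, a in enumerate(t.image_ids)
                     for b in t.image_ids[k + 1:]]
            for (a, b), d in zip(pairs, t.distances):
                rows.append((s.subject_id, t.trial_index, a, b, d))
    pd.DataFrame(rows, columns=["subject_id", "trial_index", "image_i", "image_j",
                                "distance"]).to_csv(path, sep="\t", index=False,
                                                    float_format="%.17g")


def read_session_tsv(path, image_ids=None) -> list[MultiArrangementSession]:
    """Read one or more subjects' sessions from a session TSV."""
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "trial_index", "image_i", "image_j", "distance"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if image_ids is None:
        ids: list[str] = []
        for col in ("image_i", "image_j"):
            for v in df[col].astype(str):
                if v not in ids:
                    ids.append(v)
        image_ids = ids
    sessions = []
    for subj, sdf in df.groupby("subject_id", sort=False):
        trials = []
        for tidx, tdf in sdf.groupby("trial_index", sort=True):
            members: list[str] = []
            for col in ("image_i", "image_j"):
                for v in tdf[col].astype(str):
                    if v not in members:
                        members.append(v)
            m = len(members)
            if len(tdf) != n_pairs(m):
                raise ParseError(
                    f"{path}: subject {subj} trial {tidx}: {len(tdf)} rows "
                    f"is not m(m-1)/2 for {m} images"
                )
            pos = {c: k for k, c in enumerate(members)}
            dmat = np.zeros((m, m))
            for a, b, d in zip(tdf["image_i"].astype(str), tdf["image_j"].astype(str),
                               tdf["distance"]):
                dmat[pos[a], pos[b]] = dmat[pos[b], pos[a]] = float(d)
            iu = np.triu_indices(m, k=1)
            trials.append(Trial(int(tidx), tuple(members), dmat[iu]))
        sessions.append(MultiArrangementSession(str(subj), tuple(image_ids), trials))
    return sessions


def write_conceptual_csv(model: ConceptualModel, path) -> None:
    """Conceptual CSV: header rows = dimension ids then group tags."""
    cols = pd.MultiIndex.from_tuples(
        [(d[0], d[1]) for d in model.dimensions], names=["dimension_id", "group_tag"]
    )
    df = pd.DataFrame(model.value_matrix(), index=model.image_ids, columns=cols)
    df.index.name = "image_id"
    df.to_csv(path, float_format="%.17g")


def read_conceptual_csv(path) -> ConceptualModel:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    dims = []
    for dim_id, tag in df.columns:
        try:
            dims.append((str(dim_id), str(tag), df[(dim_id, tag)].to_numpy(dtype=float)))
        except ValueError as e:
            raise ParseError(f"{path}: dimension {dim_id!r}: {e}") from e
    try:
        return ConceptualModel(tuple(df.index.astype(str)), dims)
    except InvalidInputError as e:
        raise ParseError(f"{path}: {e}") from e


def write_activations_h5(layers: list[FeatureActivationSet], path) -> None:
    """HDF5 container: /image_ids plus one group per layer, one dataset
    per dimension (images x units) with a ``group_tag`` attribute."""
    with h5py.File(path, "w") as f:
        ref_ids = layers[0].image_ids
        f.create_dataset("image_ids", data=np.array(ref_ids, dtype="S"))
        for layer in layers:
            if layer.image_ids != ref_ids:
                raise InvalidInputError("all layers must share the image order")
            grp = f.create_group(layer.name)
            for k, (dim_id, tag, mat) in enumerate(layer.dimensions):
                ds = grp.create_dataset(dim_id, data=mat)
                ds.attrs["group_tag"] = tag
                ds.attrs["order"] = k


def read_activations_h5(path) -> list[FeatureActivationSet]:
    out = []
    with h5py.File(path, "r") as f:
        if "image_ids" not in f:
            raise ParseError(f"{path}: missing image_ids dataset")
        ids = tuple(s.decode() for s in f["image_ids"][()])
        for name in f:
            if name == "image_ids":
                continue
            grp = f[name]
            dims = []
            for dim_id in grp:
                ds = grp[dim_id]
                dims.append((ds.attrs.get("order", 0), dim_id,
                             ds.attrs.get("group_tag", "parts"), ds[()]))
            dims.sort(key=lambda d: (d[0], d[1]))
            out.append(FeatureActivationSet(ids, [d[1:] for d in dims], name=name))
    return out
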