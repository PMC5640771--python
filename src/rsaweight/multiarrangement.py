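"""Averaging multi-arrangement trials into a per-subject RDM.

In the multi-arrangement task a subject drags images inside a circular
arena so that on-screen distance expresses judged dissimilarity.  Each
trial shows a subset of the images and yields pairwise distances on an
arbitrary per-trial scale — only the relations between distances within
one trial are meaningful.  Trials are combined by an iterative scaling
procedure: alternately rescale each trial (least squares) to match the
current average, and recompute the per-pair average of the rescaled
trials, until the average stops changing.

The update is linear in the current average, so the iteration is a power
iteration on a non-negative linear operator; the average is renormalized
to unit RMS each step and convergence is measured on the normalized
vector.  The final RDM is reported at unit root-mean-square
dissimilarity since absolute scale is meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rdm import RDM, InvalidInputError, n_pairs, pair_indices

__all__ = [
    "MultiArrangementSession",
    "AveragingDiagnostics",
    "CoverageError",
    "ConvergenceError",
    "iterative_scale_average",
    "trial_consistency",
]


class CoverageError(InvalidInputError):
    """Some image pair is covered by no trial."""

    def __init__(self, missing_pairs):
        self.missing_pairs = list(missing_pairs)
        super().__init__(
            f"{len(self.missing_pairs)} image pair(s) covered by no trial, "
            f"e.g. {self.missing_pairs[:5]}"
        )


class ConvergenceError(RuntimeError):
    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        super().__init__(
            f"iterative averaging did not converge in "
            f"{diagnostics.iterations_used} iterations "
            f"(final relative change {diagnostics.final_relative_change:.3g})"
        )


@dataclass
class Trial:
    trial_index: int
    image_ids: tuple[str, ...]  # subset shown on this trial, >= 3 images
    distances: np.ndarray       # m(m-1)/2 pairwise on-screen distances

    def __post_init__(self):
        self.image_ids = tuple(str(i) for i in self.image_ids)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        m = len(self.image_ids)
        if m < 3:
            raise InvalidInputError(f"trial {self.trial_index}: needs >= 3 images")
        if len(set(self.image_ids)) != m:
            raise InvalidInputError(f"trial {self.trial_index}: duplicate image ids")
        if self.distances.size != n_pairs(m):
            raise InvalidInputError(
                f"trial {self.trial_index}: expected {n_pairs(m)} distances, "
                f"got {self.distances.size}"
            )
        if self.distances.min() < 0 or not np.all(np.isfinite(self.distances)):
            raise InvalidInputError(f"trial {self.trial_index}: invalid distances")


@dataclass
class MultiArrangementSession:
    """All trials of one subject, over a fixed full image set."""

    subject_id: str
    image_ids: tuple[str, ...]
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self):
        self.image_ids = tuple(str(i) for i in self.image_ids)
        known = set(self.image_ids)
        for t in self.trials:
            unknown = set(t.image_ids) - known
            if unknown:
                raise InvalidInputError(
                    f"trial {t.trial_index}: unknown image ids {sorted(unknown)}"
                )


@dataclass
class AveragingDiagnostics:
    iterations_used: int
    final_relative_change: float
    pair_evidence_counts: np.ndarray


def _trial_pair_positions(session: MultiArrangementSession) -> list[np.ndarray]:
    """Global canonical pair index of each trial's pairs."""
    n = len(session.image_ids)
    pos = {img: k for k, img in enumerate(session.image_ids)}
    # canonical pair p <-> (i, j), i < j
    pair_no = np.zeros((n, n), dtype=np.int64)
    ii, jj = pair_indices(n)
    pair_no[ii, jj] = np.arange(ii.size)
    pair_no[jj, ii] = np.arange(ii.size)
    out = []
    for t in session.trials:
        idx = np.array([pos[i] for i in t.image_ids])
        ti, tj = pair_indices(idx.size)
        out.append(pair_no[idx[ti], idx[tj]])
    return out


def iterative_scale_average(
    session: MultiArrangementSession,
    tolerance: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[RDM, AveragingDiagnostics]:
    """Combine a session's trials into one RDM by iterative rescaling.

    Raises :class:`CoverageError` if some pair appears in no trial, and
    :class:`ConvergenceError` if the fixed point is not reached within
    ``max_iter`` iterations.
    """
    if not session.trials:
        raise InvalidInputError("session has no trials")
    n = len(session.image_ids)
    npair = n_pairs(n)
    positions = _trial_pair_positions(session)

    evidence = np.zeros(npair, dtype=np.int64)
    for p in positions:
        np.add.at(evidence, p, 1)
    if evidence.min() == 0:
        ii, jj = pair_indices(n)
        missing = [
            (session.image_ids[ii[k]], session.image_ids[jj[k]])
            for k in np.flatnonzero(evidence == 0)
        ]
        raise CoverageError(missing)

    def unit_rms(v):
        rms = np.sqrt(np.mean(v ** 2))
        return v / rms if rms > 0 else v

    trial_d = [t.distances for t in session.trials]
    # init: per-pair mean of raw (unscaled) trials
    avg = np.zeros(npair)
    for p, d in zip(positions, trial_d):
        np.add.at(avg, p, d)
    avg = unit_rms(avg / evidence)

    rel_change = np.inf
    for it in range(1, max_iter + 1):
        new = np.zeros(npair)
        for p, d in zip(positions, trial_d):
            dd = float(d @ d)
            scale = float(d @ avg[p]) / dd if dd > 0 else 1.0
            np.add.at(new, p, scale * d)
        new = unit_rms(new / evidence)
        rel_change = float(np.linalg.norm(new - avg) / max(np.linalg.norm(avg), 1e-300))
        avg = new
        if rel_change < tolerance:
            break
    diag = AveragingDiagnostics(it, rel_change, evidence)
    if rel_change >= tolerance:
        raise ConvergenceError(diag)
    return RDM(session.image_ids, avg, "judged_distance"), diag


def trial_consistency(session: MultiArrangementSession) -> float:
    """Mean Pearson r between each trial and the running average so far.

    For each trial ``t >= 2``, correlates its distances with the running
    average of trials ``1..t-1`` over shared pairs; correlations are
    averaged across trials via the Fisher z transform.  Because per-trial
    scale is arbitrary, each trial is rescaled (least squares, over
    shared pairs) to match the running average before entering it, so
    the average is scale-consistent.  Trials sharing fewer than 3 pairs
    with the running average are skipped with a warning.
    """
    if len(session.trials) < 2:
        raise InvalidInputError("trial consistency needs >= 2 trials")
    npair = n_pairs(len(session.image_ids))
    positions = _trial_pair_positions(session)

    run_sum = np.zeros(npair)
    run_cnt = np.zeros(npair, dtype=np.int64)
    zs = []
    for t, (p, trial) in enumerate(zip(positions, session.trials)):
        d = trial.distances
        if t > 0:
            shared = run_cnt[p] > 0
            avg = (run_sum[p] / np.maximum(run_cnt[p], 1))
            a = d[shared]
            b = avg[shared]
            if int(shared.sum()) < 3:
                warnings.warn(
                    f"trial {trial.trial_index}: fewer than 3 pairs shared with "
                    "previous trials; skipped in consistency estimate"
                )
            else:
                if a.std() == 0 or b.std() == 0:
                    warnings.warn(
                        f"trial {trial.trial_index}: zero variance on shared pairs; skipped"
                    )
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                    zs.append(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
            dd = float(a @ a) if shared.any() else 0.0
            if dd > 0:
                d = d * (float(a @ b) / dd)
        np.add.at(run_sum, p, d)
        np.add.at(run_cnt, p, 1)
    if not zs:
        raise InvalidInputError("no trial shared enough pairs with the running average")
    return float(np.tanh(np.mean(zs)))
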