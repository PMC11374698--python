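"""Cross-subject joint-subspace alignment.

Subjects contribute different neurons, but their task-related population
dynamics are similar.  The alignment stacks the six normalised
condition-average matrices of all subjects (cells x 240 samples), runs one
PCA over the concatenation, and splits the resulting coefficient matrix
back into per-subject blocks, which are orthonormalised by QR.  The
columns of each per-subject matrix P_s then project that subject's cell
activity into one shared k-dimensional coding space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Condition order used when concatenating the six condition averages.
CONDITION_ORDER = (
    "avoid-task1",
    "avoid-task2",
    "error-task1",
    "error-task2",
    "ITI-task1",
    "ITI-task2",
)


@dataclass
class JointSubspace:
    """Shared k-dimensional coding space across subjects."""

    k: int
    coefficients: np.ndarray  # total cells x k, PCA coefficient matrix
    projections: list[np.ndarray]  # per subject, cells_s x k, orthonormal columns
    subject_slices: list[slice]

    def __post_init__(self) -> None:
        for p in self.projections:
            err = np.abs(p.T @ p - np.eye(self.k)).max()
            if err > 1e-8:
                raise ValueError(f"projection columns not orthonormal (err={err:.2e})")


def build_joint_matrix(
    averages_by_subject: list[dict[str, np.ndarray]],
    condition_order: tuple[str, ...] = CONDITION_ORDER,
) -> tuple[np.ndarray, list[slice]]:
    """Stack and normalise condition averages into one cells x 240 matrix.

    Per condition, the subjects' cells x 40 averages are stacked along the
    cell axis, each cell's row mean within the block is subtracted, and the
    block is scaled to unit Frobenius norm; the six blocks are then
    concatenated along time.

    Returns the joint matrix and the per-subject row slices.
    """
    blocks = []
    for cond in condition_order:
        try:
            block = np.concatenate([av[cond] for av in averages_by_subject], axis=0)
        except KeyError as e:
            raise ValueError(f"condition {e.args[0]!r} missing from averages") from e
        if block.shape[1] != averages_by_subject[0][condition_order[0]].shape[1]:
            raise ValueError("condition averages must share the time axis")
        block = block - block.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(block)
        if norm == 0:
            raise ValueError(
                f"condition {cond!r} average is constant in time (zero norm)"
            )
        blocks.append(block / norm)
    joint = np.concatenate(blocks, axis=1)

    slices, start = [], 0
    for av in averages_by_subject:
        n = av[condition_order[0]].shape[0]
        slices.append(slice(start, start + n))
        start += n
    return joint, slices


def fit_joint_subspace(
    joint_matrix: np.ndarray, subject_slices: list[slice], k: int = 10
) -> JointSubspace:
    """PCA over the joint matrix, then per-subject QR orthonormalisation.

    The left singular vectors of the (already row-centred) joint matrix
    give the cells x k coefficient matrix; its per-subject row blocks are
    orthonormalised by (unpivoted) QR so that each P_s has orthonormal
    columns spanning the same subspace as the coefficient block.  Signs
    follow a deterministic convention (largest-magnitude coefficient
    entry positive; QR R-diagonal positive).
    """
    n_min = min(sl.stop - sl.start for sl in subject_slices)
    if k > n_min:
        raise ValueError(f"k={k} exceeds the smallest subject cell count {n_min}")
    u, svals, _ = np.linalg.svd(joint_matrix, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * 1e-12))
    if k > rank:
        raise ValueError(f"k={k} exceeds the joint matrix rank {rank}")
    coeff = u[:, :k]
    # deterministic sign: largest-|.| entry of each column positive
    flip = np.sign(coeff[np.argmax(np.abs(coeff), axis=0), np.arange(k)])
    coeff = coeff * flip

    projections = []
    for sl in subject_slices:
        q, r = np.linalg.qr(coeff[sl])
        q = q * np.sign(np.diag(r))
        projections.append(q)
    return JointSubspace(
        k=k, coefficients=coeff, projections=projections, subject_slices=subject_slices
    )


def project(traces: np.ndarray, p_s: np.ndarray) -> np.ndarray:
    """Project cells x time activity into the joint subspace: P_sᵀ x."""
    traces = np.asarray(traces, dtype=float)
    if traces.shape[0] != p_s.shape[0]:
        raise ValueError(
            f"trace cell count {traces.shape[0]} does not match projection "
            f"rows {p_s.shape[0]}"
        )
    return p_s.T @ traces


def explained_variance(p_s: np.ndarray, data: np.ndarray) -> float:
    """Fraction of squared Frobenius norm captured by the subspace.

    ``VE = ||P_sᵀ X||²_F / ||X||²_F``; the data must be mean-subtracted
    consistently with :func:`build_joint_matrix`.
    """
    data = np.asarray(data, dtype=float)
    total = np.linalg.norm(data) ** 2
    if total == 0:
        raise ValueError("zero-variance data")
    return float(np.linalg.norm(p_s.T @ data) ** 2 / total)


def alignment_quality(
    subspace: JointSubspace,
    averages_by_subject: list[dict[str, np.ndarray]],
    condition_order: tuple[str, ...] = CONDITION_ORDER,
) -> np.ndarray:
    """Per-dimension cross-subject similarity of the projected dynamics.

    For every joint-subspace dimension, each subject's (row-centred)
    condition averages are projected onto that dimension and the mean
    pairwise Pearson correlation of the resulting time courses across
    subjects is returned.  Scores lie in [-1, 1]; a constant projection
    contributes 0 with a warning.
    """
    n_sub = len(averages_by_subject)
    if n_sub < 2:
        raise ValueError("alignment quality requires at least 2 subjects")
    courses = []
    for s, av in enumerate(averages_by_subject):
        blocks = []
        for cond in condition_order:
            block = av[cond] - av[cond].mean(axis=1, keepdims=True)
            blocks.append(block)
        x = np.concatenate(blocks, axis=1)
        courses.append(subspace.projections[s].T @ x)  # k x 240

    scores = np.zeros(subspace.k)
    for d in range(subspace.k):
        rs = []
        for i in range(n_sub):
            for j in range(i + 1, n_sub):
                a, b = courses[i][d], courses[j][d]
                if a.std() == 0 or b.std() == 0:
                    warnings.warn(
                        f"constant projection in dimension {d}; score 0",
                        stacklevel=2,
                    )
                    rs.append(0.0)
                else:
                    rs.append(float(np.corrcoef(a, b)[0, 1]))
        scores[d] = np.mean(rs)
    return scores
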