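"""Rigid-body superposition, dihedrals and small geometric utilities.

Coordinates are flat arrays of length 3N for N interaction sites (Å) except
where a function documents otherwise.  Superposition uses the Kabsch
algorithm restricted to proper rotations, so chiral configurations are not
matched to their mirror images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .exceptions import ContractViolation

__all__ = ["AlignmentResult", "align_rmsd", "dihedral", "rotation_matrix"]


@dataclass
class AlignmentResult:
    """Outcome of a least-squares rigid superposition."""

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    degenerate: bool = False
    permutation: np.ndarray | None = None

    def __iter__(self):  # (rmsd, rotation) unpacking convenience
        yield self.rmsd
        yield self.rotation


def _as_sites(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size % 3 != 0:
        raise ContractViolation(f"coordinate length {x.size} is not 3N")
    return x.reshape(-1, 3)


def _kabsch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation minimising ||a @ R.T - b|| for centred site sets."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def align_rmsd(
    x_a: np.ndarray,
    x_b: np.ndarray,
    permute: bool = False,
    labels: np.ndarray | None = None,
) -> AlignmentResult:
    """Least-squares rigid superposition of ``x_b`` onto ``x_a``.

    Parameters
    ----------
    x_a, x_b
        Flat 3N coordinate arrays of the same length with N >= 3 sites.
    permute
        If true, identically labelled sites may be permuted (Hungarian
        assignment alternated with re-superposition).
    labels
        Optional per-site labels restricting permutations; sites may only be
        exchanged within a label class.  Ignored unless ``permute``.

    Returns
    -------
    AlignmentResult
        With ``rmsd`` (Å) and the proper ``rotation`` applied to centred
        ``x_b``.  Collinear (rank-deficient) configurations are flagged
        ``degenerate`` and fall back to translation-only superposition.
    """
    a = _as_sites(x_a)
    b = _as_sites(x_b)
    if a.shape != b.shape:
        raise ContractViolation("configurations differ in dimension")
    if a.shape[0] < 3:
        raise ContractViolation("3-D alignment needs at least 3 sites")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb

    # collinear / coincident sets: rotation is underdetermined
    rank = np.linalg.matrix_rank(a0, tol=1e-8)
    if rank < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        rmsd = float(np.sqrt(np.mean(np.sum((a0 - b0) ** 2, axis=1))))
        return AlignmentResult(rmsd, np.eye(3), ca - cb, degenerate=True)

    perm = np.arange(a.shape[0])
    if permute:
        lab = np.zeros(a.shape[0]) if labels is None else np.asarray(labels)
        label_penalty = np.where(
            np.not_equal.outer(lab, lab), 1e9, 0.0
        )

        def assignment(rot):
            cost = cdist(a0, b0 @ rot.T, "sqeuclidean") + label_penalty
            _, col = linear_sum_assignment(cost)
            return col

        best = None
        # two starts: assign before rotating, and rotate before assigning —
        # alternation can stall in either basin
        for p in (assignment(np.eye(3)), np.arange(a.shape[0])):
            for _ in range(10):
                rot = _kabsch(b0[p], a0)
                p_new = assignment(rot)
                if np.array_equal(p_new, p):
                    break
                p = p_new
            rot = _kabsch(b0[p], a0)
            moved = b0[p] @ rot.T
            rmsd = float(np.sqrt(np.mean(np.sum((moved - a0) ** 2, axis=1))))
            if best is None or rmsd < best[0]:
                best = (rmsd, rot, p)
        rmsd, rot, perm = best
        return AlignmentResult(rmsd, rot, ca - cb, permutation=perm)

    rot = _kabsch(b0, a0)
    moved = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a0) ** 2, axis=1))))
    return AlignmentResult(rmsd, rot, ca - cb, permutation=None)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` (need not be normalised) by ``angle_rad``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cc = 1 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )
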