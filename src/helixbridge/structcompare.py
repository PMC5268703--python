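"""Least-squares Cα superposition of two structures.

Residues are paired by (chain, author residue number); the optimal
rigid-body fit is the closed-form Kabsch solution (SVD of the covariance
matrix, with reflection correction), unweighted over all matched Cα and
with no outlier-rejection iterations.  An optional iterative mode
re-fits after discarding pairs beyond a distance cutoff, for
non-isomorphous cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, InsufficientDataError
from .io_core import StructureFrame


@dataclass
class SuperpositionResult:
    """Rigid-body fit of mobile onto reference coordinates.

    ``transform(x)`` maps mobile coordinates into the reference frame:
    x @ rotation.T + translation.
    """

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int
    matched_residues: list[tuple[str, int]] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def match_ca(
    ref: StructureFrame, mobile: StructureFrame
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Pair Cα atoms of two structures by (chain, residue number).

    Only residues present with a Cα in both structures are used.
    Returns (ref_coords, mobile_coords, matched residue keys).
    """
    matched = []
    ref_xyz = []
    mob_xyz = []
    for key, res in ref.topology.residues.items():
        i = res.atom_index.get("CA")
        j_res = mobile.topology.residues.get(key)
        j = j_res.atom_index.get("CA") if j_res is not None else None
        if i is not None and j is not None:
            matched.append(key)
            ref_xyz.append(ref.coordinates[i])
            mob_xyz.append(mobile.coordinates[j])
    if len(matched) < 3:
        raise InsufficientDataError(
            f"only {len(matched)} common Cα between the structures; need >= 3"
        )
    return np.array(ref_xyz), np.array(mob_xyz), matched


def superpose(
    ref_coords: np.ndarray,
    mobile_coords: np.ndarray,
    matched_residues: list[tuple[str, int]] | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid fit of mobile onto reference (Kabsch).

    Reflections are corrected so the rotation is always proper
    (det = +1).  The RMSD is computed over all paired atoms after the
    transform.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InsufficientDataError("coordinate arrays must both be (n, 3)")
    n = len(ref)
    if n < 3:
        raise InsufficientDataError("need at least 3 paired atoms")

    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    # degenerate if the paired points span < 2 dimensions in either set
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(
        mob_c, tol=1e-8
    ) < 2:
        raise FitError("collinear/degenerate coordinates: rotation is not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(
        rotation, translation, rmsd, n, list(matched_residues or [])
    )


def superpose_structures(
    ref: StructureFrame,
    mobile: StructureFrame,
    *,
    iterative_cutoff: float | None = None,
    max_iterations: int = 10,
) -> SuperpositionResult:
    """Match Cα by residue number and superpose mobile onto ref.

    ``iterative_cutoff`` (Å), if given, repeats the fit discarding pairs
    whose post-fit deviation exceeds the cutoff until the matched set is
    stable (off by default; the plain fit is the reference behaviour).
    """
    ref_xyz, mob_xyz, matched = match_ca(ref, mobile)
    result = superpose(ref_xyz, mob_xyz, matched)
    if iterative_cutoff is None:
        return result
    for _ in range(max_iterations):
        moved = result.transform(mob_xyz)
        keep = np.linalg.norm(moved - ref_xyz, axis=1) <= iterative_cutoff
        if keep.all():
            break
        if keep.sum() < 3:
            raise InsufficientDataError(
                "iterative cutoff removed too many atom pairs"
            )
        ref_xyz = ref_xyz[keep]
        mob_xyz = mob_xyz[keep]
        matched = [m for m, k in zip(matched, keep) if k]
        result = superpose(ref_xyz, mob_xyz, matched)
    return result
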