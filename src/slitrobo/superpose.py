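"""Least-squares rigid superposition (Kabsch algorithm).

Atoms are paired by (chain id, residue number, atom name) identity --
wild-type and mutant models share numbering, so no sequence alignment is
attempted.  The optimal rotation is obtained from the SVD of the
covariance matrix with the usual reflection guard (determinant sign flip),
so the returned transform is always a proper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdb import StructureModel


@dataclass(frozen=True)
class SuperpositionResult:
    rmsd: float
    n_paired: int
    rotation: np.ndarray     # 3x3, det +1; maps centred mobile onto reference
    translation: np.ndarray  # 3-vector

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def kabsch(reference: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape or reference.ndim != 2 or reference.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(reference) < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    ref_centroid = reference.mean(axis=0)
    mob_centroid = mobile.mean(axis=0)
    p = reference - ref_centroid
    q = mobile - mob_centroid
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_centroid - rotation @ mob_centroid
    moved = q @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return rotation, translation, rmsd


def paired_coordinates(
    reference: StructureModel,
    mobile: StructureModel,
    atom_filter: str | None = "CA",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Coordinates of atoms shared by both models, in reference order.

    ``atom_filter`` restricts the pairing to one atom name (CA by default);
    ``None`` pairs every atom present in both models.
    """
    mobile_index = {a.atom_key: i for i, a in enumerate(mobile.atoms)}
    ref_points, mob_points = [], []
    for i, atom in enumerate(reference.atoms):
        if atom_filter is not None and atom.name != atom_filter:
            continue
        j = mobile_index.get(atom.atom_key)
        if j is None:
            continue
        ref_points.append(reference.coords[i])
        mob_points.append(mobile.coords[j])
    return np.array(ref_points), np.array(mob_points), len(ref_points)


def superpose_rmsd(
    reference: StructureModel,
    mobile: StructureModel,
    atom_filter: str | None = "CA",
) -> SuperpositionResult:
    """RMSD after optimal rigid superposition of paired atoms."""
    ref_points, mob_points, n = paired_coordinates(reference, mobile, atom_filter)
    if n < 3:
        raise ValueError(f"only {n} paired atoms; need at least 3")
    rotation, translation, rmsd = kabsch(ref_points, mob_points)
    return SuperpositionResult(
        rmsd=rmsd, n_paired=n, rotation=rotation, translation=translation)
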