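"""Shrake-Rupley solvent-accessible surface area and accessibility orbits.

Each heavy atom is covered with a deterministic quasi-uniform point shell
(Fibonacci sphere) at radius r_vdw + probe; points falling inside any
neighbouring atom's expanded sphere are occluded, and the accessible
fraction scales the sphere area.  Residue ASA is the sum over its heavy
atoms; relative ASA divides by a theoretical residue-type maximum (the
Tien et al. set), and the "orbit" is the decile bin (1-10) of the relative
accessibility clipped to [0, 1] -- a formalisation of the concentric rings
of spiral accessibility plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pdb import StructureModel, vdw_radius
from .records import AsaShift

#: Theoretical maximum ASA per residue type (Tien et al. 2013), A^2.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: Relative-accessibility width of one orbit (decile binning).
ORBIT_WIDTH = 0.1
#: Relative-accessibility change regarded as a shift within the same orbit.
INTRA_ORBIT_TOLERANCE = 0.05


@dataclass(frozen=True)
class ResidueASA:
    chain_id: str
    res_seq: int
    res_name: str
    asa: float
    rel_asa: float
    orbit: int

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.res_seq)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def orbit_bin(rel_asa: float) -> int:
    """Decile orbit (1-10) of a relative accessibility; total on [0, inf)."""
    clipped = min(max(rel_asa, 0.0), 1.0)
    return min(int(clipped / ORBIT_WIDTH) + 1, 10)


def atom_asa(
    model: StructureModel,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = DEFAULT_PROBE,
) -> np.ndarray:
    """Per-atom accessible surface area (zeros for hydrogens)."""
    if n_points < 32:
        raise ValueError(f"n_points must be >= 32, got {n_points}")
    heavy = model.heavy_indices()
    coords = model.coords[heavy]
    radii = np.array(
        [vdw_radius(model.atoms[i].element) + probe for i in heavy])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    out = np.zeros(len(model.atoms))
    max_radius = radii.max()
    for k, (center, radius) in enumerate(zip(coords, radii)):
        neighbours = [
            m for m in tree.query_ball_point(center, radius + max_radius)
            if m != k
            and np.linalg.norm(coords[m] - center) < radius + radii[m]
        ]
        points = center + radius * sphere
        accessible = np.ones(n_points, dtype=bool)
        for m in neighbours:
            accessible &= (
                np.linalg.norm(points - coords[m], axis=1) >= radii[m])
            if not accessible.any():
                break
        fraction = accessible.mean()
        out[heavy[k]] = fraction * 4.0 * np.pi * radius ** 2
    return out


def compute_asa(
    model: StructureModel,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = DEFAULT_PROBE,
) -> list[ResidueASA]:
    """Residue-level ASA, relative ASA and accessibility orbit."""
    per_atom = atom_asa(model, n_points=n_points, probe=probe)
    results = []
    for key, indices in model.residue_atoms().items():
        res_name = model.atoms[indices[0]].res_name
        asa = float(per_atom[indices].sum())
        reference = MAX_ASA.get(res_name)
        rel = asa / reference if reference else 0.0
        results.append(ResidueASA(
            chain_id=key[0], res_seq=key[1], res_name=res_name,
            asa=asa, rel_asa=rel, orbit=orbit_bin(rel)))
    return results


def classify_asa_shift(wt: ResidueASA, mut: ResidueASA) -> AsaShift:
    """Orbit shift of a mutated residue relative to its wild-type state.

    A different orbit bin is an inter-orbit shift; the same bin with a
    relative-accessibility change above the tolerance is an intra-orbit
    shift; anything smaller is no shift.
    """
    if wt.residue_key != mut.residue_key:
        raise ValueError(
            f"residue mismatch: {wt.residue_key} vs {mut.residue_key}")
    if wt.orbit != mut.orbit:
        return AsaShift.INTER_ORBIT
    if abs(wt.rel_asa - mut.rel_asa) > INTRA_ORBIT_TOLERANCE:
        return AsaShift.INTRA_ORBIT
    return AsaShift.NONE
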