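"""Atomic structure container and PDB input/output.

A :class:`StructureModel` is a flat, ordered list of atoms with a derived
covalent bond graph (distance criterion on covalent radii).  Reading of
standard PDB files is delegated to gemmi; writing uses the fixed-column
ATOM record layout.  Waters are always excluded; other heteroatoms are
skipped by default; for alternate locations the first-listed conformer of
each atom is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

#: Van der Waals radii (Bondi set), element-keyed, in angstroms.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: Single-bond covalent radii used for bond-graph inference, in angstroms.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}

#: Tolerance added to the covalent-radius sum when inferring bonds.
BOND_TOLERANCE = 0.45

WATER_NAMES = {"HOH", "WAT", "DOD"}


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"no van der Waals radius for element {element!r}") from None


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    res_seq: int
    chain_id: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.res_seq)

    @property
    def atom_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.name)


class StructureModel:
    """Ordered atom list with coordinate array and covalent bond graph."""

    def __init__(self, atoms: list[AtomRecord]):
        if not atoms:
            raise ValueError("a structure model must contain at least one atom")
        seen: set[tuple[str, int, str, str]] = set()
        for atom in atoms:
            key = (atom.chain_id, atom.res_seq, atom.name, atom.alt_loc)
            if key in seen:
                raise ValueError(f"duplicate atom {key} after alt-loc filtering")
            seen.add(key)
        self.atoms = atoms
        self.coords = np.array([[a.x, a.y, a.z] for a in atoms])
        self.chains: set[str] = {a.chain_id for a in atoms}
        self._bonds: list[set[int]] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def has_hydrogens(self) -> bool:
        return any(a.element.upper() == "H" for a in self.atoms)

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"],
            dtype=int)

    def residue_atoms(self) -> dict[tuple[str, int], list[int]]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            out.setdefault(atom.residue_key, []).append(i)
        return out

    @property
    def bonds(self) -> list[set[int]]:
        """Adjacency sets of the inferred covalent bond graph."""
        if self._bonds is None:
            n = len(self.atoms)
            adjacency: list[set[int]] = [set() for _ in range(n)]
            radii = np.array([
                COVALENT_RADII.get(a.element.upper(), 0.77) for a in self.atoms])
            tree = cKDTree(self.coords)
            cutoff = 2.0 * radii.max() + BOND_TOLERANCE
            for i, j in tree.query_pairs(cutoff):
                d = float(np.linalg.norm(self.coords[i] - self.coords[j]))
                if 0.3 < d <= radii[i] + radii[j] + BOND_TOLERANCE:
                    adjacency[i].add(j)
                    adjacency[j].add(i)
            self._bonds = adjacency
        return self._bonds

    def bond_separation_within(self, i: int, j: int, max_bonds: int = 2) -> bool:
        """True when atoms i, j are within ``max_bonds`` covalent bonds."""
        if i == j:
            return True
        frontier = {i}
        visited = {i}
        for _ in range(max_bonds):
            frontier = {k for f in frontier for k in self.bonds[f]} - visited
            if j in frontier:
                return True
            visited |= frontier
        return False

    def attached_hydrogens(self, i: int) -> list[int]:
        return [j for j in self.bonds[i] if self.atoms[j].element.upper() == "H"]


def parse_structure(
    path: str | Path, keep_hetatm: bool = False
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    The first model is used; waters are excluded; non-water HETATM records
    are skipped unless ``keep_hetatm``; the first-listed alternate location
    of each atom is kept; insertion codes are unsupported and raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[AtomRecord] = []
    seen: set[tuple[str, int, str]] = set()
    serial = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.name in WATER_NAMES:
                    continue
                if residue.het_flag == "H" and not keep_hetatm:
                    continue
                if residue.seqid.icode not in ("", " "):
                    raise ValueError(
                        f"insertion codes are unsupported "
                        f"({chain.name} {residue.seqid.num}{residue.seqid.icode})")
                for atom in residue:
                    key = (chain.name, residue.seqid.num, atom.name)
                    if key in seen:
                        continue  # keep the first-listed alt-loc only
                    seen.add(key)
                    serial += 1
                    atoms.append(AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        alt_loc=atom.altloc if atom.altloc else "",
                        res_name=residue.name,
                        res_seq=residue.seqid.num,
                        chain_id=chain.name,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        occupancy=atom.occ,
                    ))
        break  # first model only
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return StructureModel(atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model in fixed-column PDB ATOM format."""
    lines = []
    for atom in model.atoms:
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        lines.append(
            f"ATOM  {atom.serial:>5d} {name}{atom.alt_loc or ' '}"
            f"{atom.res_name:<3s} {atom.chain_id}{atom.res_seq:>4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          "
            f"{atom.element.upper():>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
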