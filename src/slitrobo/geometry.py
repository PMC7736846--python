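"""Geometric detectors for hydrogen bonds, steric clashes and interfaces.

These engines compute, directly from coordinates, the structural
comparisons that dedicated structure-analysis servers usually provide.
Criteria follow widespread conventions and are configurable:

* hydrogen bond: donor/acceptor heavy atoms (N, O) within 3.5 A; when the
  donor carries an explicit hydrogen the D-H...A angle must be >= 120 deg;
  without hydrogens in the model, protonation is assumed and any N/O may
  donate.  Intra-residue pairs and atoms within two covalent bonds are
  excluded (the adjacent-residue O(i)..N(i+1) pair is a 1-3 contact).
* steric clash: non-bonded heavy-atom pairs (1-2 and 1-3 relations
  excluded) whose van der Waals overlap r_i + r_j - d is >= 0.4 A.
* salt bridge: side-chain nitrogen of Lys/Arg/His within 4.0 A of a
  side-chain carboxylate oxygen of Asp/Glu, counted once per residue pair.
* non-bonded contact: any remaining cross-chain heavy-atom pair within
  3.9 A that is neither a hydrogen bond nor part of a salt bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .pdb import StructureModel, vdw_radius
from .records import AsaShift, StructureChangeOutcomes


@dataclass(frozen=True)
class GeometryConfig:
    hbond_distance: float = 3.5       # donor-acceptor heavy-atom cutoff, A
    hbond_angle: float = 120.0        # minimum D-H...A angle, degrees
    clash_overlap: float = 0.4        # minimum vdW overlap, A
    saltbridge_distance: float = 4.0  # N...O cutoff, A
    contact_distance: float = 3.9     # non-bonded contact cutoff, A
    hbond_length_change: float = 0.1  # bond-length delta regarded as a change, A


DEFAULT_GEOMETRY = GeometryConfig()


@dataclass(frozen=True)
class HydrogenBond:
    donor: int      # atom index of the donor heavy atom
    acceptor: int   # atom index of the acceptor heavy atom
    distance: float

    def pair(self) -> frozenset[int]:
        return frozenset((self.donor, self.acceptor))


@dataclass(frozen=True)
class Clash:
    i: int
    j: int
    overlap: float


@dataclass(frozen=True)
class InterfaceProfile:
    chain_pair: tuple[str, str]
    n_hbonds: int
    n_nonbonded_contacts: int
    n_salt_bridges: int


_BASIC_SC_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_SC_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosine = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def _can_donate(model: StructureModel, i: int, j: int,
                config: GeometryConfig) -> bool:
    """Can atom i donate a hydrogen bond to acceptor j?"""
    hydrogens = model.attached_hydrogens(i)
    if not model.has_hydrogens:
        return True  # assumed protonation
    if not hydrogens:
        return False
    return any(
        _angle(model.coords[i], model.coords[h], model.coords[j])
        >= config.hbond_angle
        for h in hydrogens)


def detect_hbonds(
    model: StructureModel,
    chain_pair: tuple[str, str] | None = None,
    config: GeometryConfig = DEFAULT_GEOMETRY,
) -> list[HydrogenBond]:
    """All donor-acceptor pairs satisfying the distance/angle criteria.

    Each unordered heavy-atom pair is reported once; when both directions
    qualify, the donor assignment of the first qualifying direction (lower
    atom index first) is kept.
    """
    candidates = [
        i for i, a in enumerate(model.atoms) if a.element.upper() in ("N", "O")]
    if chain_pair is not None:
        wanted = set(chain_pair)
        candidates = [i for i in candidates if model.atoms[i].chain_id in wanted]
    if not candidates:
        return []
    idx = np.array(candidates)
    tree = cKDTree(model.coords[idx])
    bonds: list[HydrogenBond] = []
    for ii, jj in sorted(tree.query_pairs(config.hbond_distance)):
        i, j = int(idx[ii]), int(idx[jj])
        ai, aj = model.atoms[i], model.atoms[j]
        if ai.residue_key == aj.residue_key:
            continue
        if chain_pair is not None and \
                {ai.chain_id, aj.chain_id} != set(chain_pair):
            continue
        if model.bond_separation_within(i, j, max_bonds=2):
            continue
        distance = float(np.linalg.norm(model.coords[i] - model.coords[j]))
        if _can_donate(model, i, j, config):
            bonds.append(HydrogenBond(donor=i, acceptor=j, distance=distance))
        elif _can_donate(model, j, i, config):
            bonds.append(HydrogenBond(donor=j, acceptor=i, distance=distance))
    return bonds


def detect_clashes(
    model: StructureModel, config: GeometryConfig = DEFAULT_GEOMETRY
) -> list[Clash]:
    """Non-bonded heavy-atom pairs with vdW overlap >= the threshold,
    sorted by overlap descending."""
    heavy = model.heavy_indices()
    radii = np.array([vdw_radius(model.atoms[i].element) for i in heavy])
    tree = cKDTree(model.coords[heavy])
    clashes: list[Clash] = []
    max_cutoff = 2.0 * radii.max() - config.clash_overlap
    for ii, jj in tree.query_pairs(max_cutoff):
        i, j = int(heavy[ii]), int(heavy[jj])
        if model.bond_separation_within(i, j, max_bonds=2):
            continue
        d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
        overlap = float(radii[ii] + radii[jj] - d)
        if overlap >= config.clash_overlap:
            clashes.append(Clash(i=min(i, j), j=max(i, j), overlap=overlap))
    return sorted(clashes, key=lambda c: (-c.overlap, c.i, c.j))


def detect_salt_bridges(
    model: StructureModel,
    chain_pair: tuple[str, str] | None = None,
    config: GeometryConfig = DEFAULT_GEOMETRY,
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs forming salt bridges (basic N vs carboxylate O).

    Counted once per residue pair regardless of how many atom pairs are in
    range; with ``chain_pair`` only cross-chain bridges are reported.
    """
    basic, acidic = [], []
    for i, a in enumerate(model.atoms):
        if a.name in _BASIC_SC_N.get(a.res_name, ()):
            basic.append(i)
        elif a.name in _ACIDIC_SC_O.get(a.res_name, ()):
            acidic.append(i)
    pairs: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    for i in basic:
        for j in acidic:
            ai, aj = model.atoms[i], model.atoms[j]
            if chain_pair is not None and {ai.chain_id, aj.chain_id} != set(chain_pair):
                continue
            if ai.residue_key == aj.residue_key:
                continue
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            if d <= config.saltbridge_distance:
                pairs.add((ai.residue_key, aj.residue_key))
    return sorted(pairs)


def interface_profile(
    model: StructureModel,
    chain_pair: tuple[str, str],
    config: GeometryConfig = DEFAULT_GEOMETRY,
) -> InterfaceProfile:
    """Cross-chain hydrogen bonds, non-bonded contacts and salt bridges."""
    a, b = chain_pair
    for chain in chain_pair:
        if chain not in model.chains:
            raise ValueError(f"chain {chain!r} absent from model")

    def crosses(i: int, j: int) -> bool:
        return {model.atoms[i].chain_id, model.atoms[j].chain_id} == {a, b}

    hbonds = [hb for hb in detect_hbonds(model, config=config)
              if crosses(hb.donor, hb.acceptor)]
    hbond_pairs = {hb.pair() for hb in hbonds}
    bridges = detect_salt_bridges(model, chain_pair, config)
    bridge_residues = {frozenset(p) for p in bridges}

    heavy = model.heavy_indices()
    tree = cKDTree(model.coords[heavy])
    n_contacts = 0
    for ii, jj in tree.query_pairs(config.contact_distance):
        i, j = int(heavy[ii]), int(heavy[jj])
        if not crosses(i, j):
            continue
        if frozenset((i, j)) in hbond_pairs:
            continue
        ri = model.atoms[i].residue_key
        rj = model.atoms[j].residue_key
        if frozenset((ri, rj)) in bridge_residues:
            continue
        n_contacts += 1
    return InterfaceProfile(
        chain_pair=(a, b),
        n_hbonds=len(hbonds),
        n_nonbonded_contacts=n_contacts,
        n_salt_bridges=len(bridges),
    )


def _site_hbond_signature(
    model: StructureModel, site: tuple[str, int], config: GeometryConfig
) -> dict[tuple[tuple[str, int, str], tuple[str, int, str]], float]:
    out = {}
    for hb in detect_hbonds(model, config=config):
        keys = (model.atoms[hb.donor].atom_key, model.atoms[hb.acceptor].atom_key)
        if any(k[:2] == site for k in keys):
            out[tuple(sorted(keys))] = hb.distance
    return out


def _site_clash_signature(
    model: StructureModel, site: tuple[str, int], config: GeometryConfig
) -> set[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    out = set()
    for clash in detect_clashes(model, config):
        keys = (model.atoms[clash.i].atom_key, model.atoms[clash.j].atom_key)
        if any(k[:2] == site for k in keys):
            out.add(tuple(sorted(keys)))
    return out


def compare_wt_mut(
    wt: StructureModel,
    mut: StructureModel,
    site: tuple[str, int],
    config: GeometryConfig = DEFAULT_GEOMETRY,
    n_points: int = 960,
) -> StructureChangeOutcomes:
    """Structure-change outcomes of a mutant model at a residue site.

    The hydrogen-bond outcome changes when the set of bonds involving the
    site differs in partners or when any shared bond's length moved by more
    than ``hbond_length_change``; the clash outcome when the clash set
    involving the site differs; the accessibility outcome is the orbit
    shift of the site residue (wild type and mutant are assumed to share
    chain/residue numbering).
    """
    from .sasa import classify_asa_shift, compute_asa  # local: avoid cycle

    for model in (wt, mut):
        if site not in model.residue_atoms():
            raise ValueError(f"site {site} absent from model")

    hb_wt = _site_hbond_signature(wt, site, config)
    hb_mut = _site_hbond_signature(mut, site, config)
    hbond_changed = set(hb_wt) != set(hb_mut) or any(
        abs(hb_wt[k] - hb_mut[k]) > config.hbond_length_change for k in hb_wt)

    clash_changed = (_site_clash_signature(wt, site, config)
                     != _site_clash_signature(mut, site, config))

    asa_wt = {r.residue_key: r for r in compute_asa(wt, n_points=n_points)}
    asa_mut = {r.residue_key: r for r in compute_asa(mut, n_points=n_points)}
    shift = classify_asa_shift(asa_wt[site], asa_mut[site])

    return StructureChangeOutcomes(
        hbond_changed=hbond_changed,
        clash_changed=clash_changed,
        asa_shift=shift,
    )
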