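"""Deliberately naive reference implementations used as independent oracles.

Everything here is written as direct all-pairs loops with its own covalent
graph construction and breadth-first bond counting, so the production
KD-tree-based detectors are checked against a separate code path that
shares only the published criteria.
"""

from __future__ import annotations

import numpy as np

from slitrobo.pdb import BOND_TOLERANCE, COVALENT_RADII, VDW_RADII, StructureModel


def naive_bond_graph(model: StructureModel) -> list[set[int]]:
    n = len(model.atoms)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ri = COVALENT_RADII.get(model.atoms[i].element.upper(), 0.77)
            rj = COVALENT_RADII.get(model.atoms[j].element.upper(), 0.77)
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            if 0.3 < d <= ri + rj + BOND_TOLERANCE:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def naive_within_bonds(adj: list[set[int]], i: int, j: int, k: int) -> bool:
    seen, frontier = {i}, {i}
    for _ in range(k):
        frontier = {b for a in frontier for b in adj[a]} - seen
        if j in frontier:
            return True
        seen |= frontier
    return False


def _angle_deg(a, b, c) -> float:
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1, 1))))


def naive_hbond_pairs(
    model: StructureModel,
    max_distance: float = 3.5,
    min_angle: float = 120.0,
) -> set[frozenset[int]]:
    adj = naive_bond_graph(model)
    has_h = any(a.element.upper() == "H" for a in model.atoms)
    pairs: set[frozenset[int]] = set()
    nos = [i for i, a in enumerate(model.atoms) if a.element.upper() in ("N", "O")]

    def donates(i: int, j: int) -> bool:
        hydrogens = [h for h in adj[i] if model.atoms[h].element.upper() == "H"]
        if not has_h:
            return True
        if not hydrogens:
            return False
        return any(
            _angle_deg(model.coords[i], model.coords[h], model.coords[j]) >= min_angle
            for h in hydrogens)

    for x, i in enumerate(nos):
        for j in nos[x + 1:]:
            if model.atoms[i].residue_key == model.atoms[j].residue_key:
                continue
            if naive_within_bonds(adj, i, j, 2):
                continue
            if float(np.linalg.norm(model.coords[i] - model.coords[j])) > max_distance:
                continue
            if donates(i, j) or donates(j, i):
                pairs.add(frozenset((i, j)))
    return pairs


def naive_clash_pairs(
    model: StructureModel, min_overlap: float = 0.4
) -> set[tuple[int, int]]:
    adj = naive_bond_graph(model)
    heavy = [i for i, a in enumerate(model.atoms) if a.element.upper() != "H"]
    out = set()
    for x, i in enumerate(heavy):
        for j in heavy[x + 1:]:
            if naive_within_bonds(adj, i, j, 2):
                continue
            ri = VDW_RADII[model.atoms[i].element.upper()]
            rj = VDW_RADII[model.atoms[j].element.upper()]
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            if ri + rj - d >= min_overlap:
                out.add((i, j))
    return out


def naive_salt_bridges(
    model: StructureModel, chain_pair=None, max_distance: float = 4.0
) -> set[frozenset]:
    basic = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
             "HIS": {"ND1", "NE2"}}
    acidic = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
    out = set()
    for i, ai in enumerate(model.atoms):
        if ai.name not in basic.get(ai.res_name, ()):
            continue
        for j, aj in enumerate(model.atoms):
            if aj.name not in acidic.get(aj.res_name, ()):
                continue
            if ai.residue_key == aj.residue_key:
                continue
            if chain_pair is not None and \
                    {ai.chain_id, aj.chain_id} != set(chain_pair):
                continue
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            if d <= max_distance:
                out.add(frozenset((ai.residue_key, aj.residue_key)))
    return out


def naive_interface_counts(
    model: StructureModel, chain_pair, contact_distance: float = 3.9
) -> tuple[int, int, int]:
    """(n_hbonds, n_contacts, n_salt_bridges) across the chain pair."""
    a, b = chain_pair
    hbonds = {
        p for p in naive_hbond_pairs(model)
        if {model.atoms[i].chain_id for i in p} == {a, b}}
    bridges = naive_salt_bridges(model, chain_pair)
    heavy = [i for i, at in enumerate(model.atoms) if at.element.upper() != "H"]
    n_contacts = 0
    for x, i in enumerate(heavy):
        for j in heavy[x + 1:]:
            ai, aj = model.atoms[i], model.atoms[j]
            if {ai.chain_id, aj.chain_id} != {a, b}:
                continue
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            if d > contact_distance:
                continue
            if frozenset((i, j)) in hbonds:
                continue
            if frozenset((ai.residue_key, aj.residue_key)) in bridges:
                continue
            n_contacts += 1
    return len(hbonds), n_contacts, len(bridges)


def monte_carlo_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    n_samples: int = 40000,
    seed: int = 0,
) -> np.ndarray:
    """Random-direction surface sampling (independent of the deterministic
    Fibonacci point shell used by the implementation)."""
    rng = np.random.default_rng(seed)
    out = np.zeros(len(coords))
    for k, (center, radius) in enumerate(zip(coords, radii)):
        directions = rng.normal(size=(n_samples, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        points = center + radius * directions
        accessible = np.ones(n_samples, dtype=bool)
        for m, (other, r_other) in enumerate(zip(coords, radii)):
            if m == k:
                continue
            accessible &= np.linalg.norm(points - other, axis=1) >= r_other
        out[k] = accessible.mean() * 4.0 * np.pi * radius ** 2
    return out
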