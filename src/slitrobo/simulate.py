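"""Synthetic inputs for every pipeline stage.

Three generators, all deterministic for a fixed seed, emulate the three
kinds of input the pipeline consumes:

* predictor-annotation tables with configurable per-tool damaging-label
  probabilities and a set of planted variants designed to pass both
  prioritisation stages;
* toy coordinate models -- ideal-geometry poly-alanine helix dimers built
  from internal coordinates, with a single planted structural perturbation
  (broken hydrogen bond, steric clash, burial or exposure of a site);
* docking-parameter tables with planted disruptor complexes (weakening
  changes on at least six of the seven parameters) against a near-neutral
  background.

A single global seed governs all generators through a documented splitting
scheme (stream ids 1, 2, 3 appended to the seed), so stages can be tested
independently yet reproducibly.  Default probabilities follow the outcome
fractions reported for the real ROBO1/ROBO4/SLIT2 variant cohorts; the
generators make no attempt to mimic real mutation spectra or predictor
correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pdb import AtomRecord, StructureModel
from .records import AsaShift

_ANNOTATION_STREAM = 1
_COMPLEX_STREAM = 2
_DOCK_STREAM = 3

PLANTED_LABELS = ("none", "remove_hbond", "add_clash", "bury_site", "expose_site")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # annotation table
    n_variants: int = 100
    n_planted: int = 10
    p_provean_deleterious: float = 0.45
    p_sift_damaging: float = 0.60
    p_polyphen2_possibly: float = 0.15
    p_polyphen2_probably: float = 0.45
    p_snps_go_disease: float = 0.30
    p_imutant_decrease: float = 0.85
    p_fathmm_cancer: float = 0.02
    p_hbond_change: float = 0.55
    p_clash_change: float = 0.20
    p_asa_shift: float = 0.30
    # toy complexes
    helix_length: int = 12
    site_res_seq: int = 6
    # docking table
    category_sizes: dict[str, int] = field(
        default_factory=lambda: {"RECEPTOR:LIGAND": 20})
    n_planted_disruptors: int = 5
    energy_noise: float = 0.05   # kcal/mol
    count_jitter: int = 0        # +/- jitter on interaction counts
    rmsd_noise: float = 0.05     # angstroms

    def __post_init__(self) -> None:
        for name in ("p_provean_deleterious", "p_sift_damaging",
                     "p_polyphen2_possibly", "p_polyphen2_probably",
                     "p_snps_go_disease", "p_imutant_decrease",
                     "p_fathmm_cancer", "p_hbond_change", "p_clash_change",
                     "p_asa_shift"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.p_polyphen2_possibly + self.p_polyphen2_probably > 1.0:
            raise ValueError("polyphen2 class probabilities exceed 1")
        if self.n_variants < 0 or self.n_planted < 0:
            raise ValueError("variant counts must be >= 0")
        if any(n < 0 for n in self.category_sizes.values()):
            raise ValueError("category sizes must be >= 0")


# --------------------------------------------------------------------------
# annotation tables

_AA = "ACDEFGHIKLMNPQRSTVWY"
_GENES = ("GENE1", "GENE2", "GENE3")


def generate_annotation_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotation table plus ground truth.

    The first ``n_planted`` variants carry the worst outcome of every tool
    and all three structure changes (combined total 10); the remaining
    background draws each outcome independently from the configured
    damaging probabilities.  Ground truth records the planted flag per
    variant.
    """
    rng = np.random.default_rng([config.seed, _ANNOTATION_STREAM])
    rows, truth = [], []
    for k in range(config.n_variants):
        planted = k < config.n_planted
        gene = _GENES[k % len(_GENES)]
        position = 10 + k
        ref = _AA[int(rng.integers(len(_AA)))]
        alt_choices = [a for a in _AA if a != ref]
        alt = alt_choices[int(rng.integers(len(alt_choices)))]
        dataset = "lung" if rng.random() < 0.5 else "non_lung"
        region = ("within_docking_domain" if rng.random() < 0.5
                  else "outside_docking_domain")
        if planted:
            outcomes = dict(
                provean="Deleterious", sift="Damaging",
                polyphen2="Probably_damaging", snps_go="Disease",
                imutant="Decrease_stability", fathmm="Cancer_associated",
                hbond_changed="true", clash_changed="true",
                asa_shift="inter_orbit")
        else:
            u = rng.random(9)
            pp = ("Possibly_damaging" if u[2] < config.p_polyphen2_possibly
                  else "Probably_damaging"
                  if u[2] < config.p_polyphen2_possibly + config.p_polyphen2_probably
                  else "Benign")
            outcomes = dict(
                provean="Deleterious" if u[0] < config.p_provean_deleterious else "Neutral",
                sift="Damaging" if u[1] < config.p_sift_damaging else "Tolerated",
                polyphen2=pp,
                snps_go="Disease" if u[3] < config.p_snps_go_disease else "Neutral",
                imutant="Decrease_stability" if u[4] < config.p_imutant_decrease
                        else "Increase_stability",
                fathmm="Cancer_associated" if u[5] < config.p_fathmm_cancer
                       else "Passenger",
                hbond_changed="true" if u[6] < config.p_hbond_change else "false",
                clash_changed="true" if u[7] < config.p_clash_change else "false",
                asa_shift="inter_orbit" if u[8] < config.p_asa_shift else "none")
        change = f"{ref}{position}{alt}"
        rows.append({"gene": gene, "protein_change": change,
                     "dataset": dataset, "region": region, **outcomes})
        truth.append({"gene": gene, "protein_change": change, "planted": planted})
    columns = ["gene", "protein_change", "dataset", "region",
               "provean", "sift", "polyphen2", "snps_go", "imutant", "fathmm",
               "hbond_changed", "clash_changed", "asa_shift"]
    return (pd.DataFrame(rows, columns=columns),
            pd.DataFrame(truth, columns=["gene", "protein_change", "planted"]))


# --------------------------------------------------------------------------
# toy coordinate models

_BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329,
                 "C-O": 1.231, "CA-CB": 1.530, "N-H": 1.010}
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-length * math.cos(ang),
                  length * math.sin(ang) * math.cos(tor),
                  length * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_helix(
    n_residues: int,
    chain_id: str = "A",
    start_res_seq: int = 1,
    with_hydrogens: bool = True,
) -> list[AtomRecord]:
    """Ideal-geometry poly-alanine alpha helix built from internal coordinates.

    Backbone torsions are the canonical helix values (phi -57, psi -47);
    each residue carries N, (amide H), CA, CB, C, O.
    """
    backbone: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_LENGTHS["N-CA"], 0.0, 0.0])
    c0 = _place(np.array([0.0, -1.0, 0.0]), n0, ca0,
                _BOND_LENGTHS["CA-C"], 111.2, 60.0)
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = backbone[-1]
        n_next = _place(prev["N"], prev["CA"], prev["C"],
                        _BOND_LENGTHS["C-N"], 116.2, _PSI)
        ca_next = _place(prev["CA"], prev["C"], n_next,
                         _BOND_LENGTHS["N-CA"], 121.7, _OMEGA)
        c_next = _place(prev["C"], n_next, ca_next,
                        _BOND_LENGTHS["CA-C"], 111.2, _PHI)
        backbone.append({"N": n_next, "CA": ca_next, "C": c_next})

    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, element: str, pos: np.ndarray, res_seq: int) -> None:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element, alt_loc="",
            res_name="ALA", res_seq=res_seq, chain_id=chain_id,
            x=float(pos[0]), y=float(pos[1]), z=float(pos[2])))

    for i, res in enumerate(backbone):
        res_seq = start_res_seq + i
        add("N", "N", res["N"], res_seq)
        if with_hydrogens and i > 0:
            prev_c = backbone[i - 1]["C"]
            u = (res["N"] - prev_c) / np.linalg.norm(res["N"] - prev_c)
            v = (res["N"] - res["CA"]) / np.linalg.norm(res["N"] - res["CA"])
            h_dir = (u + v) / np.linalg.norm(u + v)
            add("H", "H", res["N"] + _BOND_LENGTHS["N-H"] * h_dir, res_seq)
        add("CA", "C", res["CA"], res_seq)
        cb = _place(res["C"], res["N"], res["CA"],
                    _BOND_LENGTHS["CA-CB"], 110.5, 122.5)
        add("CB", "C", cb, res_seq)
        add("C", "C", res["C"], res_seq)
        if i + 1 < len(backbone):
            o = _place(res["N"], res["CA"], res["C"],
                       _BOND_LENGTHS["C-O"], 120.8, _PSI + 180.0)
        else:
            o = _place(res["N"], res["CA"], res["C"],
                       _BOND_LENGTHS["C-O"], 120.8, 133.0)
        add("O", "O", o, res_seq)
    return atoms


def _translate(atoms: list[AtomRecord], shift: np.ndarray) -> list[AtomRecord]:
    return [replace(a, x=a.x + shift[0], y=a.y + shift[1], z=a.z + shift[2])
            for a in atoms]


def _renumber(atoms: list[AtomRecord], start_serial: int) -> list[AtomRecord]:
    return [replace(a, serial=start_serial + i) for i, a in enumerate(atoms)]


def _blocker_shell(
    model_atoms: list[AtomRecord],
    center: np.ndarray,
    radius: float = 4.5,
    min_clearance: float = 3.25,
    n_candidates: int = 60,
    chain_id: str = "X",
) -> list[AtomRecord]:
    """Carbon atoms on a sphere around ``center`` that stay clear of every
    heavy atom, used to occlude a site without clashing or hydrogen bonding."""
    from .sasa import fibonacci_sphere

    heavy = np.array([[a.x, a.y, a.z] for a in model_atoms
                      if a.element.upper() != "H"])
    points = center + radius * fibonacci_sphere(n_candidates)
    kept = []
    for p in points:
        if np.min(np.linalg.norm(heavy - p, axis=1)) >= min_clearance:
            kept.append(p)
    atoms = []
    for i, p in enumerate(kept):
        atoms.append(AtomRecord(
            serial=0, name=f"C{i + 1}", element="C", alt_loc="",
            res_name="UNK", res_seq=900 + i, chain_id=chain_id,
            x=float(p[0]), y=float(p[1]), z=float(p[2])))
    return atoms


def generate_toy_complex(
    config: SimulationConfig, planted: str = "none"
) -> tuple[StructureModel, StructureModel, dict]:
    """Wild-type/mutant helical dimer pair with one planted structural delta.

    Returns ``(wt, mut, truth)`` where ``truth`` records the site and the
    structure-change outcomes the construction guarantees (``None`` for
    outcomes the perturbation does not control).
    """
    if planted not in PLANTED_LABELS:
        raise ValueError(f"unknown planted label {planted!r}; "
                         f"choose from {PLANTED_LABELS}")
    n = config.helix_length
    site = ("A", config.site_res_seq)
    chain_a = build_helix(n, chain_id="A")
    chain_b = _translate(build_helix(n, chain_id="B"), np.array([14.0, 0.0, 0.0]))

    def model_of(atoms_a: list[AtomRecord], extra: list[AtomRecord]) -> StructureModel:
        return StructureModel(_renumber(atoms_a + chain_b + extra, 1))

    index = {(a.chain_id, a.res_seq, a.name): i for i, a in enumerate(chain_a)}
    truth: dict[str, object] = {"site": site, "planted": planted,
                                "hbond_changed": None, "clash_changed": None,
                                "asa_shift": None}

    if planted == "none":
        wt = model_of(list(chain_a), [])
        mut = model_of(list(chain_a), [])
        truth.update(hbond_changed=False, clash_changed=False,
                     asa_shift=AsaShift.NONE)
    elif planted == "remove_hbond":
        # rotate the amide hydrogen of the i+4 donor out of the bond plane so
        # the N(site+4)-H...O(site) angle drops below the cutoff; heavy atoms
        # are untouched, so clashes and accessibility are bitwise identical
        donor_res = config.site_res_seq + 4
        if donor_res > n:
            raise ValueError("helix too short to host the site's i+4 donor")
        atoms = list(chain_a)
        h_idx = index[("A", donor_res, "H")]
        n_pos = atoms[index[("A", donor_res, "N")]].position
        ca_pos = atoms[index[("A", donor_res, "CA")]].position
        c_prev = atoms[index[("A", donor_res - 1, "C")]].position
        normal = np.cross(n_pos - c_prev, n_pos - ca_pos)
        normal = normal / np.linalg.norm(normal)
        new_h = n_pos + _BOND_LENGTHS["N-H"] * normal
        atoms[h_idx] = replace(atoms[h_idx], x=float(new_h[0]),
                               y=float(new_h[1]), z=float(new_h[2]))
        wt = model_of(list(chain_a), [])
        mut = model_of(atoms, [])
        truth.update(hbond_changed=True, clash_changed=False,
                     asa_shift=AsaShift.NONE)
    elif planted == "add_clash":
        # pull the following residue's CB towards the site CB to a 0.6 A
        # van der Waals overlap (C-C contact at 2.8 A)
        atoms = list(chain_a)
        cb_site = atoms[index[site + ("CB",)]].position
        cb_next_idx = index[("A", config.site_res_seq + 1, "CB")]
        cb_next = atoms[cb_next_idx].position
        direction = (cb_next - cb_site) / np.linalg.norm(cb_next - cb_site)
        new_cb = cb_site + 2.8 * direction
        atoms[cb_next_idx] = replace(atoms[cb_next_idx], x=float(new_cb[0]),
                                     y=float(new_cb[1]), z=float(new_cb[2]))
        wt = model_of(list(chain_a), [])
        mut = model_of(atoms, [])
        truth.update(clash_changed=True, hbond_changed=False)
    elif planted in ("bury_site", "expose_site"):
        cb_site = chain_a[index[site + ("CB",)]].position
        shell = _blocker_shell(chain_a + chain_b, cb_site)
        if planted == "bury_site":
            wt = model_of(list(chain_a), [])
            mut = model_of(list(chain_a), shell)
        else:
            wt = model_of(list(chain_a), shell)
            mut = model_of(list(chain_a), [])
        truth.update(asa_shift=AsaShift.INTER_ORBIT)
    return wt, mut, truth


# --------------------------------------------------------------------------
# docking tables

#: Baseline wild-type:wild-type docking parameters of the synthetic complex.
_WT_BASELINE = {
    "free_energy": -12.0,      # kcal/mol
    "binding_affinity": -8.0,  # kcal/mol
    "solvation": -6.0,         # kcal/mol
    "hbond": 10,
    "vdw": 150,
    "saltbridge": 3,
}

#: Parameter deltas of a planted disruptor (weakening on all six) and of the
#: near-neutral background (mild strengthening-side drift).
_PLANTED_DELTA = {
    "free_energy": +2.0, "binding_affinity": +2.0, "solvation": +2.0,
    "hbond": -3, "vdw": -30, "saltbridge": -2,
}
_BACKGROUND_DELTA = {
    "free_energy": -0.5, "binding_affinity": -0.5, "solvation": -0.5,
    "hbond": +1, "vdw": +10, "saltbridge": +1,
}
_RMSD_PLANTED, _RMSD_BACKGROUND = 3.0, 0.5


def generate_dock_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Docking-parameter table (raw value pairs) plus ground-truth grades.

    In each category the first ``n_planted_disruptors`` complexes receive
    weakening-type changes on all six energy/count parameters and an RMSD
    far above the background, so at the default noise scales their grades
    are unambiguous; the background drifts mildly to the strengthening
    side.  Raising the noise scales lets classes flip and grades mix.
    """
    rng = np.random.default_rng([config.seed, _DOCK_STREAM])
    rows, truth = [], []
    for category, size in config.category_sizes.items():
        if size < 2:
            raise ValueError(
                f"category {category!r} needs >= 2 complexes for a mean-based "
                f"grading, got {size}")
        n_planted = min(config.n_planted_disruptors, size)
        receptor, _, ligand = category.partition(":")
        for k in range(size):
            planted = k < n_planted
            deltas = _PLANTED_DELTA if planted else _BACKGROUND_DELTA
            row = {
                "category": category,
                "variant": f"A{100 + k}V",
                "mutant_gene": receptor,
                "mutated_partner": receptor,
                "wild_type_partner": ligand or "PARTNER",
            }
            for param in ("free_energy", "binding_affinity", "solvation"):
                wt_v = _WT_BASELINE[param]
                mut_v = (wt_v + deltas[param]
                         + config.energy_noise * rng.standard_normal())
                row[f"{param}_wt"] = round(wt_v, 4)
                row[f"{param}_mut"] = round(mut_v, 4)
            for param in ("hbond", "vdw", "saltbridge"):
                wt_v = _WT_BASELINE[param]
                jitter = (int(rng.integers(-config.count_jitter,
                                           config.count_jitter + 1))
                          if config.count_jitter else 0)
                mut_v = max(wt_v + deltas[param] + jitter, 0)
                row[f"{param}_wt"] = wt_v
                row[f"{param}_mut"] = mut_v
            base_rmsd = _RMSD_PLANTED if planted else _RMSD_BACKGROUND
            row["rmsd"] = round(
                abs(base_rmsd + config.rmsd_noise * rng.standard_normal()), 4)
            rows.append(row)
            truth.append({"category": category, "variant": row["variant"],
                          "planted_disruptor": planted})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
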