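import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slitrobo.pdb import AtomRecord, StructureModel
from slitrobo.simulate import SimulationConfig, build_helix

settings.register_profile(
    "suite", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def helix_model() -> StructureModel:
    return StructureModel(build_helix(12))


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


def random_structure(
    rng: np.random.Generator,
    n_atoms: int = 120,
    two_chains: bool = True,
    box: float = 12.0,
    with_hydrogens: bool = False,
) -> StructureModel:
    """Random atom soup (optionally split into two chains) for oracle tests."""
    elements = ["C", "N", "O", "S"] + (["H"] if with_hydrogens else [])
    names = {"C": "C", "N": "N", "O": "O", "S": "SG", "H": "H"}
    atoms = []
    for i in range(n_atoms):
        element = elements[int(rng.integers(len(elements)))]
        chain = "B" if two_chains and i >= n_atoms // 2 else "A"
        pos = rng.uniform(0, box, size=3)
        if chain == "B":
            pos[0] += box * 0.6
        res_name, name = "UNK", f"{names[element]}{i}"
        # sprinkle in charged side-chain atoms so salt bridges can occur
        if element == "N" and rng.random() < 0.5:
            res_name, name = "LYS", "NZ"
        elif element == "O" and rng.random() < 0.5:
            res_name, name = "GLU", "OE1"
        atoms.append(AtomRecord(
            serial=i + 1, name=name, element=element,
            alt_loc="", res_name=res_name, res_seq=i + 1, chain_id=chain,
            x=float(pos[0]), y=float(pos[1]), z=float(pos[2])))
    return StructureModel(atoms)
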