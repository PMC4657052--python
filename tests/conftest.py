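import numpy as np
import pytest

from metox.io_data import Atom, MetSite, ProteinRecord, StructureModel
from metox.synthetic import SyntheticConfig, gen_proteome, gen_toy_structure, plant_env_bias


@pytest.fixture(scope="session")
def toy_proteome():
    """Small i.i.d. proteome with planted glutamate bias and labelled sites."""
    cfg = SyntheticConfig(n_proteins=120, mean_length=300, seed=42)
    proteome, sites = plant_env_bias(gen_proteome(cfg), cfg)
    return proteome, sites


@pytest.fixture(scope="session")
def toy_structure():
    """50-methionine lattice structure with known motif ground truth."""
    return gen_toy_structure(n_mets=50, motif_fraction=0.5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_protein(seq: str, pid: str = "P1") -> ProteinRecord:
    return ProteinRecord(id=pid, seq=seq)


def make_site(pid: str, pos: int, oxidized: bool = True) -> MetSite:
    return MetSite(protein_id=pid, pos=pos, oxidized=oxidized)


def single_atom_model(element: str = "S") -> StructureModel:
    return StructureModel(atoms=[Atom("A", 1, "MET", "SD", element, 0.0, 0.0, 0.0)])
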