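import numpy as np
import pytest

from ligscreen import chemio, synthkit


@pytest.fixture(scope="session")
def pocket():
    """Toy cage receptor with its search box, dock-typed."""
    system, box = synthkit.make_pocket_receptor(seed=0)
    chemio.assign_dock_types(system)
    return system, box


@pytest.fixture(scope="session")
def ligand_set(pocket):
    receptor, _ = pocket
    ligands = synthkit.make_ligand_set(synthkit.ToyScreenSpec(seed=0), receptor)
    for lig in ligands:
        chemio.assign_dock_types(lig.system)
    return ligands


def make_atom(element="C", coords=(0.0, 0.0, 0.0), **kw):
    return chemio.Atom.from_element(element, np.asarray(coords, float), **kw)


@pytest.fixture
def single_atom_system():
    return chemio.MolecularSystem([make_atom()], name="one")
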