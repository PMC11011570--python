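import numpy as np
import pytest

from metallotraj.model import AtomRecord, StructureModel


def make_atom(serial, name, resnum, resname="ALA", chain="A",
              pos=(0.0, 0.0, 0.0), element=None):
    return AtomRecord.create(serial, name, resnum, resname, chain, pos,
                             element=element)


def make_glycine(resnum=1, chain="A", offset=(0.0, 0.0, 0.0), serial0=1):
    """One glycine residue: backbone N, CA, C, O plus amide/alpha hydrogens."""
    offset = np.asarray(offset, dtype=float)
    template = {
        "N": (0.0, 0.0, 0.0), "CA": (1.45, 0.0, 0.0),
        "C": (2.0, 1.4, 0.0), "O": (1.3, 2.4, 0.0), "H": (-0.9, 0.6, 0.0),
    }
    atoms = []
    for i, (name, pos) in enumerate(template.items()):
        atoms.append(make_atom(serial0 + i, name, resnum, "GLY", chain,
                               np.array(pos) + offset))
    return atoms


@pytest.fixture
def glycine_model():
    return StructureModel(make_glycine(), title="single glycine")


@pytest.fixture
def two_chain_model():
    atoms = make_glycine(1, "A") + make_glycine(1, "B", offset=(10.0, 0.0, 0.0),
                                                serial0=6)
    return StructureModel(atoms, title="two chains")


@pytest.fixture
def rng():
    return np.random.default_rng(20240325)
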