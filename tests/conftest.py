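import numpy as np
import pytest

from zpocket.structure_io import AtomRecord, MolecularStructure
from zpocket.synthetic import ToyComplexSpec, make_toy_complex


def make_protein(ca_positions, names=None, chain="A"):
    """Single-CA-per-residue pseudo-protein from a list of coordinates."""
    ca_positions = np.asarray(ca_positions, dtype=float)
    names = names or ["ALA"] * len(ca_positions)
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", residue_name=names[i],
                   residue_id=(chain, i + 1, ""), coordinates=p, is_ca=True,
                   is_heavy=True)
        for i, p in enumerate(ca_positions)
    ]
    return MolecularStructure(atoms, role="protein")


def make_ligand(positions, resname="LIG"):
    positions = np.asarray(positions, dtype=float)
    atoms = [
        AtomRecord(serial=i + 1, name=f"C{i + 1}", element="C", residue_name=resname,
                   residue_id=("L", 1, ""), coordinates=p, is_ca=False, is_heavy=True)
        for i, p in enumerate(positions)
    ]
    return MolecularStructure(atoms, role="ligand")


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic carved-pocket complex shared across tests."""
    return make_toy_complex(ToyComplexSpec(seed=3))


@pytest.fixture(scope="session")
def toy_surface(toy_complex):
    from zpocket.surface import build_surface

    return build_surface(toy_complex.protein, seed=3)
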