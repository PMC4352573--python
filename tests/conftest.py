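import numpy as np
import pytest
from rdkit import Chem

from apfp3d.chem_io import Molecule3D, _from_rdkit


def mol_from_smiles(smiles: str, mol_id: str = "mol") -> Molecule3D:
    """Heavy-atom Molecule3D from SMILES (2D graph only, no coordinates)."""
    rd = Chem.MolFromSmiles(smiles)
    assert rd is not None, f"bad SMILES {smiles!r}"
    return _from_rdkit(rd, mol_id, has_3d=False)


@pytest.fixture
def benzene():
    return mol_from_smiles("c1ccccc1", "benzene")


@pytest.fixture
def ethanol():
    return mol_from_smiles("CCO", "ethanol")


@pytest.fixture
def pyridine():
    return mol_from_smiles("c1ccncc1", "pyridine")


@pytest.fixture
def tetrahedron():
    """Regular tetrahedron of 4 carbons, edge sqrt(8)."""
    coords = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                      dtype=float)
    bonds = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]
    return Molecule3D("tet", ["C"] * 4, coords, bonds, [0] * 4)
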