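"""Shared fixtures: tiny PDB text fixtures and synthetic complexes."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem, RDLogger

from dmdock.mol_io import Pocket, ProteinStructure
from dmdock.synthdata import make_complex, packaged_smiles

RDLogger.DisableLog("rdApp.warning")

ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.986  -0.773  -1.206  1.00  0.00           C
ATOM      6  H   ALA A   1      -0.500   0.800   0.000  1.00  0.00           H
END
"""

ALA_HOH_PDB = ALA_PDB.replace("END\n", """\
HETATM    7  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
""")


@pytest.fixture
def ala_pdb(tmp_path):
    path = tmp_path / "ala.pdb"
    path.write_text(ALA_PDB)
    return path


@pytest.fixture
def ala_hoh_pdb(tmp_path):
    path = tmp_path / "ala_hoh.pdb"
    path.write_text(ALA_HOH_PDB)
    return path


@pytest.fixture(scope="session")
def smiles():
    return packaged_smiles()


@pytest.fixture(scope="session")
def flexible_complex(smiles):
    """Aspirin-sized flexible ligand in a 48-67 atom shell."""
    return make_complex(smiles["L012"], seed=3, hetero_frac=0.15)


@pytest.fixture(scope="session")
def rigid_complex(smiles):
    """Asymmetric rigid ligand (indole) complex."""
    return make_complex(smiles["L001"], seed=5)


@pytest.fixture(scope="session")
def contact_complex(smiles):
    """Complex with a close shell so pocket-ligand contacts exist below
    the 6 Angstrom lDDT inclusion radius."""
    return make_complex(smiles["L011"], seed=7, shell_radius=(3.2, 7.0))


def random_protein(n: int = 40, seed: int = 0,
                   spread: float = 6.0) -> ProteinStructure:
    rng = np.random.default_rng(seed)
    return ProteinStructure(
        element=np.array(["C", "N", "O", "S"])[rng.integers(0, 4, n)].astype("U4"),
        atom_name=np.array(["CA"] * n),
        res_name=np.array(["ALA"] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        coords=rng.normal(0.0, spread, (n, 3)),
        is_hetero=np.zeros(n, dtype=bool),
    )


@pytest.fixture
def random_pocket():
    return Pocket(atoms=random_protein(40, seed=1))


def mol_from_smiles(smi: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smi)
    assert mol is not None
    return mol
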