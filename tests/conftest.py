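import pytest
from rdkit import Chem

from scaffoldmap import Molecule, build_hierarchy, generate_fixture_library


def mol_from_smiles(smiles: str, mid: str = "m") -> Molecule:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"bad fixture SMILES {smiles!r}"
    return Molecule(id=mid, mol=mol)


#: Well-known drugs used as worked examples throughout the tests.
DRUGS = {
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "sulfamethoxazole": "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",
    "diazepam": "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "hydrocortisone": ("C[C@]12C[C@H](O)[C@H]3[C@@H](CCC4=CC(=O)CC[C@]43C)"
                       "[C@@H]1CC[C@@]2(O)C(=O)CO"),
}


@pytest.fixture(scope="session")
def fixture_library():
    """500 synthetic molecules plus their ground-truth chain table."""
    return generate_fixture_library(500, seed=11)


@pytest.fixture(scope="session")
def fixture_hierarchy(fixture_library):
    mols, _ = fixture_library
    return build_hierarchy(mols)
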