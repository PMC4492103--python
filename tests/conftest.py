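import numpy as np
import pytest
from rdkit.Chem import AllChem

import sarclust as sc


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def embedded_conformer(smiles: str, compound_id: int = 1,
                       conformer_index: int = 1) -> tuple[sc.Conformer, object]:
    """A 3-D conformer (heavy atoms) plus its connection table, embedded
    deterministically from SMILES."""
    mol = sc.mol_from_smiles(smiles)
    molh = AllChem.AddHs(mol)
    AllChem.EmbedMolecule(molh, randomSeed=42)
    pos = molh.GetConformer().GetPositions()
    elements, coords = [], []
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() > 1:
            elements.append(atom.GetSymbol())
            coords.append(pos[atom.GetIdx()])
    conf = sc.Conformer(compound_id, conformer_index, elements, np.array(coords))
    return conf, mol


@pytest.fixture(scope="session")
def small_fixture_data():
    """One small planted-scaffold dataset shared by read-only tests."""
    return sc.generate_fixture(sc.FixtureSpec(
        seed=3, n_scaffolds=2, compounds_per_scaffold=3,
        conformers_per_compound=2, n_assays=3,
    ))


def random_toy_conformer(rng, compound_id=1, conformer_index=1, n_atoms=None):
    """A random valence-relaxed point molecule (asymmetric by construction)."""
    n = int(rng.integers(4, 7)) if n_atoms is None else n_atoms
    coords = rng.uniform(-2.0, 2.0, size=(n, 3)) * np.array([1.0, 0.7, 0.4])
    elements = ["C"] * n
    elements[0] = "N"
    conf = sc.Conformer(compound_id, conformer_index, elements, coords)
    sc.assign_planted_features(conf)
    return conf


def random_fingerprint(rng, compound_id, n_bits=64, density=0.4):
    bits = (rng.random(n_bits) < density).astype(np.uint8)
    return sc.Fingerprint(compound_id, bits)
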