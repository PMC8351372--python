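import numpy as np
import pytest

from qphar import Feature, FeatureType, Pharmacophore

TYPES = list(FeatureType)


def embedded_mol(smiles: str, seed: int = 42):
    """A 3D-embedded RDKit molecule with explicit hydrogens."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    return mol


def random_pharmacophore(rng: np.random.Generator, n_features: int,
                         sample_id: str = "p", min_sep: float = 2.0,
                         box: float = 8.0) -> Pharmacophore:
    """Random typed feature set with a minimum inter-feature separation."""
    positions: list[np.ndarray] = []
    while len(positions) < n_features:
        cand = rng.uniform(-box, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in positions):
            positions.append(cand)
    feats = [
        Feature(type=TYPES[int(rng.integers(len(TYPES)))], position=p)
        for p in positions
    ]
    return Pharmacophore(sample_id=sample_id, features=feats)


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10.0, 10.0, size=3)
    return R, t


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
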