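"""Rule-based perception of pharmacophore features from 3D conformers.

Perception maps a conformer to typed feature spheres:

* AR  — centroid of each aromatic ring,
* HBD — each donor heavy atom (O/N/S carrying at least one H),
* HBA — each acceptor heavy atom (neutral O; neutral trivalent-or-lower N
  not bonded to oxygen, excluding pyrrole-like NH),
* PI  — each positively charged atom, plus guanidinium/amidinium carbons,
* NI  — each negatively charged atom, plus carboxylic-acid groups (centroid
  of the COO group),
* H   — centroid of every connected group of apolar carbons (carbons whose
  heavy neighbours are all carbons).

The rule set is deliberately small, versioned, and shipped as a data table
(`RULES`) so that baseline vectors and perceived models are auditable and
reproducible.  Donors are counted per donor heavy atom, not per hydrogen.
"""

from __future__ import annotations

import numpy as np

from .core import (
    DEFAULT_FEATURE_RADIUS,
    FEATURE_TYPE_ORDER,
    Feature,
    FeatureType,
    Pharmacophore,
    QpharError,
)

RULES_VERSION = "qphar-rules-1"

# SMARTS patterns for atom-centred feature types.  Each match places one
# feature at the first mapped atom.  AR and H features are geometric
# (ring/group centroids) and handled separately below.
RULES: dict[FeatureType, list[str]] = {
    FeatureType.HBD: ["[#7!H0;!$([nX3](:*):*)]", "[#8!H0]", "[#16!H0]"],
    FeatureType.HBA: [
        "[#8;!$([#8+]);!$([OX2H0]c)]",
        "[#7;!$([#7+]);X1,X2,X3;!$([#7]~[#8]);!$([#7!H0;!$([nX3](:*):*)]);!$([nX3H1])]",
    ],
    FeatureType.PI: ["[+;!$([+]~[-])]", "[CX3](=[NX2])[NX3]"],
    FeatureType.NI: ["[-;!$([-]~[+])]", "[CX3](=[OX1])[OX2H1]"],
}


def _conformer_positions(mol, conf_id: int) -> np.ndarray:
    conf = mol.GetConformer(conf_id)
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])


def perceive_pharmacophore(mol, conf_id: int = 0, sample_id: str = "",
                           radius: float = DEFAULT_FEATURE_RADIUS) -> Pharmacophore:
    """Perceive the spherical pharmacophore of one conformer.

    Raises :class:`QpharError` when no feature at all can be perceived,
    since such a sample cannot participate in alignment.
    """
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise QpharError("molecule has no conformer")
    pos = _conformer_positions(mol, conf_id)
    features: list[Feature] = []

    # Aromatic ring centroids
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            features.append(Feature(FeatureType.AR, pos[list(ring)].mean(axis=0),
                                    radius=radius, source_id=sample_id))

    # Atom-centred SMARTS features
    covered: dict[FeatureType, set[int]] = {}
    for ftype, patterns in RULES.items():
        seen = covered.setdefault(ftype, set())
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            for match in mol.GetSubstructMatches(patt):
                if ftype in (FeatureType.PI, FeatureType.NI) and len(match) > 1:
                    key = min(match)
                    if key in seen:
                        continue
                    seen.add(key)
                    features.append(Feature(ftype, pos[list(match)].mean(axis=0),
                                            radius=radius, source_id=sample_id))
                else:
                    idx = match[0]
                    if idx in seen:
                        continue
                    seen.add(idx)
                    features.append(Feature(ftype, pos[idx], radius=radius,
                                            source_id=sample_id))

    # Hydrophobes: connected components of apolar carbons -> one centroid each
    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetFormalCharge() != 0:
            continue
        if all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors()):
            apolar.add(atom.GetIdx())
    unvisited = set(apolar)
    while unvisited:
        stack = [unvisited.pop()]
        group = set(stack)
        while stack:
            a = stack.pop()
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                j = n.GetIdx()
                if j in unvisited:
                    unvisited.discard(j)
                    group.add(j)
                    stack.append(j)
        features.append(Feature(FeatureType.H, pos[sorted(group)].mean(axis=0),
                                radius=radius, source_id=sample_id))

    if not features:
        raise QpharError(
            f"no pharmacophore feature perceivable for sample {sample_id!r}; "
            "the sample cannot participate in alignment"
        )
    return Pharmacophore(sample_id=sample_id, features=features,
                         conformer_index=conf_id)


def count_features_by_type(pharmacophore: Pharmacophore) -> np.ndarray:
    """Count features per type in the fixed order (H, AR, PI, NI, HBD, HBA)."""
    counts = np.zeros(len(FEATURE_TYPE_ORDER), dtype=int)
    index = {t: i for i, t in enumerate(FEATURE_TYPE_ORDER)}
    for f in pharmacophore.features:
        counts[index[f.type]] += 1
    return counts


def count_rotatable_bonds(mol) -> int:
    """Count rotatable bonds (non-ring single bonds between non-terminal
    heavy atoms) — the rigidity criterion for template selection.

    Counted on the implicit-hydrogen graph so explicit Hs do not make
    terminal methyls look non-terminal."""
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    return int(rdMolDescriptors.CalcNumRotatableBonds(Chem.RemoveHs(mol)))


def compute_descriptors(mol) -> np.ndarray:
    """The seven physico-chemical baseline descriptors, in fixed order:
    (HBD, HBA, nRot, MW, nHeavy, cLogP, TPSA).

    Donor/acceptor counts use the package's own perception rule table
    (one count per donor/acceptor heavy atom, not per hydrogen) so the
    baseline vectors stay consistent with perceived pharmacophores."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    heavy = Chem.RemoveHs(mol)

    def rule_count(ftype: FeatureType) -> int:
        atoms: set[int] = set()
        for smarts in RULES[ftype]:
            patt = Chem.MolFromSmarts(smarts)
            atoms.update(m[0] for m in heavy.GetSubstructMatches(patt))
        return len(atoms)

    return np.array([
        rule_count(FeatureType.HBD),
        rule_count(FeatureType.HBA),
        rdMolDescriptors.CalcNumRotatableBonds(heavy),
        Descriptors.MolWt(heavy),
        heavy.GetNumHeavyAtoms(),
        Crippen.MolLogP(heavy),
        rdMolDescriptors.CalcTPSA(heavy),
    ])


def most_rigid_order(dataset) -> list[int]:
    """Indices of molecule samples sorted by rigidity: fewest rotatable
    bonds, then fewest heavy atoms, then lexicographic id."""
    keyed = []
    for i, s in enumerate(dataset.samples):
        if s.molecule is None:
            raise QpharError("most_rigid_order requires molecule samples")
        keyed.append((count_rotatable_bonds(s.molecule),
                      s.molecule.GetNumHeavyAtoms(), s.sample_id, i))
    return [i for *_, i in sorted(keyed)]
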