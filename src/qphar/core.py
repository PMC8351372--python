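"""Domain types and file I/O for quantitative pharmacophore modelling.

A pharmacophore is an abstract 3D arrangement of chemical interaction
features (H-bond donors/acceptors, aromatic rings, hydrophobes, ionisable
groups).  Every feature is a sphere: a typed point in space with a tolerance
radius (default 1.5 Å) inside which another feature of the same type is
considered to match ("overlap").  Directed features (e.g. donor vectors) are
reduced to their base point on input; the model operates on spherical
features only.

Activities are handled internally as pActivity = -log10(molar value), so
differences are "log units" and an IC50 of 1 nM maps to 9.0.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("qphar")

#: Spherical tolerance radius of a pharmacophore feature, in Å.
DEFAULT_FEATURE_RADIUS = 1.5


class FeatureType(str, enum.Enum):
    """The six pharmacophore feature types.

    H hydrophobic, AR aromatic, PI/NI positive/negative ionisable,
    HBD/HBA hydrogen-bond donor/acceptor.  Features of different types
    never interact: alignment correspondences, clustering and featurization
    all operate within a single type.
    """

    H = "H"
    AR = "AR"
    PI = "PI"
    NI = "NI"
    HBD = "HBD"
    HBA = "HBA"


#: Canonical ordering used for count vectors.
FEATURE_TYPE_ORDER: tuple[FeatureType, ...] = (
    FeatureType.H,
    FeatureType.AR,
    FeatureType.PI,
    FeatureType.NI,
    FeatureType.HBD,
    FeatureType.HBA,
)


class QpharError(Exception):
    """Base class for qphar errors."""


class SchemaError(QpharError):
    """Malformed pharmacophore JSON or activity table."""


class DegenerateModelError(QpharError):
    """All merged features were pruned; no model can be built.

    Usually indicates a template that shares only scaffold features with
    the training set, or a cluster cutoff that merges everything.  Try a
    different template or a smaller cutoff.
    """


@dataclass
class Feature:
    """A typed spherical pharmacophore feature.

    ``activities`` and ``member_count`` carry provenance once features are
    merged into a consensus model: a merged feature inherits one activity
    entry per source feature it represents, and ``member_count`` records how
    many source features it absorbed.
    """

    type: FeatureType
    position: np.ndarray
    radius: float = DEFAULT_FEATURE_RADIUS
    activities: list[float] = field(default_factory=list)
    member_count: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        self.type = FeatureType(self.type)
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("feature position must be finite")
        if not self.radius > 0:
            raise ValueError("feature radius must be positive")
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")

    def copy(self) -> "Feature":
        return Feature(
            type=self.type,
            position=self.position.copy(),
            radius=self.radius,
            activities=list(self.activities),
            member_count=self.member_count,
            source_id=self.source_id,
        )

    def activity_span(self) -> float:
        if not self.activities:
            return 0.0
        return max(self.activities) - min(self.activities)

    def distance(self, other: "Feature") -> float:
        return float(np.linalg.norm(self.position - other.position))

    def overlaps(self, other: "Feature") -> bool:
        """Two features overlap when their distance is below both radii."""
        return self.distance(other) < min(self.radius, other.radius)


@dataclass
class Pharmacophore:
    """A set of spherical features for one sample (one conformer).

    ``activity`` is in log units (pActivity) when present; ``conformer_index``
    tracks which conformer of a multi-conformer sample produced it.
    """

    sample_id: str
    features: list[Feature]
    activity: float | None = None
    conformer_index: int | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a pharmacophore must contain at least one feature")

    def __len__(self) -> int:
        return len(self.features)

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Pharmacophore":
        """Return a rigidly transformed copy (x -> R x + t)."""
        feats = []
        for f in self.features:
            g = f.copy()
            g.position = rotation @ f.position + np.asarray(translation, dtype=float)
            feats.append(g)
        return Pharmacophore(
            sample_id=self.sample_id,
            features=feats,
            activity=self.activity,
            conformer_index=self.conformer_index,
        )


@dataclass
class Sample:
    """One training/test sample: a molecule or a set of conformer pharmacophores.

    Exactly one of ``molecule`` (an RDKit Mol with >=1 conformer) or
    ``pharmacophores`` (one Pharmacophore per conformer) is populated.
    ``activity`` is in the dataset's unit_of_origin until log conversion.
    """

    sample_id: str
    activity: float
    molecule: object | None = None
    pharmacophores: list[Pharmacophore] | None = None

    @property
    def is_molecule(self) -> bool:
        return self.molecule is not None


@dataclass
class ActivityDataset:
    """Samples with activity values plus the unit they were measured in."""

    samples: list[Sample]
    unit_of_origin: str = "logunits"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        for s in self.samples:
            if not math.isfinite(s.activity):
                raise ValueError(f"sample {s.sample_id} has non-finite activity")

    def __len__(self) -> int:
        return len(self.samples)

    def activities(self) -> np.ndarray:
        return np.array([s.activity for s in self.samples])

    def to_log(self) -> "ActivityDataset":
        """Convert all activities to pActivity (-log10 molar)."""
        if self.unit_of_origin == "logunits":
            return self
        samples = [
            dataclasses.replace(s, activity=to_log_activity(s.activity, self.unit_of_origin))
            for s in self.samples
        ]
        return ActivityDataset(samples=samples, unit_of_origin="logunits")

    def subset(self, indices: Iterable[int]) -> "ActivityDataset":
        return ActivityDataset(
            samples=[self.samples[i] for i in indices],
            unit_of_origin=self.unit_of_origin,
        )


@dataclass
class QpharConfig:
    """Hyperparameters of the quantitative pharmacophore model.

    Defaults follow the recommended out-of-the-box settings: fuzzy spherical
    features, inverse-distance weighting, most-rigid-molecule template, a
    cluster cutoff equal to the feature radius, and a heavily restricted
    random forest (10 trees, depth 3) to avoid overfitting the small
    datasets typical of SAR series.
    """

    fuzzy: bool = True
    weight_type: str = "distance"  # distance | nrOfFeatures | none
    most_rigid_template: bool = True
    cluster_cutoff: float = DEFAULT_FEATURE_RADIUS
    model_type: str = "random_forest"  # random_forest | ridge | pls | pca_ridge | pca_linear
    rf_n_estimators: int = 10
    rf_max_depth: int = 3
    random_seed: int = 0

    _WEIGHT_TYPES = ("distance", "nrOfFeatures", "none")
    _MODEL_TYPES = ("random_forest", "ridge", "pls", "pca_ridge", "pca_linear")

    def __post_init__(self) -> None:
        if self.weight_type not in self._WEIGHT_TYPES:
            raise ValueError(f"unknown weight_type {self.weight_type!r}")
        if self.model_type not in self._MODEL_TYPES:
            raise ValueError(f"unknown model_type {self.model_type!r}")
        if not self.cluster_cutoff > 0:
            raise ValueError("cluster_cutoff must be positive")

    def to_dict(self) -> dict:
        return {
            "fuzzy": self.fuzzy,
            "weight_type": self.weight_type,
            "most_rigid_template": self.most_rigid_template,
            "cluster_cutoff": self.cluster_cutoff,
            "model_type": self.model_type,
            "rf_n_estimators": self.rf_n_estimators,
            "rf_max_depth": self.rf_max_depth,
            "random_seed": self.random_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QpharConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


# ---------------------------------------------------------------------------
# Activity scale


_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}


def to_log_activity(value: float, unit: str) -> float:
    """Convert a raw activity to pActivity = -log10(value in mol/L).

    ``logunits`` passes through unchanged.  1 nM -> 9.0, 1 µM -> 6.0.
    """
    if unit == "logunits":
        return float(value)
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown activity unit {unit!r}; expected nM, µM, M or logunits")
    if not value > 0:
        raise ValueError(f"cannot log-transform non-positive activity {value!r}")
    return float(-math.log10(value * _UNIT_TO_MOLAR[unit]))


# ---------------------------------------------------------------------------
# SDF molecules


def load_molecules(path: str, activity_field: str, unit: str = "nM",
                   id_field: str | None = None) -> tuple[ActivityDataset, int]:
    """Read a multi-conformer SDF into an ActivityDataset.

    Records sharing one id (the SDF title line by default, or the SD tag
    ``id_field``) are grouped as conformers of a single sample.  Activities
    are parsed from the SD tag ``activity_field`` in the declared unit and
    are NOT log-transformed here (use :meth:`ActivityDataset.to_log`).

    Records without the activity field are skipped with a warning; the
    second return value is the skip count.  Records without 3D coordinates
    raise.
    """
    from rdkit import Chem

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
    grouped: dict[str, object] = {}
    activities: dict[str, float] = {}
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("record %d could not be parsed; skipped", i)
            skipped += 1
            continue
        if mol.GetNumConformers() == 0 or not mol.GetConformer().Is3D():
            raise QpharError(f"record {i} has no 3D coordinates")
        if id_field is not None:
            if not mol.HasProp(id_field):
                raise SchemaError(f"record {i} lacks id field {id_field!r}")
            sid = mol.GetProp(id_field)
        else:
            sid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not sid:
            sid = f"record_{i}"
        if not mol.HasProp(activity_field):
            logger.warning("record %d (%s) lacks activity field %r; skipped",
                           i, sid, activity_field)
            skipped += 1
            continue
        act = float(mol.GetProp(activity_field))
        if sid in grouped:
            conf = mol.GetConformer()
            grouped[sid].AddConformer(conf, assignId=True)
        else:
            grouped[sid] = mol
            activities[sid] = act
    samples = [
        Sample(sample_id=sid, activity=activities[sid], molecule=m)
        for sid, m in grouped.items()
    ]
    return ActivityDataset(samples=samples, unit_of_origin=unit), skipped


def write_molecules(dataset: ActivityDataset, path: str, activity_field: str) -> None:
    """Write molecule samples to SDF, one record per conformer."""
    from rdkit import Chem

    writer = Chem.SDWriter(path)
    try:
        for s in dataset.samples:
            if s.molecule is None:
                raise QpharError(f"sample {s.sample_id} is not a molecule")
            mol = s.molecule
            mol.SetProp("_Name", s.sample_id)
            mol.SetProp(activity_field, repr(float(s.activity)))
            for conf in mol.GetConformers():
                writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Pharmacophore JSON

_JSON_SCHEMA_NOTE = (
    'expected {"id": str, "activity": float|null, "features": '
    '[{"type": "H|AR|PI|NI|HBD|HBA", "x": f, "y": f, "z": f, "radius": f}]}'
)


def _feature_from_json(d: dict, fuzzy: bool = True) -> Feature:
    try:
        ftype = FeatureType(d["type"])
    except ValueError:
        raise SchemaError(f"unknown feature type code {d.get('type')!r}; {_JSON_SCHEMA_NOTE}")
    except KeyError:
        raise SchemaError(f"feature missing 'type'; {_JSON_SCHEMA_NOTE}")
    try:
        pos = np.array([d["x"], d["y"], d["z"]], dtype=float)
    except KeyError as e:
        raise SchemaError(f"feature missing coordinate {e}; {_JSON_SCHEMA_NOTE}")
    # Directed features carry a direction vector; spherical (fuzzy) handling
    # keeps only the base point.  The flag is accepted for forward
    # compatibility but v1 always stores spherical features.
    return Feature(
        type=ftype,
        position=pos,
        radius=float(d.get("radius", DEFAULT_FEATURE_RADIUS)),
        activities=list(d.get("activities", [])),
        member_count=int(d.get("member_count", 1)),
        source_id=str(d.get("source_id", "")),
    )


def _feature_to_json(f: Feature, with_provenance: bool = False) -> dict:
    d = {
        "type": f.type.value,
        "x": float(f.position[0]),
        "y": float(f.position[1]),
        "z": float(f.position[2]),
        "radius": float(f.radius),
    }
    if with_provenance:
        d["activities"] = [float(a) for a in f.activities]
        d["member_count"] = int(f.member_count)
        if f.source_id:
            d["source_id"] = f.source_id
    return d


def pharmacophore_from_dict(d: dict, fuzzy: bool = True) -> Pharmacophore:
    if "features" not in d or not d["features"]:
        raise SchemaError(f"pharmacophore has no features; {_JSON_SCHEMA_NOTE}")
    return Pharmacophore(
        sample_id=str(d.get("id", "")),
        features=[_feature_from_json(fd, fuzzy=fuzzy) for fd in d["features"]],
        activity=None if d.get("activity") is None else float(d["activity"]),
        conformer_index=d.get("conformer_index"),
    )


def pharmacophore_to_dict(p: Pharmacophore, with_provenance: bool = False) -> dict:
    d = {
        "id": p.sample_id,
        "activity": p.activity,
        "features": [_feature_to_json(f, with_provenance) for f in p.features],
    }
    if p.conformer_index is not None:
        d["conformer_index"] = p.conformer_index
    return d


def read_pharmacophore_json(path: str, fuzzy: bool = True) -> Pharmacophore:
    """Read one pharmacophore from the JSON schema (see module docstring)."""
    with open(path) as fh:
        return pharmacophore_from_dict(json.load(fh), fuzzy=fuzzy)


def write_pharmacophore_json(p: Pharmacophore, path: str,
                             with_provenance: bool = False) -> None:
    with open(path, "w") as fh:
        json.dump(pharmacophore_to_dict(p, with_provenance), fh, indent=1)
        fh.write("\n")


def load_pharmacophore_dataset(paths: Sequence[str],
                               activities: dict[str, float] | None = None) -> ActivityDataset:
    """Load pharmacophore JSON files as a dataset.

    Files sharing a pharmacophore id are grouped as conformers of one
    sample.  Activities come from the JSON itself or, if given, from the
    ``activities`` mapping (id -> log-unit value), which takes precedence.
    """
    grouped: dict[str, list[Pharmacophore]] = {}
    for path in sorted(paths):
        p = read_pharmacophore_json(path)
        grouped.setdefault(p.sample_id, []).append(p)
    samples = []
    for sid, phs in grouped.items():
        if activities is not None and sid in activities:
            act = activities[sid]
        elif phs[0].activity is not None:
            act = phs[0].activity
        else:
            raise SchemaError(f"pharmacophore {sid!r} has no activity")
        for k, p in enumerate(phs):
            p.conformer_index = k
            p.activity = act
        samples.append(Sample(sample_id=sid, activity=act, pharmacophores=phs))
    return ActivityDataset(samples=samples, unit_of_origin="logunits")


def read_activity_csv(path: str) -> dict[str, float]:
    """Read an (id, activity, unit) CSV into a mapping id -> pActivity."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("id", "activity"):
        if needed not in cols:
            raise SchemaError(f"activity CSV missing column {needed!r}")
    unit_col = cols.get("unit")
    out = {}
    for _, row in df.iterrows():
        unit = str(row[unit_col]) if unit_col else "logunits"
        out[str(row[cols["id"]])] = to_log_activity(float(row[cols["activity"]]), unit)
    return out


# ---------------------------------------------------------------------------
# Model archive (directory with merged pharmacophore, config, regressor)


def save_model_archive(model, path: str) -> None:
    """Persist a fitted QpharModel to a directory.

    Layout: merged_pharmacophore.json (representatives with inherited
    activities and member counts), template.json, config.yaml (config plus
    the training activity range), regressor.joblib.
    """
    import joblib

    os.makedirs(path, exist_ok=True)
    merged = Pharmacophore(sample_id="merged", features=model.representatives)
    write_pharmacophore_json(merged, os.path.join(path, "merged_pharmacophore.json"),
                             with_provenance=True)
    write_pharmacophore_json(model.template, os.path.join(path, "template.json"))
    meta = {
        "config": model.config.to_dict(),
        "global_min": float(model.global_min),
        "global_max": float(model.global_max),
    }
    with open(os.path.join(path, "config.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    joblib.dump(model.regressor, os.path.join(path, "regressor.joblib"))


def load_model_archive(path: str):
    import joblib

    from .model import QpharModel  # late import to avoid a cycle

    with open(os.path.join(path, "config.yaml")) as fh:
        meta = yaml.safe_load(fh)
    merged = read_pharmacophore_json(os.path.join(path, "merged_pharmacophore.json"))
    template = read_pharmacophore_json(os.path.join(path, "template.json"))
    regressor = joblib.load(os.path.join(path, "regressor.joblib"))
    return QpharModel(
        template=template,
        representatives=merged.features,
        global_min=meta["global_min"],
        global_max=meta["global_max"],
        regressor=regressor,
        config=QpharConfig.from_dict(meta["config"]),
    )
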