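"""The quantitative pharmacophore model.

Model construction runs five consecutive steps:

1. **Template selection** — an explicit pharmacophore, or the pharmacophore
   perceived from the most rigid training molecule after aligning it to the
   second most rigid one over all conformer pairs.
2. **Alignment** — every training sample is rigidly aligned to the template
   (best conformer wins); all aligned features are pooled, each annotated
   with its parent sample's activity, into six per-type containers.
3. **Clustering** — single-linkage (minimum-distance) clustering within
   each container: features closer than the cutoff (default 1.5 Å, the
   feature radius) chain into one cluster.
4. **Representative selection and pruning** — each cluster is collapsed to
   one or more representative features that inherit all member activities
   and the member count; representatives whose activity span exceeds half
   the global activity range, or that represent a single feature, are
   removed as non-conclusive.
5. **Regression** — every alignable sample is featurized against the
   surviving representatives (inverse distance to the nearest overlapping
   same-type feature, 0 when nothing overlaps) and a restricted regressor
   is fitted on the vectors and activities.

Prediction aligns a query to the template (failure = out-of-domain),
featurizes it, and applies the regressor; query features that overlap no
representative are counted but contribute nothing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .alignment import AlignmentResult, align_pharmacophores, align_sample, sample_pharmacophores
from .core import (
    ActivityDataset,
    DegenerateModelError,
    Feature,
    FeatureType,
    Pharmacophore,
    QpharConfig,
    QpharError,
    Sample,
)
from .perception import most_rigid_order, perceive_pharmacophore

logger = logging.getLogger("qphar")

#: Floor on the feature distance used in inverse-distance featurization, Å.
#: Guards the 1/d entry against unbounded values as d -> 0.
DISTANCE_EPSILON = 0.01


@dataclass
class FeatureCluster:
    """A single-type cluster of aligned features."""

    members: list[Feature]
    type: FeatureType

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        if any(m.type != self.type for m in self.members):
            raise ValueError("cluster members must share one feature type")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class QpharModel:
    """A fitted quantitative pharmacophore model."""

    template: Pharmacophore
    representatives: list[Feature]
    global_min: float
    global_max: float
    regressor: object
    config: QpharConfig
    training_ids: list[str] = field(default_factory=list)

    def predict(self, sample):
        return predict(self, sample)


@dataclass
class Prediction:
    """Outcome of predicting one sample.

    ``estimate`` is None when the sample could not be aligned to the
    template (out-of-domain).  ``out_of_domain_features`` counts query
    features that overlapped no model representative and therefore
    contributed no information.
    """

    estimate: float | None
    in_domain: bool
    out_of_domain_features: int


# ---------------------------------------------------------------------------
# Step 1: template selection


def select_template(dataset: ActivityDataset, config: QpharConfig,
                    template: Pharmacophore | None = None) -> Pharmacophore:
    """Choose the reference pharmacophore for alignment.

    An explicitly supplied pharmacophore is used verbatim.  For molecule
    datasets the most rigid molecule (fewest rotatable bonds, ties by fewer
    heavy atoms then id) is aligned to the second most rigid over all
    conformer pairs and the pharmacophore of its best-aligned conformer is
    returned.  For pharmacophore-only datasets the first sample by id order
    is used.
    """
    if template is not None:
        return template
    if not dataset.samples:
        raise QpharError("cannot select a template from an empty dataset")
    if all(s.molecule is None for s in dataset.samples):
        first = min(dataset.samples, key=lambda s: s.sample_id)
        logger.info("pharmacophore-only dataset: using %r as template", first.sample_id)
        return first.pharmacophores[0]
    mol_idx = [i for i, s in enumerate(dataset.samples) if s.molecule is not None]
    if config.most_rigid_template and len(mol_idx) >= 2:
        mols = dataset.subset(mol_idx)
        order = most_rigid_order(mols)
        first, second = mols.samples[order[0]], mols.samples[order[1]]
    else:
        first = dataset.samples[mol_idx[0]]
        second = dataset.samples[mol_idx[1]] if len(mol_idx) > 1 else first
    first_pharms = sample_pharmacophores(first)
    second_pharms = sample_pharmacophores(second)
    best_key, best_pharm = None, first_pharms[0]
    for fp, sp in itertools.product(first_pharms, second_pharms):
        result = align_pharmacophores(sp, fp)
        if result is None:
            continue
        key = (-result.score, result.rmsd, fp.conformer_index or 0)
        if best_key is None or key < best_key:
            best_key, best_pharm = key, fp
    return best_pharm


# ---------------------------------------------------------------------------
# Step 3: clustering


def cluster_features(features: Sequence[Feature], cutoff: float) -> list[FeatureCluster]:
    """Single-linkage clustering of same-type features at a distance cutoff.

    Two clusters belong together iff some inter-member distance is < cutoff,
    i.e. the partition is the connected components of the graph whose edges
    join features closer than the cutoff — exactly the minimum-distance
    hierarchical clustering cut from the Euclidean distance matrix.
    """
    features = list(features)
    if not features:
        return []
    ftype = features[0].type
    if any(f.type != ftype for f in features):
        raise ValueError("cluster_features expects features of a single type")
    if len(features) == 1:
        return [FeatureCluster(members=features, type=ftype)]
    dist = squareform(pdist(np.array([f.position for f in features])))
    adjacency = csr_matrix(dist < cutoff)
    n_comp, labels = connected_components(adjacency, directed=False)
    clusters = []
    for c in range(n_comp):
        members = [features[i] for i in np.flatnonzero(labels == c)]
        clusters.append(FeatureCluster(members=members, type=ftype))
    return clusters


# ---------------------------------------------------------------------------
# Step 4a: representative feature selection


def _overlaps_all(candidate: Feature, members: Sequence[Feature],
                  skip: int | None = None) -> bool:
    return all(candidate.overlaps(m)
               for i, m in enumerate(members) if i != skip)


def _merge_into(base: Feature, members: Sequence[Feature]) -> Feature:
    """Representative inheriting all member activities and the member count."""
    merged = base.copy()
    merged.activities = [a for m in members for a in (m.activities or [])]
    merged.member_count = sum(m.member_count for m in members)
    return merged


def select_representatives(cluster: FeatureCluster,
                           radius: float | None = None) -> list[Feature]:
    """Collapse a cluster into representative features.

    Five strategies are tried in order: (1) a singleton represents itself;
    (2) an existing member overlapping all other members; (3) a new feature
    at the cluster centroid (mean position) if it overlaps every member;
    (4) a new feature at the cluster centre (bounding-box centre) likewise;
    (5) greedily pick the member overlapping the most remaining members,
    assign the overlapped set to it, and repeat until all members are
    assigned.  Representatives inherit all activities of the members they
    represent and record the member count.
    """
    members = cluster.members
    if radius is None:
        radius = members[0].radius
    if len(members) == 1:
        return [_merge_into(members[0], members)]
    # (2) an existing member covering all others
    for i, m in enumerate(members):
        if _overlaps_all(m, members, skip=i):
            return [_merge_into(m, members)]
    positions = np.array([m.position for m in members])
    # (3) centroid, (4) bounding-box centre
    for point in (positions.mean(axis=0),
                  (positions.min(axis=0) + positions.max(axis=0)) / 2.0):
        candidate = Feature(type=cluster.type, position=point, radius=radius)
        if _overlaps_all(candidate, members):
            return [_merge_into(candidate, members)]
    # (5) greedy cover: most overlaps first, ties by lowest member index
    remaining = list(range(len(members)))
    representatives = []
    while remaining:
        def n_overlaps(i: int) -> int:
            return sum(1 for j in remaining
                       if j != i and members[i].overlaps(members[j]))
        best = max(remaining, key=lambda i: (n_overlaps(i), -remaining.index(i)))
        assigned = [best] + [j for j in remaining
                             if j != best and members[best].overlaps(members[j])]
        representatives.append(_merge_into(members[best],
                                           [members[j] for j in assigned]))
        remaining = [j for j in remaining if j not in assigned]
    return representatives


# ---------------------------------------------------------------------------
# Step 4b: removing ambiguous features


def prune_ambiguous(representatives: Sequence[Feature], global_min: float,
                    global_max: float) -> list[Feature]:
    """Drop non-conclusive representatives.

    A representative is kept iff its inherited activities span at most half
    the global activity range (otherwise it carries no activity signal — the
    shared-scaffold case) AND it merged at least two source features
    (features encountered only once are outliers).
    """
    if not global_max > global_min:
        raise ValueError("global_max must exceed global_min")
    half_range = (global_max - global_min) / 2.0
    kept = [f for f in representatives
            if f.member_count >= 2 and f.activity_span() <= half_range]
    if not kept:
        raise DegenerateModelError(
            "all merged features were pruned as non-conclusive; try another "
            "template or a different cluster cutoff"
        )
    return kept


# ---------------------------------------------------------------------------
# Step 5: featurization and regression


def _feature_vector(aligned: Pharmacophore, representatives: Sequence[Feature],
                    weight_type: str) -> tuple[np.ndarray, int]:
    """Input vector of a sample against the representatives.

    Entry i = 1/max(d, ε) for the nearest overlapping same-type sample
    feature at distance d from representative i, else 0.  weight_type
    'none' binarizes entries; 'nrOfFeatures' multiplies each entry by the
    representative's member count.  The second return value counts sample
    features that overlapped no representative (locally out-of-domain).
    """
    vec = np.zeros(len(representatives))
    matched_sample_features: set[int] = set()
    for i, rep in enumerate(representatives):
        best_d = None
        for j, f in enumerate(aligned.features):
            if f.type != rep.type:
                continue
            d = rep.distance(f)
            if d < min(rep.radius, f.radius):
                matched_sample_features.add(j)
                if best_d is None or d < best_d:
                    best_d = d
        if best_d is None:
            continue
        if weight_type == "none":
            vec[i] = 1.0
        else:
            vec[i] = 1.0 / max(best_d, DISTANCE_EPSILON)
            if weight_type == "nrOfFeatures":
                vec[i] *= rep.member_count
    oo_domain = len(aligned.features) - len(matched_sample_features)
    return vec, oo_domain


def featurize(alignment: AlignmentResult, model: QpharModel) -> np.ndarray:
    """Public featurization of an aligned sample against a fitted model."""
    vec, _ = _feature_vector(alignment.aligned_query, model.representatives,
                             model.config.weight_type)
    return vec


def _make_regressor(config: QpharConfig, n_features: int, n_samples: int):
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.decomposition import PCA
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import LinearRegression, Ridge
    from sklearn.pipeline import make_pipeline

    n_comp = max(1, min(2, n_features, n_samples - 1))
    if config.model_type == "random_forest":
        return RandomForestRegressor(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            random_state=config.random_seed,
        )
    if config.model_type == "ridge":
        return Ridge()
    if config.model_type == "pls":
        return PLSRegression(n_components=n_comp)
    if config.model_type == "pca_ridge":
        return make_pipeline(PCA(n_components=n_comp), Ridge())
    if config.model_type == "pca_linear":
        return make_pipeline(PCA(n_components=n_comp), LinearRegression())
    raise ValueError(f"unknown model_type {config.model_type!r}")


# ---------------------------------------------------------------------------
# End-to-end fit / predict


def _merge_training_set(dataset: ActivityDataset, config: QpharConfig,
                        template: Pharmacophore):
    """Steps 1-4: template, alignments, pruned representatives."""
    alignments: list[AlignmentResult | None] = []
    kept_samples: list[Sample] = []
    containers: dict[FeatureType, list[Feature]] = {t: [] for t in FeatureType}
    for sample in dataset.samples:
        result = align_sample(sample, template)
        if result is None:
            logger.warning("sample %r cannot be aligned to the template; dropped",
                           sample.sample_id)
            continue
        alignments.append(result)
        kept_samples.append(sample)
        for f in result.aligned_query.features:
            g = f.copy()
            g.activities = [float(sample.activity)]
            g.member_count = 1
            g.source_id = sample.sample_id
            containers[g.type].append(g)
    if len(kept_samples) < 3:
        raise QpharError(
            f"only {len(kept_samples)} training samples could be aligned; "
            "at least 3 are required"
        )
    activities = np.array([s.activity for s in kept_samples])
    global_min, global_max = float(activities.min()), float(activities.max())
    representatives: list[Feature] = []
    for ftype in FeatureType:
        for cluster in cluster_features(containers[ftype], config.cluster_cutoff):
            representatives.extend(select_representatives(cluster))
    representatives = prune_ambiguous(representatives, global_min, global_max)
    return alignments, kept_samples, representatives, global_min, global_max


def fit(dataset: ActivityDataset, config: QpharConfig | None = None,
        template: Pharmacophore | None = None) -> QpharModel:
    """Fit a quantitative pharmacophore model on a training set.

    Activities are converted to log units first.  Samples that cannot be
    aligned to the template are dropped with a warning; fewer than 3
    alignable samples is an error.
    """
    config = config or QpharConfig()
    dataset = dataset.to_log()
    if len(dataset) < 5:
        logger.warning("training on only %d samples; expect high variance",
                       len(dataset))
    chosen = select_template(dataset, config, template)
    alignments, kept, reps, gmin, gmax = _merge_training_set(dataset, config, chosen)
    X = np.array([
        _feature_vector(a.aligned_query, reps, config.weight_type)[0]
        for a in alignments
    ])
    y = np.array([s.activity for s in kept])
    regressor = _make_regressor(config, X.shape[1], X.shape[0])
    regressor.fit(X, y)
    return QpharModel(
        template=chosen,
        representatives=reps,
        global_min=gmin,
        global_max=gmax,
        regressor=regressor,
        config=config,
        training_ids=[s.sample_id for s in kept],
    )


def predict(model: QpharModel, sample: Sample | Pharmacophore) -> Prediction:
    """Predict the log-unit activity of a sample, with domain flags."""
    if isinstance(sample, Pharmacophore):
        sample = Sample(sample_id=sample.sample_id, activity=0.0,
                        pharmacophores=[sample])
    result = align_sample(sample, model.template)
    if result is None:
        return Prediction(estimate=None, in_domain=False, out_of_domain_features=0)
    vec, oo_count = _feature_vector(result.aligned_query, model.representatives,
                                    model.config.weight_type)
    est = float(np.asarray(model.regressor.predict(vec[None, :])).ravel()[0])
    return Prediction(estimate=est, in_domain=True, out_of_domain_features=oo_count)


def model_report(model: QpharModel) -> dict:
    """Interpretability report: each representative with its type, position,
    member count and inherited activity span (the favourable/unfavourable
    region surface), plus the training activity range."""
    return {
        "n_representatives": len(model.representatives),
        "global_min": model.global_min,
        "global_max": model.global_max,
        "config": model.config.to_dict(),
        "representatives": [
            {
                "type": f.type.value,
                "position": [round(float(x), 4) for x in f.position],
                "radius": f.radius,
                "member_count": f.member_count,
                "activity_min": min(f.activities) if f.activities else None,
                "activity_max": max(f.activities) if f.activities else None,
                "activity_span": round(f.activity_span(), 4),
                "mean_activity": (float(np.mean(f.activities))
                                  if f.activities else None),
            }
            for f in model.representatives
        ],
    }


# ---------------------------------------------------------------------------
# Hyperparameter grid search


def default_grid() -> list[QpharConfig]:
    """The 90-point hyperparameter grid: 3 weight types x 3 cutoffs x
    (4 non-forest models + 3x2 random-forest variants)."""
    grid = []
    for cutoff in (1.0, 1.5, 2.0):
        for weight in ("distance", "nrOfFeatures", "none"):
            for model_type in ("random_forest", "ridge", "pls",
                               "pca_ridge", "pca_linear"):
                if model_type == "random_forest":
                    for n_est in (10, 15, 20):
                        for depth in (2, 3):
                            grid.append(QpharConfig(
                                weight_type=weight, cluster_cutoff=cutoff,
                                model_type=model_type, rf_n_estimators=n_est,
                                rf_max_depth=depth))
                else:
                    grid.append(QpharConfig(
                        weight_type=weight, cluster_cutoff=cutoff,
                        model_type=model_type))
    return grid


def grid_search(dataset: ActivityDataset, folds: int = 5, seed: int = 0,
                grid: list[QpharConfig] | None = None,
                template: Pharmacophore | None = None):
    """Exhaustive grid search by mean cross-validated RMSE.

    Returns (best config, table).  The table has one row per config with
    its mean RMSE and mean representative count; ties on RMSE are broken by
    fewer representatives, then grid order.  Alignments and merged models
    are shared across configs that only differ in weighting or regressor.
    """
    import pandas as pd

    from .datasets import evaluate, stratified_kfold

    dataset = dataset.to_log()
    grid = grid if grid is not None else default_grid()
    for g in grid:
        g.random_seed = seed
    fold_indices = stratified_kfold(dataset, k=folds, seed=seed)

    # cache steps 1-4 per (fold, cutoff); they are weight/model independent
    merged_cache: dict = {}
    rows = []
    for ci, config in enumerate(grid):
        fold_rmses, rep_counts = [], []
        for fi, (train_idx, test_idx) in enumerate(fold_indices):
            key = (fi, config.cluster_cutoff)
            train = dataset.subset(train_idx)
            if key not in merged_cache:
                try:
                    chosen = select_template(train, config, template)
                    merged_cache[key] = (_merge_training_set(train, config, chosen),
                                         chosen)
                except (QpharError, DegenerateModelError) as e:
                    merged_cache[key] = (None, e)
            merged, chosen = merged_cache[key]
            if merged is None:
                continue
            alignments, kept, reps, gmin, gmax = merged
            X = np.array([
                _feature_vector(a.aligned_query, reps, config.weight_type)[0]
                for a in alignments
            ])
            y = np.array([s.activity for s in kept])
            regressor = _make_regressor(config, X.shape[1], X.shape[0])
            regressor.fit(X, y)
            model = QpharModel(template=chosen, representatives=reps,
                               global_min=gmin, global_max=gmax,
                               regressor=regressor, config=config)
            preds, truths = [], []
            for idx in test_idx:
                p = predict(model, dataset.samples[idx])
                if p.in_domain:
                    preds.append(p.estimate)
                    truths.append(dataset.samples[idx].activity)
            if preds:
                rmse, _ = evaluate(np.array(preds), np.array(truths))
                fold_rmses.append(rmse)
                rep_counts.append(len(reps))
        rows.append({
            "grid_index": ci,
            "weight_type": config.weight_type,
            "model_type": config.model_type,
            "cluster_cutoff": config.cluster_cutoff,
            "rf_n_estimators": config.rf_n_estimators,
            "rf_max_depth": config.rf_max_depth,
            "n_folds_completed": len(fold_rmses),
            "mean_rmse": float(np.mean(fold_rmses)) if fold_rmses else np.inf,
            "mean_n_representatives": (float(np.mean(rep_counts))
                                       if rep_counts else np.inf),
        })
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mean_rmse", "mean_n_representatives", "grid_index"]).index
    best = grid[int(table.loc[order[0], "grid_index"])]
    return best, table
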