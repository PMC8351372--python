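import itertools

import numpy as np
import pytest

from qphar import (
    ActivityDataset,
    DegenerateModelError,
    Feature,
    FeatureCluster,
    FeatureType,
    Pharmacophore,
    QpharConfig,
    Sample,
    cluster_features,
    default_grid,
    fit,
    generate,
    grid_search,
    predict,
    prune_ambiguous,
    recovery_series_spec,
    select_representatives,
    select_template,
)
from qphar.model import _feature_vector, model_report


def _h(x, radius=1.5, activities=None, mc=1):
    """1D helper: a hydrophobe at (x, 0, 0)."""
    return Feature(FeatureType.H, [float(x), 0.0, 0.0], radius=radius,
                   activities=list(activities or []), member_count=mc)


# ---------------------------------------------------------------------------
# Clustering


def brute_force_single_linkage(positions, cutoff):
    """Oracle: repeatedly merge the two clusters with minimum inter-member
    distance while it is below the cutoff."""
    clusters = [{i} for i in range(len(positions))]
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            d = min(np.linalg.norm(positions[x] - positions[y])
                    for x in a for y in b)
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        if d >= cutoff:
            break
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def _partition_of(clusters, features):
    index = {id(f): i for i, f in enumerate(features)}
    return {frozenset(index[id(m)] for m in c.members) for c in clusters}


def test_cluster_1d_example():
    feats = [_h(0.0), _h(1.0), _h(2.6)]
    clusters = cluster_features(feats, cutoff=1.5)
    assert _partition_of(clusters, feats) == {frozenset({0, 1}), frozenset({2})}


def test_cluster_all_close_single_cluster():
    feats = [_h(0.0), _h(1.4), _h(0.7)]
    assert len(cluster_features(feats, cutoff=1.5)) == 1


def test_cluster_edges():
    assert cluster_features([], cutoff=1.5) == []
    single = cluster_features([_h(0.0)], cutoff=1.5)
    assert len(single) == 1 and len(single[0]) == 1
    with pytest.raises(ValueError):
        cluster_features([_h(0.0), Feature(FeatureType.AR, [0, 0, 0])], 1.5)


def test_cluster_matches_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(1, 9))
        positions = rng.uniform(-5, 5, size=(n, 3))
        cutoff = float(rng.uniform(0.5, 4.0))
        feats = [Feature(FeatureType.H, p) for p in positions]
        got = _partition_of(cluster_features(feats, cutoff), feats)
        assert got == brute_force_single_linkage(positions, cutoff)


# ---------------------------------------------------------------------------
# Representative selection (the five branches)


def test_singleton_represents_itself():
    c = FeatureCluster([_h(0.0, activities=[5.0])], FeatureType.H)
    reps = select_representatives(c)
    assert len(reps) == 1
    assert reps[0].member_count == 1
    assert np.allclose(reps[0].position, [0, 0, 0])


def test_member_covering_all_is_chosen():
    feats = [_h(0.0, activities=[5.0]), _h(1.4, activities=[6.0]),
             _h(2.8, activities=[7.0])]
    reps = select_representatives(FeatureCluster(feats, FeatureType.H))
    assert len(reps) == 1
    assert np.allclose(reps[0].position, [1.4, 0, 0])
    assert reps[0].member_count == 3
    assert sorted(reps[0].activities) == [5.0, 6.0, 7.0]


def test_centroid_branch():
    # cross layout: no member overlaps all, centroid (origin) overlaps all
    feats = [
        Feature(FeatureType.H, [1.4, 0, 0], activities=[5.0]),
        Feature(FeatureType.H, [-1.4, 0, 0], activities=[6.0]),
        Feature(FeatureType.H, [0, 1.4, 0], activities=[7.0]),
        Feature(FeatureType.H, [0, -1.4, 0], activities=[8.0]),
    ]
    reps = select_representatives(FeatureCluster(feats, FeatureType.H))
    assert len(reps) == 1
    assert np.allclose(reps[0].position, [0, 0, 0], atol=1e-12)
    assert reps[0].member_count == 4


def test_bounding_box_centre_branch():
    # mass near one end pulls the centroid too far from the lone far member;
    # the bounding-box centre still reaches everything
    feats = [_h(0.0, activities=[5.0]), _h(0.0, activities=[5.5]),
             _h(0.0, activities=[6.0]), _h(2.8, activities=[7.0])]
    reps = select_representatives(FeatureCluster(feats, FeatureType.H))
    assert len(reps) == 1
    assert np.allclose(reps[0].position, [1.4, 0, 0])
    assert reps[0].member_count == 4


def test_greedy_branch_covers_everything():
    feats = [_h(0.0, activities=[5.0]), _h(1.0, activities=[5.5]),
             _h(2.0, activities=[6.0]), _h(3.0, activities=[6.5])]
    reps = select_representatives(FeatureCluster(feats, FeatureType.H))
    assert len(reps) == 2
    assert sum(r.member_count for r in reps) == 4
    # every member is within the radius of its assigned representative
    positions = [f.position for f in feats]
    for p in positions:
        assert any(np.linalg.norm(p - r.position) < 1.5 for r in reps)


# ---------------------------------------------------------------------------
# Pruning


def test_prune_span_rule():
    wide = _h(0, activities=[5.0, 9.0], mc=2)     # span 4 > 2.5
    narrow = _h(3, activities=[6.0, 7.0], mc=3)   # span 1 <= 2.5
    kept = prune_ambiguous([wide, narrow], global_min=4.0, global_max=9.0)
    assert kept == [narrow]


def test_prune_outlier_rule():
    once = _h(0, activities=[6.5], mc=1)
    twice = _h(3, activities=[6.0, 6.5], mc=2)
    kept = prune_ambiguous([once, twice], 4.0, 9.0)
    assert kept == [twice]


def test_prune_all_removed_is_degenerate():
    with pytest.raises(DegenerateModelError):
        prune_ambiguous([_h(0, activities=[4.0, 9.0], mc=2)], 4.0, 9.0)


# ---------------------------------------------------------------------------
# Featurization


def _aligned(features):
    return Pharmacophore("s", features)


def test_feature_vector_inverse_distance():
    rep = _h(0.0, activities=[5, 6], mc=2)
    vec, ood = _feature_vector(_aligned([_h(0.5)]), [rep], "distance")
    assert vec[0] == pytest.approx(2.0)
    assert ood == 0


def test_feature_vector_no_overlap_zero():
    rep = _h(0.0)
    vec, ood = _feature_vector(_aligned([_h(2.0)]), [rep], "distance")
    assert vec[0] == 0.0
    assert ood == 1


def test_feature_vector_weight_variants():
    rep = _h(0.0, mc=3)
    sample = _aligned([_h(0.5)])
    binary, _ = _feature_vector(sample, [rep], "none")
    assert binary[0] == 1.0
    weighted, _ = _feature_vector(sample, [rep], "nrOfFeatures")
    assert weighted[0] == pytest.approx(6.0)  # (1/0.5) * member_count 3


def test_feature_vector_epsilon_floor_and_bounds(rng):
    rep = _h(0.0)
    vec, _ = _feature_vector(_aligned([_h(0.0)]), [rep], "distance")
    assert vec[0] == pytest.approx(100.0)  # 1/epsilon
    for _ in range(50):
        d = float(rng.uniform(0, 3))
        vec, _ = _feature_vector(_aligned([_h(d)]), [rep], "distance")
        assert 0.0 <= vec[0] <= 100.0
        assert (vec[0] == 0.0) == (d >= 1.5)


def test_type_mismatch_never_matches():
    rep = _h(0.0)
    other = Feature(FeatureType.AR, [0.0, 0, 0])
    vec, ood = _feature_vector(_aligned([other]), [rep], "distance")
    assert vec[0] == 0.0 and ood == 1


# ---------------------------------------------------------------------------
# Fit / predict


def test_fit_smoke_and_determinism():
    ds, _ = generate(recovery_series_spec(noise_sd=0.3, seed=4))
    cfg = QpharConfig(random_seed=4)
    m1 = fit(ds, cfg)
    m2 = fit(ds, QpharConfig(random_seed=4))
    assert len(m1.representatives) >= 1
    assert m1.global_max > m1.global_min
    for s in ds.samples[:8]:
        p1, p2 = predict(m1, s), predict(m2, s)
        assert p1.in_domain and p2.in_domain
        assert p1.estimate == p2.estimate  # bitwise determinism


def test_training_samples_in_domain_and_sane_range():
    ds, _ = generate(recovery_series_spec(noise_sd=0.0, seed=1))
    model = fit(ds, QpharConfig(random_seed=1))
    span = model.global_max - model.global_min
    for s in ds.samples:
        p = predict(model, s)
        assert p.in_domain
        assert model.global_min - span <= p.estimate <= model.global_max + span


def test_out_of_type_sample_is_out_of_domain():
    ds, _ = generate(recovery_series_spec(noise_sd=0.0, seed=1))
    model = fit(ds, QpharConfig(random_seed=1))
    alien = Pharmacophore("alien", [
        Feature(FeatureType.PI, [0, 0, 0]),
        Feature(FeatureType.PI, [3, 0, 0]),
        Feature(FeatureType.PI, [0, 3, 0]),
    ])
    p = predict(model, alien)
    assert not p.in_domain and p.estimate is None


def test_degenerate_dataset_errors():
    # all samples share identical features, activities straddle the range:
    # every cluster inherits the full span and must be pruned
    feats = lambda: [Feature(FeatureType.AR, [0, 0, 0]),
                     Feature(FeatureType.HBD, [4, 0, 0]),
                     Feature(FeatureType.H, [0, 4, 0])]
    samples = [
        Sample(f"s{i}", activity=a,
               pharmacophores=[Pharmacophore(f"s{i}", feats(), activity=a)])
        for i, a in enumerate([5.0, 9.0, 5.0, 9.0, 5.0])
    ]
    ds = ActivityDataset(samples=samples, unit_of_origin="logunits")
    with pytest.raises(DegenerateModelError):
        fit(ds, QpharConfig(random_seed=0))


def test_explicit_template_used_verbatim():
    ds, _ = generate(recovery_series_spec(noise_sd=0.0, seed=2))
    explicit = ds.samples[3].pharmacophores[0]
    chosen = select_template(ds, QpharConfig(), template=explicit)
    assert chosen is explicit


def test_pharmacophore_dataset_template_is_first_by_id():
    ds, _ = generate(recovery_series_spec(noise_sd=0.0, seed=2))
    chosen = select_template(ds, QpharConfig())
    assert chosen.sample_id == "synth_000"


def test_model_report_lists_representatives():
    ds, _ = generate(recovery_series_spec(noise_sd=0.0, seed=0))
    model = fit(ds, QpharConfig(random_seed=0))
    report = model_report(model)
    assert report["n_representatives"] == len(model.representatives)
    for row in report["representatives"]:
        assert row["member_count"] >= 2
        assert row["activity_span"] <= (model.global_max - model.global_min) / 2


# ---------------------------------------------------------------------------
# Grid search


def test_grid_cardinality():
    assert len(default_grid()) == 90


def test_grid_search_smoke_and_argmin():
    spec = recovery_series_spec(noise_sd=0.3, seed=5)
    spec.n_samples = 10
    ds, _ = generate(spec)
    best, table = grid_search(ds, folds=2, seed=5)
    assert len(table) == 90
    default_rows = table[
        (table.weight_type == "distance") & (table.model_type == "random_forest")
        & (table.cluster_cutoff == 1.5) & (table.rf_n_estimators == 10)
        & (table.rf_max_depth == 3)
    ]
    assert len(default_rows) == 1
    best_row = table[table.mean_rmse == table.mean_rmse.min()]
    assert float(best_row.mean_rmse.iloc[0]) <= float(default_rows.mean_rmse.iloc[0])
    assert isinstance(best, QpharConfig)
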