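import json

import numpy as np
import pandas as pd
import pytest

from qphar import (
    QpharConfig,
    baseline_in_domain,
    curate_records,
    evaluate,
    fit_baseline,
    generate,
    kl_heterogeneity,
    make_split,
    predict_baseline,
    recovery_series_spec,
    run_cv,
    stratified_kfold,
)
from qphar.datasets import BaselineModel, _activity_bins


# ---------------------------------------------------------------------------
# KL heterogeneity


def test_kl_uniform_occupancy_is_zero():
    report = kl_heterogeneity([4.5, 5.5, 6.5, 7.5])
    assert report.kl == pytest.approx(0.0, abs=1e-12)
    assert report.n_bins == 4
    assert report.passed  # range 3.0 >= 3 and KL 0


def test_kl_single_bin_concentration():
    # all mass lands in one bin: KL = ln N
    report = kl_heterogeneity([5.0, 5.001, 5.002, 9.0])
    # three of four in bin 0, one in the last bin
    expected = 0.75 * np.log(0.75 * 4) + 0.25 * np.log(0.25 * 4)
    assert report.kl == pytest.approx(expected)
    degenerate = kl_heterogeneity([5.0, 5.0, 5.0, 5.0])
    assert degenerate.kl == np.inf and not degenerate.passed


def test_kl_range_gate():
    # KL 0 but range below three log units fails the conjunction
    report = kl_heterogeneity([5.0, 5.5, 6.0, 6.5])
    assert report.kl == pytest.approx(0.0, abs=1e-12)
    assert not report.passed
    wide = kl_heterogeneity([4.0, 5.67, 7.33, 9.0])
    assert wide.passed


def test_kl_affine_invariance(rng):
    for _ in range(100):
        acts = rng.uniform(3, 10, size=int(rng.integers(4, 40)))
        a = kl_heterogeneity(acts).kl
        scale = float(rng.uniform(0.2, 5))
        shift = float(rng.uniform(-10, 10))
        b = kl_heterogeneity(acts * scale + shift).kl
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# Splits


def _pharm_dataset(activities):
    from qphar import ActivityDataset, Feature, FeatureType, Pharmacophore, Sample

    samples = []
    for i, a in enumerate(activities):
        p = Pharmacophore(f"s{i:02d}", [Feature(FeatureType.H, [0, 0, 0])],
                          activity=a)
        samples.append(Sample(f"s{i:02d}", a, pharmacophores=[p]))
    return ActivityDataset(samples, unit_of_origin="logunits")


def test_stratified_kfold_balanced_bins():
    ds = _pharm_dataset([float(v) for v in range(1, 11)])
    folds = stratified_kfold(ds, k=5, seed=0)
    acts = ds.activities()
    classes = _activity_bins(acts, 5)
    for train, test in folds:
        assert len(test) == 2
        assert len({classes[i] for i in test}) == 2  # two distinct bins


def test_kfold_partition_and_reproducibility():
    ds = _pharm_dataset(list(np.linspace(4, 9, 23)))
    folds = stratified_kfold(ds, k=5, seed=7)
    all_test = sorted(i for _, te in folds for i in te)
    assert all_test == list(range(23))
    for train, test in folds:
        assert not set(train) & set(test)
        assert sorted(train + test) == list(range(23))
    assert folds == stratified_kfold(ds, k=5, seed=7)
    assert folds != stratified_kfold(ds, k=5, seed=8)


def test_fold_class_proportions_within_one(rng):
    ds = _pharm_dataset(list(rng.uniform(4, 9, size=37)))
    k = 5
    folds = stratified_kfold(ds, k=k, seed=3)
    classes = _activity_bins(ds.activities(), k)
    for c in range(k):
        per_fold = [sum(classes[i] == c for i in te) for _, te in folds]
        assert max(per_fold) - min(per_fold) <= 1


@pytest.mark.parametrize("fraction,n_train", [(0.8, 40), (0.2, 10)])
def test_make_split_sizes(fraction, n_train):
    ds = _pharm_dataset(list(np.linspace(4, 9, 50)))
    train, test = make_split(ds, fraction, seed=1)
    assert len(train) == n_train and len(test) == 50 - n_train
    assert sorted(train + test) == list(range(50))


# ---------------------------------------------------------------------------
# Curation predicates


def _records(rows):
    cols = ["molecule_id", "standard_type", "standard_value", "standard_units",
            "standard_relation", "assay_type", "assay_id", "target_organism"]
    return pd.DataFrame(rows, columns=cols)


def test_curation_filters_and_gates():
    good_acts = [1.0, 30.0, 1000.0, 30000.0]  # pIC50 9..4.5, well spread
    rows = [
        (f"m{i}", "IC50", v, "nM", "=", "B", "assay_good", "Homo sapiens")
        for i, v in enumerate(good_acts)
    ]
    # records that must be filtered out record-wise
    rows += [
        ("x1", "EC50", 5.0, "nM", "=", "B", "assay_good", "Homo sapiens"),
        ("x2", "IC50", 5.0, "uM", "=", "B", "assay_good", "Homo sapiens"),
        ("x3", "IC50", 5.0, "nM", ">", "B", "assay_good", "Homo sapiens"),
        ("x4", "IC50", 5.0, "nM", "=", "F", "assay_good", "Homo sapiens"),
        ("x5", "IC50", 5.0, "nM", "=", "B", "assay_good", "Mus musculus"),
    ]
    # an assay whose activities span < 3 log units is dismissed entirely
    rows += [
        (f"n{i}", "Ki", v, "nM", "=", "B", "assay_narrow", "Homo sapiens")
        for i, v in enumerate([10.0, 20.0, 40.0, 80.0])
    ]
    out = curate_records(_records(rows))
    assert set(out["assay_id"]) == {"assay_good"}
    assert len(out) == 4
    assert sorted(out["p_activity"]) == pytest.approx(
        sorted(-np.log10(np.array(good_acts) * 1e-9)))
    assert (out["assay_kl"] <= 0.75).all()


def test_curation_missing_column_errors():
    with pytest.raises(Exception, match="standard_type"):
        curate_records(pd.DataFrame({"assay_id": ["a"]}))


# ---------------------------------------------------------------------------
# Baselines


def test_baseline_domain_bounds_toy():
    model = BaselineModel(kind="feature_counts", regressor=None,
                          domain_min=np.array([1.0, 2.0]),
                          domain_max=np.array([3.0, 4.0]))
    assert baseline_in_domain(model, [2, 3])
    assert not baseline_in_domain(model, [0, 3])
    assert not baseline_in_domain(model, [2, 5])
    with pytest.raises(ValueError):
        baseline_in_domain(model, [1, 2, 3])


def test_feature_count_baseline_on_synthetic_series():
    ds, _ = generate(recovery_series_spec(noise_sd=0.3, seed=2))
    model = fit_baseline("feature_counts", ds, QpharConfig(random_seed=2))
    assert model.domain_min.shape == (6,)
    for s in ds.samples:
        est, in_dom = predict_baseline(model, s)
        assert np.isfinite(est)
        assert in_dom  # training vectors are inside their own bounds
    again = fit_baseline("feature_counts", ds, QpharConfig(random_seed=2))
    assert predict_baseline(model, ds.samples[0])[0] == \
           predict_baseline(again, ds.samples[0])[0]


# ---------------------------------------------------------------------------
# Metrics


def test_evaluate_closed_forms():
    assert evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)
    rmse, r2 = evaluate([1.0, 1.0], [0.0, 2.0])
    assert rmse == pytest.approx(1.0) and r2 == pytest.approx(0.0)
    truths = np.array([4.0, 5.0, 7.0, 8.0])
    rmse, r2 = evaluate(np.full(4, truths.mean()), truths)
    assert r2 == pytest.approx(0.0)
    _, r2 = evaluate([1.0, 2.0], [3.0, 3.0])
    assert np.isnan(r2)


# ---------------------------------------------------------------------------
# CV harness


def test_run_cv_aggregates_and_determinism():
    ds, _ = generate(recovery_series_spec(noise_sd=0.3, seed=6))
    reports = run_cv(ds, methods=("qphar", "feature_baseline"), k=5, seed=6,
                     enforce_gates=False)
    for rep in reports.values():
        assert rep.mean_rmse == pytest.approx(np.mean(rep.fold_rmse))
        assert rep.sd_rmse == pytest.approx(np.std(rep.fold_rmse))
    again = run_cv(ds, methods=("qphar", "feature_baseline"), k=5, seed=6,
                   enforce_gates=False)
    a = json.dumps({m: r.to_dict() for m, r in reports.items()}, sort_keys=True)
    b = json.dumps({m: r.to_dict() for m, r in again.items()}, sort_keys=True)
    assert a == b


def test_run_cv_gate_enforcement():
    ds, _ = generate(recovery_series_spec(noise_sd=0.0, seed=0))
    # noiseless discrete levels are maximally clustered -> gate refuses
    with pytest.raises(Exception, match="heterogeneity"):
        run_cv(ds, methods=("qphar",), k=5, seed=0)
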