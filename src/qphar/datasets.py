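"""Dataset curation, splitting, baselines and the cross-validation harness.

Curation mirrors the filters used to qualify bioassay datasets for QSAR
modelling: activity records are reduced to comparable measurements
(IC50/Ki, nM, '=' relation, binding assays on human targets, grouped per
assay), datasets spanning less than three log units are dismissed, and a
heterogeneity gate discards datasets whose activity distribution is too
clustered — measured as the KL divergence of the binned empirical
distribution against a uniform reference, with a cutoff of 0.75.

Splits stratify the continuous endpoint by binning it into equal-width
classes, the standard workaround to use stratified K-fold machinery on
regression data.

Two baselines put the pharmacophore model in context: regressing activity
on per-type feature counts, and on seven physico-chemical descriptors.
Both use the same restricted regressor as the main model and carry a
min/max applicability domain over their training vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivityDataset, QpharConfig, QpharError
from .perception import compute_descriptors, count_features_by_type

logger = logging.getLogger("qphar")

KL_CUTOFF = 0.75
MIN_LOG_RANGE = 3.0


# ---------------------------------------------------------------------------
# Heterogeneity (KL divergence) filter


@dataclass
class HeterogeneityReport:
    kl: float
    n_bins: int
    range: tuple[float, float]
    passed: bool
    log_base: str = "natural"


def kl_heterogeneity(activities, kl_cutoff: float = KL_CUTOFF,
                     min_range: float = MIN_LOG_RANGE) -> HeterogeneityReport:
    """Heterogeneity gate for a dataset's log-unit activities.

    The activity range [a, b] is split into N equal-width bins (N = sample
    size, last bin right-closed); P is the per-bin frequency and Q the
    uniform reference 1/N.  KL(P, Q) = sum P ln(P/Q) over occupied bins
    (empty bins contribute 0 by the limit convention).  The dataset passes
    iff KL <= cutoff and b - a >= the minimum log range.
    """
    acts = np.asarray(list(activities), dtype=float)
    if len(acts) < 2:
        raise ValueError("heterogeneity needs at least 2 activities")
    if not np.all(np.isfinite(acts)):
        raise ValueError("activities must be finite")
    a, b = float(acts.min()), float(acts.max())
    n = len(acts)
    if a == b:
        return HeterogeneityReport(kl=np.inf, n_bins=n, range=(a, b), passed=False)
    counts, _ = np.histogram(acts, bins=n, range=(a, b))
    p = counts / n
    occupied = p > 0
    kl = float(np.sum(p[occupied] * np.log(p[occupied] * n)))
    passed = (kl <= kl_cutoff) and ((b - a) >= min_range)
    return HeterogeneityReport(kl=kl, n_bins=n, range=(a, b), passed=passed)


# ---------------------------------------------------------------------------
# Stratified splits for regression


def _activity_bins(activities: np.ndarray, k: int) -> np.ndarray:
    """Bin activities into k equal-width classes over [min, max]."""
    a, b = activities.min(), activities.max()
    if a == b:
        return np.zeros(len(activities), dtype=int)
    edges = np.linspace(a, b, k + 1)
    return np.clip(np.digitize(activities, edges[1:-1]), 0, k - 1)


def stratified_kfold(dataset: ActivityDataset, k: int = 5,
                     seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """K disjoint, exhaustive (train, test) index partitions stratified by
    activity class.

    Activities are binned into k equal-width classes; members of each class
    are shuffled (seeded) and dealt round-robin across folds with a rolling
    offset, so each fold's class proportions match the dataset's within one
    sample per class.  Classes smaller than k simply spread over a subset
    of folds (logged).
    """
    n = len(dataset)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    activities = dataset.to_log().activities()
    classes = _activity_bins(activities, k)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    pointer = 0
    for c in range(classes.max() + 1):
        members = np.flatnonzero(classes == c)
        if 0 < len(members) < k:
            logger.debug("activity class %d has %d < k members; spread round-robin",
                         c, len(members))
        rng.shuffle(members)
        for m in members:
            fold_of[m] = pointer % k
            pointer += 1
    folds = []
    for f in range(k):
        test = [int(i) for i in np.flatnonzero(fold_of == f)]
        train = [int(i) for i in np.flatnonzero(fold_of != f)]
        folds.append((train, test))
    return folds


def make_split(dataset: ActivityDataset, train_fraction: float = 0.8,
               seed: int = 0, n_classes: int = 5) -> tuple[list[int], list[int]]:
    """Single stratified (train, test) index split at the given fraction.

    Uses the same equal-width activity binning as the K-fold procedure;
    80-20 is the standard split, 20-80 mimics the data-poor SAR setting.
    """
    n = len(dataset)
    n_train = int(round(n * train_fraction))
    activities = dataset.to_log().activities()
    classes = _activity_bins(activities, n_classes)
    rng = np.random.default_rng(seed)
    order = []
    for c in range(classes.max() + 1):
        members = np.flatnonzero(classes == c)
        rng.shuffle(members)
        order.append(members)
    # interleave classes so truncation at n_train stays proportional
    interleaved = []
    queues = [list(m) for m in order if len(m)]
    while queues:
        for q in list(queues):
            interleaved.append(q.pop(0))
            if not q:
                queues.remove(q)
    train = sorted(int(i) for i in interleaved[:n_train])
    test = sorted(int(i) for i in interleaved[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# Activity-record curation (the pure-predicate side of the ChEMBL filters)

CURATION_FILTERS = {
    "standard_type": ("IC50", "Ki"),
    "standard_units": ("nM",),
    "standard_relation": ("=",),
    "assay_type": ("B",),
    "target_organism": ("Homo sapiens",),
}


def curate_records(records: pd.DataFrame,
                   kl_cutoff: float = KL_CUTOFF,
                   min_range: float = MIN_LOG_RANGE) -> pd.DataFrame:
    """Filter raw activity records and qualify per-assay datasets.

    Applies the record-level predicates (IC50/Ki in nM with '=' relation,
    binding assays, human targets), groups records by assay id, converts
    activities to pActivity, and keeps only assay groups passing the range
    and KL heterogeneity gates.  Returns the surviving records with
    ``p_activity`` and ``assay_kl`` columns added.  Purely local — the
    caller supplies the CSV; no network access.
    """
    from .core import to_log_activity

    df = records.copy()
    for col, allowed in CURATION_FILTERS.items():
        if col not in df.columns:
            raise QpharError(f"records are missing the column {col!r}")
        df = df[df[col].isin(allowed)]
    df = df[pd.to_numeric(df["standard_value"], errors="coerce") > 0]
    df["p_activity"] = [to_log_activity(float(v), "nM")
                        for v in df["standard_value"]]
    kept = []
    for assay_id, group in df.groupby("assay_id"):
        if len(group) < 2:
            continue
        report = kl_heterogeneity(group["p_activity"], kl_cutoff, min_range)
        if report.passed:
            g = group.copy()
            g["assay_kl"] = report.kl
            kept.append(g)
    if not kept:
        return df.iloc[0:0].assign(assay_kl=np.nan)
    return pd.concat(kept, ignore_index=True)


# ---------------------------------------------------------------------------
# Baselines with a min/max applicability domain


@dataclass
class BaselineModel:
    kind: str  # feature_counts | physchem
    regressor: object
    domain_min: np.ndarray
    domain_max: np.ndarray


def _baseline_vector(sample, kind: str) -> np.ndarray:
    if kind == "physchem":
        if sample.molecule is None:
            raise QpharError("the physico-chemical baseline requires molecules")
        return compute_descriptors(sample.molecule)
    if kind == "feature_counts":
        from .alignment import sample_pharmacophores

        pharm = sample_pharmacophores(sample)[0]
        return count_features_by_type(pharm).astype(float)
    raise ValueError(f"unknown baseline kind {kind!r}")


def fit_baseline(kind: str, train_set: ActivityDataset,
                 config: QpharConfig | None = None) -> BaselineModel:
    """Fit a baseline regressor with the same restricted learner as the
    pharmacophore model, recording per-dimension training min/max bounds
    as its applicability domain."""
    from .model import _make_regressor

    config = config or QpharConfig()
    train_set = train_set.to_log()
    X = np.array([_baseline_vector(s, kind) for s in train_set.samples])
    y = train_set.activities()
    regressor = _make_regressor(config, X.shape[1], X.shape[0])
    regressor.fit(X, y)
    return BaselineModel(kind=kind, regressor=regressor,
                         domain_min=X.min(axis=0), domain_max=X.max(axis=0))


def baseline_in_domain(model: BaselineModel, vector: np.ndarray) -> bool:
    """True iff the vector lies inside the training min/max box."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != model.domain_min.shape:
        raise ValueError(
            f"vector dimension {vector.shape} does not match the baseline "
            f"domain {model.domain_min.shape}"
        )
    return bool(np.all(vector >= model.domain_min)
                and np.all(vector <= model.domain_max))


def predict_baseline(model: BaselineModel, sample) -> tuple[float, bool]:
    vec = _baseline_vector(sample, model.kind)
    est = float(np.asarray(model.regressor.predict(vec[None, :])).ravel()[0])
    return est, baseline_in_domain(model, vec)


# ---------------------------------------------------------------------------
# Metrics


def evaluate(predictions, truths) -> tuple[float, float]:
    """(RMSE, R²) of predictions against true log-unit activities.

    R² is NaN when the truths have zero variance.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        return rmse, float("nan")
    r2 = 1.0 - float(np.sum((p - t) ** 2)) / ss_tot
    return rmse, r2


# ---------------------------------------------------------------------------
# Cross-validation harness


@dataclass
class CVReport:
    method: str
    fold_rmse: list[float]
    fold_r2: list[float]
    mean_rmse: float
    sd_rmse: float
    failed_folds: list[int]
    out_of_domain_per_fold: list[int] = field(default_factory=list)
    #: per out-of-domain baseline sample: did the pharmacophore model's
    #: absolute error beat the baseline's?
    improved_on_out_of_domain: list[bool] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fold_rmse": [round(v, 6) for v in self.fold_rmse],
            "fold_r2": [round(v, 6) for v in self.fold_r2],
            "mean_rmse": round(self.mean_rmse, 6),
            "sd_rmse": round(self.sd_rmse, 6),
            "failed_folds": self.failed_folds,
            "out_of_domain_per_fold": self.out_of_domain_per_fold,
            "improved_on_out_of_domain": self.improved_on_out_of_domain,
        }


def run_cv(dataset: ActivityDataset, methods=("qphar",), k: int = 5,
           seed: int = 0, config: QpharConfig | None = None,
           enforce_gates: bool = True) -> dict[str, CVReport]:
    """Stratified K-fold cross-validation of the pharmacophore model and/or
    the baselines.

    Per fold, every requested method is trained on the training split and
    evaluated on the test split (RMSE in log units).  For baselines the
    out-of-domain test samples are tracked, and when the pharmacophore
    model also runs, each such sample records whether the pharmacophore
    prediction had the smaller absolute error — the head-to-head
    applicability-domain comparison.  Folds where the pharmacophore model
    cannot be fitted are marked failed and excluded from the means.
    """
    from .model import fit as fit_qphar
    from .model import predict as predict_qphar

    dataset = dataset.to_log()
    if enforce_gates:
        report = kl_heterogeneity(dataset.activities())
        if not report.passed:
            raise QpharError(
                f"dataset fails the heterogeneity gate (KL={report.kl:.3f}, "
                f"range={report.range[1] - report.range[0]:.2f} log units); "
                "pass enforce_gates=False to override"
            )
    config = config or QpharConfig(random_seed=seed)
    folds = stratified_kfold(dataset, k=k, seed=seed)
    reports = {m: CVReport(method=m, fold_rmse=[], fold_r2=[], mean_rmse=np.nan,
                           sd_rmse=np.nan, failed_folds=[]) for m in methods}

    for fi, (train_idx, test_idx) in enumerate(folds):
        train = dataset.subset(train_idx)
        test_samples = [dataset.samples[i] for i in test_idx]
        truths = np.array([s.activity for s in test_samples])
        qphar_abs_err: dict[int, float] = {}

        if "qphar" in methods:
            rep = reports["qphar"]
            try:
                model = fit_qphar(train, config)
            except QpharError as e:
                logger.warning("fold %d: pharmacophore model failed (%s)", fi, e)
                rep.failed_folds.append(fi)
                model = None
            if model is not None:
                preds, ts, n_ood = [], [], 0
                for j, s in enumerate(test_samples):
                    p = predict_qphar(model, s)
                    if p.in_domain:
                        preds.append(p.estimate)
                        ts.append(truths[j])
                        qphar_abs_err[j] = abs(p.estimate - truths[j])
                    else:
                        n_ood += 1
                rep.out_of_domain_per_fold.append(n_ood)
                if preds:
                    rmse, r2 = evaluate(preds, ts)
                    rep.fold_rmse.append(rmse)
                    rep.fold_r2.append(r2)
                else:
                    rep.failed_folds.append(fi)

        for kind in ("feature_baseline", "physchem_baseline"):
            if kind not in methods:
                continue
            rep = reports[kind]
            bkind = "feature_counts" if kind == "feature_baseline" else "physchem"
            bmodel = fit_baseline(bkind, train, config)
            preds, in_domain_flags = [], []
            for s in test_samples:
                est, in_dom = predict_baseline(bmodel, s)
                preds.append(est)
                in_domain_flags.append(in_dom)
            rmse, r2 = evaluate(preds, truths)
            rep.fold_rmse.append(rmse)
            rep.fold_r2.append(r2)
            rep.out_of_domain_per_fold.append(int(sum(not f for f in in_domain_flags)))
            for j, in_dom in enumerate(in_domain_flags):
                if not in_dom and j in qphar_abs_err:
                    rep.improved_on_out_of_domain.append(
                        qphar_abs_err[j] < abs(preds[j] - truths[j]))

    for rep in reports.values():
        if rep.fold_rmse:
            rep.mean_rmse = float(np.mean(rep.fold_rmse))
            rep.sd_rmse = float(np.std(rep.fold_rmse))
    return reports
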