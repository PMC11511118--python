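"""Leave-one-subject-out cross-validation, evaluation metrics, and the experiment runner.

One fold per subject: all five task instances of the held-out subject form
the test set and every other subject's instances form the training set.
Standardization and (optionally) PCA are fit on the training fold only and
applied to the held-out instances, so no test information leaks into the
preprocessing.  The frozen-shoulder class is the positive class.

Metrics are computed on the confusion counts pooled over all folds
(micro-averaging); per-fold metrics and their literal arithmetic mean are
also reported, since each fold contributes only five instances and per-fold
ratios are individually unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, build
from .core import Cohort
from .features import FeatureSchema, extract_cohort_features, feature_schema
from .reduction import apply_pca, apply_standardizer, fit_pca, fit_standardizer

__all__ = [
    "FoldPlan",
    "Metrics",
    "ExperimentConfig",
    "ExperimentResult",
    "make_folds",
    "compute_metrics",
    "prepare_fold_data",
    "run_experiment",
    "run_grid",
    "plot_grid",
]

META_COLUMNS = ["subject_id", "group", "task"]


@dataclass(frozen=True)
class FoldPlan:
    """One (test subject, training subjects) pair per subject."""

    folds: tuple[tuple[str, tuple[str, ...]], ...]
    n: int


def make_folds(cohort_or_ids: Cohort | Sequence[str]) -> FoldPlan:
    """Build the leave-one-subject-out fold plan."""
    if isinstance(cohort_or_ids, Cohort):
        ids = [s.subject_id for s in cohort_or_ids]
    else:
        ids = list(cohort_or_ids)
    if len(ids) < 2:
        raise ValueError("at least 2 subjects required for leave-one-subject-out folds")
    folds = tuple(
        (test_id, tuple(i for i in ids if i != test_id))
        for test_id in ids
    )
    return FoldPlan(folds=folds, n=len(ids))


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the four derived fractions (FS = positive class).

    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_percent(self) -> dict[str, float]:
        return {
            "accuracy": 100 * self.accuracy,
            "precision": 100 * self.precision,
            "recall": 100 * self.recall,
            "f1": 100 * self.f1,
        }


def compute_metrics(y_true: Sequence[str], y_pred: Sequence[str]) -> Metrics:
    """Accuracy, precision, recall and F1 from hard labels (FS positive)."""
    t = np.asarray([getattr(v, "value", v) for v in y_true])
    p = np.asarray([getattr(v, "value", v) for v in y_pred])
    if t.shape != p.shape or t.size < 1:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    tp = int(np.sum((t == "FS") & (p == "FS")))
    tn = int(np.sum((t == "healthy") & (p == "healthy")))
    fp = int(np.sum((t == "healthy") & (p == "FS")))
    fn = int(np.sum((t == "FS") & (p == "healthy")))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(tp, tn, fp, fn, accuracy, precision, recall, f1, tuple(undefined))


@dataclass(frozen=True)
class ExperimentConfig:
    """One point on the comparison axes: features x placement x reduction x classifier."""

    classifier: ClassifierSpec
    feature_set: str = "all"          # all | statistical | kinematic
    placement: str = "both"           # both | arm | wrist
    pca_threshold: float | None = None  # None | 0.95 | 0.99
    standardize: bool = True
    fit_scope: str = "fold"           # fold (leakage-free) | global (literal comparison)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in ("all", "statistical", "kinematic"):
            raise ValueError(f"invalid feature_set {self.feature_set!r}")
        if self.placement not in ("both", "arm", "wrist"):
            raise ValueError(f"invalid placement {self.placement!r}")
        if self.pca_threshold is not None and not (0 < self.pca_threshold <= 1):
            raise ValueError("pca_threshold must lie in (0, 1] or be None")
        if self.fit_scope not in ("fold", "global"):
            raise ValueError(f"invalid fit_scope {self.fit_scope!r}")

    def label(self) -> str:
        pca = "none" if self.pca_threshold is None else f"{self.pca_threshold:g}"
        return f"{self.classifier.kind}|{self.feature_set}|{self.placement}|pca={pca}"


@dataclass(frozen=True)
class ExperimentResult:
    config: ExperimentConfig
    predictions: pd.DataFrame          # subject_id, task, fold, y_true, y_pred
    metrics: Metrics                   # pooled over folds (micro)
    fold_metrics: tuple[Metrics, ...]
    fold_averaged: dict[str, float]    # literal mean of per-fold fractions
    n_components: tuple[int, ...] = () # per-fold retained PCA dimensions


def _feature_matrix(
    features: pd.DataFrame, schema: FeatureSchema, config: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = schema.select(config.feature_set, config.placement)
    X = features.drop(columns=META_COLUMNS).to_numpy(dtype=float)[:, cols]
    y = features["group"].to_numpy()
    sid = features["subject_id"].to_numpy()
    return X, y, sid


def _preprocess(
    X_tr: np.ndarray, X_te: np.ndarray, config: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray, int | None]:
    if config.standardize:
        std = fit_standardizer(X_tr)
        X_tr = apply_standardizer(std, X_tr)
        X_te = apply_standardizer(std, X_te)
    k = None
    if config.pca_threshold is not None:
        pca = fit_pca(X_tr, config.pca_threshold)
        X_tr = apply_pca(pca, X_tr)
        X_te = apply_pca(pca, X_te)
        k = pca.n_components
    return X_tr, X_te, k


def prepare_fold_data(
    features: pd.DataFrame,
    schema: FeatureSchema | None = None,
    config: ExperimentConfig | None = None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per-fold (X_train, y_train, X_test, y_test), preprocessed fold-locally."""
    schema = schema or feature_schema()
    config = config or ExperimentConfig(ClassifierSpec("knn"))
    X, y, sid = _feature_matrix(features, schema, config)
    plan = make_folds(list(dict.fromkeys(sid)))
    out = []
    for test_id, _ in plan.folds:
        te = sid == test_id
        X_tr, X_te, _ = _preprocess(X[~te], X[te], config)
        out.append((X_tr, y[~te], X_te, y[te]))
    return out


def run_experiment(
    cohort: Cohort | None = None,
    config: ExperimentConfig | None = None,
    *,
    features: pd.DataFrame | None = None,
    schema: FeatureSchema | None = None,
) -> ExperimentResult:
    """Leave-one-subject-out evaluation of one configuration.

    Either a cohort (features are extracted on the fly) or a precomputed
    feature table from :func:`fsid.features.extract_cohort_features` must be
    supplied.
    """
    if config is None:
        raise ValueError("config is required")
    if features is None:
        if cohort is None:
            raise ValueError("either cohort or features must be supplied")
        features = extract_cohort_features(cohort)
    schema = schema or feature_schema()

    X, y, sid = _feature_matrix(features, schema, config)
    plan = make_folds(list(dict.fromkeys(sid)))

    if config.fit_scope == "global":
        # Literal whole-dataset preprocessing (leaky); kept for comparison runs.
        X, _, _ = _preprocess(X, X[:0] if X.shape[0] else X, replace(config, pca_threshold=None))
        if config.pca_threshold is not None:
            pca = fit_pca(X, config.pca_threshold)
            X = apply_pca(pca, X)

    records = []
    fold_metrics = []
    n_components: list[int] = []
    for fold_idx, (test_id, _) in enumerate(plan.folds):
        te = sid == test_id
        if config.fit_scope == "fold":
            X_tr, X_te, k = _preprocess(X[~te], X[te], config)
            if k is not None:
                n_components.append(k)
        else:
            X_tr, X_te = X[~te], X[te]
        model = build(replace(config.classifier, seed=config.classifier.seed + config.seed))
        model.fit(X_tr, y[~te])
        pred = model.predict(X_te)
        fold_metrics.append(compute_metrics(y[te], pred))
        for tsk, yt, yp in zip(features.loc[te, "task"], y[te], pred):
            records.append({
                "subject_id": test_id, "task": tsk, "fold": fold_idx,
                "y_true": yt, "y_pred": yp,
            })

    predictions = pd.DataFrame.from_records(records)
    pooled = compute_metrics(predictions["y_true"], predictions["y_pred"])
    fold_averaged = {
        name: float(np.mean([getattr(m, name) for m in fold_metrics]))
        for name in ("accuracy", "precision", "recall", "f1")
    }
    return ExperimentResult(
        config=config,
        predictions=predictions,
        metrics=pooled,
        fold_metrics=tuple(fold_metrics),
        fold_averaged=fold_averaged,
        n_components=tuple(n_components),
    )


def run_grid(
    cohort: Cohort | None,
    configs: Sequence[ExperimentConfig],
    *,
    features: pd.DataFrame | None = None,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Run several configurations; tidy table with one row per config x metric."""
    if len(configs) == 0:
        raise ValueError("config list is empty")
    if features is None:
        if cohort is None:
            raise ValueError("either cohort or features must be supplied")
        features = extract_cohort_features(cohort)
    rows = []
    for config in configs:
        result = run_experiment(config=config, features=features, schema=schema)
        for metric, value in result.metrics.as_percent().items():
            rows.append({
                "classifier": config.classifier.kind,
                "feature_set": config.feature_set,
                "placement": config.placement,
                "pca_threshold": config.pca_threshold,
                "metric": metric,
                "value": value,
            })
    return pd.DataFrame(rows)


def plot_grid(table: pd.DataFrame, path: str, by: str = "placement") -> None:
    """Grouped-bar chart of a run_grid table, one panel per metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["accuracy", "precision", "recall", "f1"]
    fig, axes = plt.subplots(2, 2, figsize=(12, 8), sharey=True)
    for ax, metric in zip(axes.ravel(), metrics):
        sub = table[table["metric"] == metric]
        pivot = sub.pivot_table(index="classifier", columns=by, values="value")
        pivot.plot.bar(ax=ax, legend=(metric == "accuracy"))
        ax.set_title(metric)
        ax.set_ylabel("%")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
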