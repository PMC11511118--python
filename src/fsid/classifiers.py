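"""Uniform build/fit/predict interface over the nine shoulder-task classifiers.

Seven classical techniques (k-nearest neighbors, RBF-kernel SVM, decision
tree, random forest, Gaussian naive Bayes, AdaBoost, gradient-boosted trees)
are backed by scikit-learn and XGBoost; the multilayer perceptron and the 1-D
convolutional network are small seeded numpy networks trained full-batch with
Adam on cross-entropy, for at most 100 epochs with early stopping once the
training loss fails to drop by 0.01 for 10 consecutive epochs.

The CNN treats the ordered feature vector of a task instance as a
single-channel 1-D sequence: each convolution block is convolution (stride 1,
same padding) -> batch normalization -> ReLU -> max-pooling (size 2), followed
by dropout, a ReLU fully-connected layer and a 2-class softmax output.

Hyperparameters are validated against the documented grids: k in 1..30 for
KNN; for the neural models, 1-3 fully-connected layers (MLP) or 1-2
convolution blocks with kernel size in {3, 5, 7} and {16, 32, 64} filters
(CNN), hidden units in {16, 32, 64}, dropout in {0.1, 0.3, 0.5} and learning
rate in {0.001, 0.0005, 0.0001}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._nn import (
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    Network,
    ReLU,
    Reshape1D,
)

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "Model",
    "build",
    "fit",
    "predict",
    "knn_k_sweep",
    "default_specs",
]

CLASSIFIER_KINDS = (
    "knn", "svm_rbf", "dtree", "rforest", "nbayes", "adaboost", "gboost", "mlp", "cnn",
)
NEURAL_KINDS = ("mlp", "cnn")

POSITIVE_LABEL = "FS"
NEGATIVE_LABEL = "healthy"

MAX_EPOCHS = 100
PATIENCE = 10
MIN_DELTA = 0.01

_HIDDEN_GRID = (16, 32, 64)
_DROPOUT_GRID = (0.1, 0.3, 0.5)
_LR_GRID = (0.001, 0.0005, 0.0001)

#: Allowed hyperparameters per kind: name -> validator.
_GRIDS: Mapping[str, Mapping[str, object]] = {
    "knn": {"k": tuple(range(1, 31))},
    "svm_rbf": {"C": "positive_float", "gamma": "gamma"},
    "dtree": {"max_depth": "depth"},
    "rforest": {"n_estimators": "positive_int", "max_depth": "depth"},
    "nbayes": {},
    "adaboost": {"n_estimators": "positive_int"},
    "gboost": {"n_estimators": "positive_int", "max_depth": "positive_int",
               "learning_rate": "positive_float"},
    "mlp": {"n_layers": (1, 2, 3), "hidden": _HIDDEN_GRID,
            "dropout": _DROPOUT_GRID, "lr": _LR_GRID},
    "cnn": {"blocks": (1, 2), "kernel": (3, 5, 7), "filters": _HIDDEN_GRID,
            "hidden": _HIDDEN_GRID, "dropout": _DROPOUT_GRID, "lr": _LR_GRID},
}

_DEFAULTS: Mapping[str, dict] = {
    "knn": {"k": 5},
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "dtree": {"max_depth": None},
    "rforest": {"n_estimators": 100, "max_depth": None},
    "nbayes": {},
    "adaboost": {"n_estimators": 50},
    "gboost": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.3},
    "mlp": {"n_layers": 2, "hidden": 32, "dropout": 0.3, "lr": 0.001},
    "cnn": {"blocks": 1, "kernel": 5, "filters": 16, "hidden": 32,
            "dropout": 0.3, "lr": 0.001},
}


def _validate(kind: str, key: str, value) -> None:
    grid = _GRIDS[kind]
    if key not in grid:
        raise ValueError(f"{kind}: unknown hyperparameter {key!r}; allowed: {sorted(grid)}")
    rule = grid[key]
    if isinstance(rule, tuple):
        if value not in rule:
            raise ValueError(f"{kind}.{key}={value!r} not in allowed values {rule}")
    elif rule == "positive_int":
        if not (isinstance(value, (int, np.integer)) and value > 0):
            raise ValueError(f"{kind}.{key} must be a positive integer, got {value!r}")
    elif rule == "positive_float":
        if not (isinstance(value, (int, float)) and value > 0):
            raise ValueError(f"{kind}.{key} must be a positive number, got {value!r}")
    elif rule == "depth":
        if value is not None and not (isinstance(value, (int, np.integer)) and value > 0):
            raise ValueError(f"{kind}.{key} must be None or a positive integer, got {value!r}")
    elif rule == "gamma":
        ok = value == "scale" or (isinstance(value, (int, float)) and value > 0)
        if not ok:
            raise ValueError(f"{kind}.{key} must be 'scale' or a positive number, got {value!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration: kind, hyperparameters and seed."""

    kind: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; allowed: {CLASSIFIER_KINDS}")
        for key, value in self.hyperparams.items():
            _validate(self.kind, key, value)
        object.__setattr__(self, "hyperparams", dict(self.hyperparams))

    def resolved(self) -> dict:
        hp = dict(_DEFAULTS[self.kind])
        hp.update(self.hyperparams)
        return hp


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """One documented default configuration per classifier kind."""
    return [ClassifierSpec(kind, seed=seed) for kind in CLASSIFIER_KINDS]


class Model:
    """A (possibly unfitted) classifier with a uniform fit/predict surface."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.fitted = False
        self.n_features_: int | None = None
        self.training_log: list[float] = []
        self._backend = None
        self._knn_y: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    def build_network(self, n_features: int) -> Network:
        """Materialize the seeded neural network for an input of given width."""
        hp = self.spec.resolved()
        rng = np.random.default_rng(self.spec.seed)
        if self.spec.kind == "mlp":
            layers: list = []
            width = n_features
            for _ in range(hp["n_layers"]):
                layers += [Dense(width, hp["hidden"], rng), ReLU(), Dropout(hp["dropout"], rng)]
                width = hp["hidden"]
            layers.append(Dense(width, 2, rng))
            return Network(layers, lr=hp["lr"], rng=rng)
        if self.spec.kind == "cnn":
            layers = [Reshape1D()]
            c_in, length = 1, n_features
            for _ in range(hp["blocks"]):
                layers += [
                    Conv1D(c_in, hp["filters"], hp["kernel"], rng),
                    BatchNorm1D(hp["filters"]),
                    ReLU(),
                    MaxPool1D(2),
                ]
                c_in = hp["filters"]
                length //= 2
            layers += [
                Flatten(),
                Dropout(hp["dropout"], rng),
                Dense(c_in * length, hp["hidden"], rng),
                ReLU(),
                Dense(hp["hidden"], 2, rng),
            ]
            return Network(layers, lr=hp["lr"], rng=rng)
        raise ValueError(f"{self.spec.kind} is not a neural kind")

    def _build_classical(self):
        hp = self.spec.resolved()
        seed = self.spec.seed
        kind = self.spec.kind
        if kind == "knn":
            return NearestNeighbors(n_neighbors=hp["k"])
        if kind == "svm_rbf":
            return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], random_state=seed)
        if kind == "dtree":
            return DecisionTreeClassifier(max_depth=hp["max_depth"], random_state=seed)
        if kind == "rforest":
            return RandomForestClassifier(
                n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
                random_state=seed, n_jobs=1,
            )
        if kind == "nbayes":
            return GaussianNB()
        if kind == "adaboost":
            return AdaBoostClassifier(n_estimators=hp["n_estimators"], random_state=seed)
        if kind == "gboost":
            return XGBClassifier(
                n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
                learning_rate=hp["learning_rate"], random_state=seed,
                n_jobs=1, verbosity=0, eval_metric="logloss", tree_method="hist",
            )
        raise AssertionError(kind)

    # -- fitting and prediction -------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "Model":
        X = np.asarray(X, dtype=float)
        y01 = _encode(y)
        if X.ndim != 2 or X.shape[0] != y01.size or X.shape[0] < 2:
            raise ValueError("X and y must be matched with >= 2 rows")
        if len(np.unique(y01)) < 2:
            raise ValueError("training labels contain a single class")
        self.n_features_ = X.shape[1]
        if self.spec.kind in NEURAL_KINDS:
            net = self.build_network(X.shape[1])
            net.fit(X, y01, max_epochs=MAX_EPOCHS, patience=PATIENCE, min_delta=MIN_DELTA)
            self.training_log = list(net.training_log)
            self._backend = net
        elif self.spec.kind == "knn":
            nn = self._build_classical()
            nn.fit(X)
            self._backend = nn
            self._knn_y = y01
        else:
            clf = self._build_classical()
            clf.fit(X, y01)
            self._backend = clf
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} columns, got {X.shape[1]}")
        if self.spec.kind in NEURAL_KINDS:
            y01 = self._backend.predict_proba(X).argmax(axis=1)
        elif self.spec.kind == "knn":
            y01 = self._knn_predict(X)
        else:
            y01 = np.asarray(self._backend.predict(X), dtype=int)
        return _decode(y01)

    def _knn_predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over the k nearest training points; ties go to the nearest one."""
        _, idx = self._backend.kneighbors(X)
        votes = self._knn_y[idx]
        pos = votes.sum(axis=1)
        k = votes.shape[1]
        out = (2 * pos > k).astype(int)
        tie = 2 * pos == k
        out[tie] = votes[tie, 0]
        return out


def _encode(y: Sequence) -> np.ndarray:
    labels = np.asarray([getattr(v, "value", v) for v in y])
    bad = set(np.unique(labels)) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"unknown labels {bad}; expected {POSITIVE_LABEL}/{NEGATIVE_LABEL}")
    return (labels == POSITIVE_LABEL).astype(int)


def _decode(y01: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y01) == 1, POSITIVE_LABEL, NEGATIVE_LABEL)


def build(spec: ClassifierSpec) -> Model:
    """Construct an unfitted model from a validated spec."""
    return Model(spec)


def fit(model: Model, X: np.ndarray, y: Sequence[str]) -> Model:
    return model.fit(X, y)


def predict(model: Model, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def knn_k_sweep(
    fold_data: Sequence[tuple[np.ndarray, Sequence[str], np.ndarray, Sequence[str]]],
    k_range: Sequence[int] = range(1, 31),
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled leave-one-subject-out accuracy of KNN for each k.

    ``fold_data`` is a sequence of (X_train, y_train, X_test, y_test) tuples,
    already preprocessed per fold.  Returns one row per k with the best k
    (ties broken toward the smallest) flagged in the ``best`` column.
    """
    rows = []
    for k in k_range:
        correct = total = 0
        for X_tr, y_tr, X_te, y_te in fold_data:
            model = build(ClassifierSpec("knn", {"k": int(k)}, seed=seed)).fit(X_tr, y_tr)
            pred = model.predict(X_te)
            correct += int(np.sum(pred == np.asarray([getattr(v, "value", v) for v in y_te])))
            total += len(pred)
        rows.append({"k": int(k), "accuracy": correct / total})
    df = pd.DataFrame(rows)
    best_idx = df["accuracy"].idxmax()  # idxmax returns the first maximum: smallest k
    df["best"] = False
    df.loc[best_idx, "best"] = True
    return df
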