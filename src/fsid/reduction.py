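"""Feature standardization and PCA reduction, fit on training folds only.

Standardization is the z-score with population statistics; columns with zero
training variance map to zero rather than dividing by zero.  PCA is computed
by singular-value decomposition of the centered matrix with a deterministic
sign convention (the largest-magnitude loading of each component is positive),
and the retained dimension is the smallest number of components whose
cumulative explained-variance ratio reaches the requested threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StandardizerParams",
    "PCAModel",
    "fit_standardizer",
    "apply_standardizer",
    "fit_pca",
    "apply_pca",
]


@dataclass(frozen=True)
class StandardizerParams:
    mu: np.ndarray
    sigma: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma shapes differ")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.feature_names is not None and len(self.feature_names) != self.mu.size:
            raise ValueError("feature_names length mismatch")


@dataclass(frozen=True)
class PCAModel:
    components: np.ndarray              # (k, p) orthonormal rows
    explained_variance: np.ndarray      # (k,) retained eigenvalues (ddof=1)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                    # (p,) training column means
    n_components: int
    threshold: float | None


def fit_standardizer(
    train: np.ndarray, feature_names: Sequence[str] | None = None
) -> StandardizerParams:
    """Column means and population SDs of the training matrix."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training matrix must be 2-D with >= 2 rows")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    # columns constant up to float round-off are treated as zero-variance
    sigma[sigma <= 1e-12 * np.maximum(1.0, np.abs(mu))] = 0.0
    return StandardizerParams(
        mu=mu,
        sigma=sigma,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def apply_standardizer(params: StandardizerParams, X: np.ndarray) -> np.ndarray:
    """Z-score ``X`` with training parameters; zero-variance columns map to 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.mu.size:
        raise ValueError(f"expected {params.mu.size} columns, got {X.shape[1]}")
    safe_sigma = np.where(params.sigma == 0.0, 1.0, params.sigma)
    Z = (X - params.mu) / safe_sigma
    Z[:, params.sigma == 0.0] = 0.0
    return Z


def fit_pca(train: np.ndarray, threshold: float | None = None) -> PCAModel:
    """PCA of the (already standardized) training matrix via SVD.

    ``threshold`` is the retained-variance fraction in (0, 1]; ``None`` keeps
    the full decomposition (min(n_rows - 1, n_features) components).
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training matrix must be 2-D with >= 2 rows")
    if threshold is not None and not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")

    mean = X.mean(axis=0)
    Xc = X - mean
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eigenvalues = S**2 / (n - 1)
    total = eigenvalues.sum()
    ratio = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)

    # Deterministic sign: largest-magnitude loading of each component positive.
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]

    max_k = min(n - 1, X.shape[1])
    if threshold is None:
        k = max_k
    else:
        cum = np.cumsum(ratio)
        k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
        k = min(k, max_k)

    return PCAModel(
        components=Vt[:k],
        explained_variance=eigenvalues[:k],
        explained_variance_ratio=ratio[:k],
        mean=mean,
        n_components=k,
        threshold=threshold,
    )


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project ``X`` onto the retained components (scores of width n_components)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean.size:
        raise ValueError(f"expected {model.mean.size} columns, got {X.shape[1]}")
    return (X - model.mean) @ model.components.T
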