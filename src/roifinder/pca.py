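"""Principal component analysis of the standardized feature table.

Features are standardized (mean 0, sample standard deviation 1, n-1
denominator) and decomposed by SVD of the standardized matrix
``Xs = U S V^T``, equivalent to the eigendecomposition ``C = V L V^T`` of
the covariance matrix ``C = Xs^T Xs / (n-1)`` with eigenvalues
``L = S^2 / (n-1)``.  Scores are the projections ``Xs V`` (equal to
``U S``); loadings are ``V S / (n-1)``, whose rows show which features
drive each component.

Eigenvector signs are fixed so the largest-magnitude entry of each column
of V is positive (ties broken by first index), making two fits of the same
data bit-comparable.  Standardizing first means multiplying a raw feature
by a positive constant leaves scores unchanged: count-to-concentration
conversion cannot move the cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ZeroVarianceError


@dataclass
class PCAModel:
    """Fitted PCA: standardization stats, axes, spectra and projections.

    Attributes
    ----------
    feature_means, feature_stds : (f,) arrays
        Standardization statistics (stds use the n-1 denominator).
    components : (f, f) array
        Principal axes V, one column per component, ordered by decreasing
        eigenvalue; columns orthonormal with deterministic sign.
    eigenvalues : (f,) array
        Variance along each axis, non-increasing.
    singular_values : (f,) array
        S of the SVD; ``S**2 = (n - 1) * eigenvalues``.
    scores : (n, f) array
        Projections of the training data, ``Xs @ V``.
    loadings : (f, f) array
        ``V @ diag(S) / (n - 1)``.
    explained_ratio : (f,) array
        ``eigenvalues / eigenvalues.sum()``, sums to 1.
    """

    n: int
    feature_names: list[str] | None
    feature_means: np.ndarray
    feature_stds: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    singular_values: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    explained_ratio: np.ndarray

    @property
    def f(self) -> int:
        return len(self.feature_means)


def standardize(X: np.ndarray,
                feature_names: Sequence[str] | None = None,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column and scale to unit sample standard deviation.

    Returns ``(Xs, means, stds)``.  A constant column cannot be scaled and
    raises :class:`ZeroVarianceError` naming the feature.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x f matrix with n >= 2")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(stds <= 1e-12 * np.maximum(1.0, np.abs(means)))
    if zero.size:
        j = int(zero[0])
        name = feature_names[j] if feature_names is not None else f"column {j}"
        raise ZeroVarianceError(str(name))
    return (X - means) / stds, means, stds


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        i = int(np.argmax(np.abs(col)))  # first index on ties
        if col[i] < 0:
            V[:, j] = -col
    return V


def fit_pca(X: np.ndarray,
            feature_names: Sequence[str] | None = None,
            *, standardized: bool = False) -> PCAModel:
    """Fit PCA to a feature matrix (standardizing it first by default).

    Pass ``standardized=True`` if ``X`` is already standardized; the model
    then records zero means and unit stds.
    """
    X = np.asarray(X, dtype=np.float64)
    if standardized:
        Xs = X
        means = np.zeros(X.shape[1])
        stds = np.ones(X.shape[1])
    else:
        Xs, means, stds = standardize(X, feature_names)
    n, f = Xs.shape
    _, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    # pad to f components when n - 1 < f (rank-deficient case)
    if S.shape[0] < f:
        S = np.pad(S, (0, f - S.shape[0]))
        Vt = np.vstack([Vt, np.zeros((f - Vt.shape[0], f))])
    V = _fix_signs(Vt.T)
    eigenvalues = S ** 2 / (n - 1)
    scores = Xs @ V
    loadings = V * S / (n - 1)
    total = eigenvalues.sum()
    explained = eigenvalues / total if total > 0 else np.zeros(f)
    return PCAModel(
        n=n,
        feature_names=list(feature_names) if feature_names is not None else None,
        feature_means=means,
        feature_stds=stds,
        components=V,
        eigenvalues=eigenvalues,
        singular_values=S,
        scores=scores,
        loadings=loadings,
        explained_ratio=explained,
    )


def project(model: PCAModel, X_new: np.ndarray,
            n_components: int = 2) -> np.ndarray:
    """Project new rows onto the first ``n_components`` principal axes.

    New data is standardized with the model's means and stds.
    """
    if n_components > model.f:
        raise ValueError(
            f"n_components={n_components} exceeds feature count {model.f}")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    Xs = (X_new - model.feature_means) / model.feature_stds
    return Xs @ model.components[:, :n_components]


def scree(model: PCAModel) -> np.ndarray:
    """Explained-variance ratio per component (non-increasing, sums to 1)."""
    return model.explained_ratio.copy()


def save_model(model: PCAModel, path) -> None:
    """Serialize a fitted model to JSON (arrays as nested lists)."""
    import json

    payload = {
        "n": model.n,
        "feature_names": model.feature_names,
        "feature_means": model.feature_means.tolist(),
        "feature_stds": model.feature_stds.tolist(),
        "components": model.components.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "singular_values": model.singular_values.tolist(),
        "scores": model.scores.tolist(),
        "loadings": model.loadings.tolist(),
        "explained_ratio": model.explained_ratio.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PCAModel:
    """Load a model written by :func:`save_model`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    arrays = {k: np.asarray(v, dtype=np.float64)
              for k, v in payload.items() if k not in ("n", "feature_names")}
    return PCAModel(n=int(payload["n"]),
                    feature_names=payload["feature_names"], **arrays)
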