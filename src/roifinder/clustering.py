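"""Hard and fuzzy k-means on PC scores, with confidence ranking.

Hard k-means minimizes the within-cluster sum of squares (Lloyd iterations,
k-means++ starts, best of ``n_init`` runs).  Fuzzy k-means (fuzzy c-means)
minimizes

    J = sum_i sum_j w_ij^m ||x_i - c_j||^2,   sum_j w_ij = 1,

with fuzziness m > 1 (default 2; m -> 1 recovers hard clustering), by
alternating the center update ``c_j = sum_i w_ij^m x_i / sum_i w_ij^m`` and
the weight update ``w_ij = 1 / sum_c (||x_i - c_j|| / ||x_i - c_c||)^(2/(m-1))``.
A point coincident with a center gets an indicator weight row (the formula
would divide by zero).  A cell's confidence is its largest membership
weight; cells below the confidence cutoff (default 0.99, strict) are
flagged as borderline — typically outliers, dividing cells or scan
artifacts worth a manual look.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_K = 2
DEFAULT_FUZZINESS = 2.0
DEFAULT_CONFIDENCE_THRESHOLD = 0.99


@dataclass
class HardClustering:
    """k-means result: centers, integer labels and the WCSS objective."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    inertia: float


@dataclass
class FuzzyClustering:
    """Fuzzy k-means result with per-cell membership weights.

    ``weights`` is n x k and row-stochastic; ``confidence`` is the rowwise
    maximum weight (in [1/k, 1]); ``hard_labels`` the rowwise argmax.
    """

    k: int
    m: float
    centers: np.ndarray
    weights: np.ndarray
    objective: float
    n_iter: int
    objective_history: list[float] | None = None

    @property
    def confidence(self) -> np.ndarray:
        return self.weights.max(axis=1)

    @property
    def hard_labels(self) -> np.ndarray:
        return self.weights.argmax(axis=1)


def kmeans(scores: np.ndarray, k: int = DEFAULT_K, seed: int | None = 0,
           n_init: int = 10, max_iter: int = 300,
           tol: float = 1e-6) -> HardClustering:
    """Hard k-means on score rows; deterministic for a fixed seed."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2:
        raise ValueError("scores must be an n x d matrix")
    n = scores.shape[0]
    if n < k:
        raise ValueError(f"cannot form k={k} clusters from n={n} points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=tol, random_state=seed,
                algorithm="lloyd").fit(scores)
    return HardClustering(k=k, centers=km.cluster_centers_,
                          labels=km.labels_.astype(int),
                          inertia=float(km.inertia_))


def _fuzzy_weights(scores: np.ndarray, centers: np.ndarray,
                   m: float) -> np.ndarray:
    """Membership weights for fixed centers (indicator rows at distance 0)."""
    d2 = ((scores[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    w = np.zeros((scores.shape[0], centers.shape[0]))
    zero_rows = (d2 == 0).any(axis=1)
    if zero_rows.any():
        hits = d2[zero_rows] == 0
        w[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    pos = ~zero_rows
    if pos.any():
        # w_ij = 1 / sum_c (d_ij / d_ic)^(2/(m-1)), via d^( -2/(m-1) ) normalized
        inv = d2[pos] ** (-1.0 / (m - 1.0))
        w[pos] = inv / inv.sum(axis=1, keepdims=True)
    return w


def fuzzy_kmeans(scores: np.ndarray, k: int = DEFAULT_K,
                 m: float = DEFAULT_FUZZINESS, seed: int | None = 0,
                 max_iter: int = 300, tol: float = 1e-9) -> FuzzyClustering:
    """Fuzzy k-means; initialized from a hard k-means run with the same seed.

    Iterates center and weight updates until ``max |dW| < tol`` or
    ``max_iter``; the objective is non-increasing across iterations.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if m <= 1:
        raise ValueError("fuzziness m must be > 1; use kmeans() for m = 1")
    n = scores.shape[0]
    if n < k:
        raise ValueError(f"cannot form k={k} clusters from n={n} points")
    centers = kmeans(scores, k=k, seed=seed).centers.copy()
    weights = _fuzzy_weights(scores, centers, m)
    history = [fuzzy_objective(scores, centers, weights, m)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        wm = weights ** m
        centers = (wm.T @ scores) / wm.sum(axis=0)[:, None]
        new_weights = _fuzzy_weights(scores, centers, m)
        delta = np.abs(new_weights - weights).max()
        weights = new_weights
        history.append(fuzzy_objective(scores, centers, weights, m))
        if delta < tol:
            break
    return FuzzyClustering(k=k, m=m, centers=centers, weights=weights,
                           objective=history[-1], n_iter=n_iter,
                           objective_history=history)


def fuzzy_objective(scores: np.ndarray, centers: np.ndarray,
                    weights: np.ndarray, m: float) -> float:
    """The fuzzy WCSS objective J for given scores, centers and weights."""
    d2 = ((np.asarray(scores)[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((weights ** m) * d2).sum())


def confidence(fc: FuzzyClustering) -> np.ndarray:
    """Per-cell confidence: the largest membership weight, in [1/k, 1]."""
    return fc.confidence


def flag_low_confidence(values: np.ndarray,
                        threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                        ) -> np.ndarray:
    """Flag cells strictly below the confidence cutoff.

    The comparison is strict: a cell at exactly the threshold is kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError("confidence threshold must be in (0, 1]")
    values = np.asarray(values, dtype=np.float64)
    return values < threshold


def assign_treatment_labels(clustering: FuzzyClustering | HardClustering,
                            feature_table: pd.DataFrame,
                            element: str = "K",
                            aggregator_prefix: str = "max",
                            ) -> tuple[dict[int, str], np.ndarray]:
    """Label the two clusters as healthy (A) vs poisoned (B) by potassium.

    Intracellular K is high in cells frozen live with an intact inner
    membrane and leaks out when the membrane is disrupted, so the cluster
    with the higher mean K feature is called type A (healthy) and the other
    type B (poisoned).  Defined only for k = 2; a K tie raises and requires
    manual assignment.

    Returns the cluster -> type mapping and the per-cell predicted labels.
    """
    if clustering.k != 2:
        raise ValueError("treatment heuristic is defined only for k = 2")
    labels = (clustering.hard_labels if isinstance(clustering, FuzzyClustering)
              else clustering.labels)
    if len(feature_table) != len(labels):
        raise ValueError("feature table rows do not align with clustered rows")
    col = f"{aggregator_prefix}_{element}"
    if col not in feature_table.columns:
        raise KeyError(f"feature table has no column {col!r}")
    k_values = feature_table[col].to_numpy(dtype=np.float64)
    means = [k_values[labels == j].mean() if (labels == j).any() else -np.inf
             for j in range(2)]
    if means[0] == means[1]:
        raise ValueError(
            "clusters have equal mean K; assign treatment types manually")
    high = int(np.argmax(means))
    mapping = {high: "A", 1 - high: "B"}
    predicted = np.array([mapping[int(j)] for j in labels])
    return mapping, predicted


def clustering_table(feature_table: pd.DataFrame, fc: FuzzyClustering,
                     threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                     predicted_type: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell clustering report (ids, weights, confidence, flags)."""
    out = feature_table[["scan_id", "roi_id"]].copy()
    out["hard_label"] = fc.hard_labels
    for j in range(fc.k):
        out[f"w{j + 1}"] = fc.weights[:, j]
    out["confidence"] = fc.confidence
    out["flagged"] = flag_low_confidence(fc.confidence, threshold)
    if predicted_type is not None:
        out["predicted_type"] = predicted_type
    return out
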