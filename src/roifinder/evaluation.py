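"""Clustering accuracy (dice score), subsampling experiments and SNR.

The dice score of a cluster matched to a ground-truth treatment label is

    DS = 2 T_P / (2 T_P + F_P + F_N)

with true positives, false positives and false negatives counted by
treating that cluster's members as positive predictions for the label.
Clusters are unordered, so the cluster <-> label assignment is chosen as
the bijection maximizing the mean DS (exhaustive over permutations; exact
and cheap for the k <= 4 used here).

The subsampling experiment measures how clustering accuracy depends on the
number of cells available: for each proportion p it repeatedly samples
``ceil(p * n_type)`` cells per type without replacement, reruns PCA (2 PCs)
plus k-means, and averages the mean dice over repetitions.

SNR of a scan against a reference binary cell mask is defined here as
``(mean inside - mean outside) / std outside`` — a contrast-to-background-
noise ratio.  The definition is a documented choice; only its monotone
behavior with dwell time is asserted, not any absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering as _clustering
from . import pca as _pca
from .features import feature_matrix


@dataclass
class DiceResult:
    """Per-cluster dice scores under the best cluster->label matching."""

    per_cluster_dice: dict[int, float]
    mean_dice: float
    matching: dict[int, object]


@dataclass
class SubsampleResult:
    """One row per proportion: mean dice and per-type sampled counts."""

    rows: pd.DataFrame  # proportion, mean_dice, per-type counts, n_total
    reps: int
    seed: int


def _dice_for_matching(pred: np.ndarray, true: np.ndarray,
                       clusters: Sequence[int],
                       labels: Sequence[object]) -> dict[int, float]:
    scores = {}
    for cluster, lab in zip(clusters, labels):
        p = pred == cluster
        t = true == lab
        tp = int(np.sum(p & t))
        fp = int(np.sum(p & ~t))
        fn = int(np.sum(~p & t))
        denom = 2 * tp + fp + fn
        scores[cluster] = 1.0 if denom == 0 else 2 * tp / denom
    return scores


def dice(pred_labels, true_labels) -> DiceResult:
    """Dice scores of predicted clusters against ground-truth labels.

    Invariant to relabeling of clusters and of ground-truth label values:
    all bijections between cluster ids and label values are tried and the
    one maximizing the mean DS is reported.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("pred_labels and true_labels must have equal length")
    clusters = sorted(np.unique(pred).tolist())
    labels = sorted(np.unique(true).tolist())
    if len(clusters) > len(labels):
        # allow extra clusters only by padding with unmatched dummy labels
        raise ValueError(
            f"{len(clusters)} clusters but {len(labels)} label values")
    best = None
    for perm in permutations(labels, len(clusters)):
        scores = _dice_for_matching(pred, true, clusters, perm)
        mean = float(np.mean(list(scores.values())))
        if best is None or mean > best[0]:
            best = (mean, scores, dict(zip(clusters, perm)))
    mean, scores, matching = best
    return DiceResult(per_cluster_dice=scores, mean_dice=mean,
                      matching=matching)


def subsample_experiment(feature_table: pd.DataFrame,
                         proportions: Sequence[float],
                         reps: int = 1000,
                         seed: int = 0,
                         n_components: int = 2,
                         k: int | None = None,
                         label_column: str = "true_label",
                         ) -> SubsampleResult:
    """Clustering accuracy as a function of the sampled data fraction.

    For each proportion p and each of ``reps`` repetitions, sample
    ``ceil(p * n_type)`` cells of every type without replacement, fit PCA on
    the sampled features, k-means the first ``n_components`` scores with
    k = number of types, and record the mean dice against the true labels.
    Deterministic for a fixed seed.
    """
    if label_column not in feature_table.columns:
        raise ValueError(f"feature table needs a {label_column!r} column")
    labels = feature_table[label_column].to_numpy()
    types = sorted(pd.unique(labels).tolist())
    if len(types) < 2:
        raise ValueError("need at least two label types")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    k = len(types) if k is None else k
    X = feature_matrix(feature_table)
    by_type = {t: np.flatnonzero(labels == t) for t in types}
    rng = np.random.default_rng(seed)
    rows = []
    for p in proportions:
        counts = {t: math.ceil(p * len(idx)) for t, idx in by_type.items()}
        if any(c < 1 for c in counts.values()) or sum(counts.values()) < k:
            raise ValueError(
                f"proportion {p} leaves too few cells to form {k} clusters")
        dices = []
        for _ in range(reps):
            take = np.concatenate([
                rng.choice(by_type[t], size=counts[t], replace=False)
                for t in types
            ])
            model = _pca.fit_pca(X[take])
            scores = model.scores[:, :n_components]
            hc = _clustering.kmeans(
                scores, k=k, seed=int(rng.integers(2 ** 31)))
            dices.append(dice(hc.labels, labels[take]).mean_dice)
        row = {"proportion": p, "mean_dice": float(np.mean(dices))}
        for t in types:
            row[f"n_type{t}_sampled"] = counts[t]
        row["n_total"] = sum(counts.values())
        rows.append(row)
    return SubsampleResult(rows=pd.DataFrame(rows), reps=reps, seed=seed)


def snr(image: np.ndarray, reference_mask: np.ndarray) -> float:
    """Contrast-to-background-noise ratio of an image against a cell mask.

    ``(mean(image[mask]) - mean(image[~mask])) / std(image[~mask])``.
    Raises if the mask is single-class or the background has zero spread.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(reference_mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if mask.all() or not mask.any():
        raise ValueError("reference mask must contain both classes")
    inside = image[mask]
    outside = image[~mask]
    spread = outside.std()
    if spread == 0:
        raise ValueError("background has zero variance; SNR undefined")
    return float((inside.mean() - outside.mean()) / spread)
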