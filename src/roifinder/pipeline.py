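"""End-to-end coarse-scan -> recommendation pipeline with on-disk artifacts.

Every stage's defaults are the values the workflow was validated with:
segmentation composite from K+P+S+Ca, 1.25x Otsu, <= 8 px artifact
rejection, 7 features with max-count aggregation, 2 principal components,
k = 2 clusters at fuzziness m = 2, confidence cutoff 0.99.  All randomness
is funneled through one seed so a re-run reproduces identical CSV content.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering as _clustering
from . import features as _features
from . import io as _io
from . import pca as _pca
from . import recommend as _recommend
from . import segmentation as _segmentation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline; defaults are the validated values."""

    segmentation_channels: tuple[str, ...] = ("K", "P", "S", "Ca")
    feature_elements: tuple[str, ...] = ("K", "P", "Ca", "Zn", "Fe")
    aggregator: str = "max"
    otsu_multiplier: float = 1.25
    min_pixels: int = 8  # exclusive: components <= this size are rejected
    n_components: int = 2
    k: int = 2
    m: float = 2.0
    confidence_threshold: float = 0.99
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        for key in ("segmentation_channels", "feature_elements"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("segmentation_channels", "feature_elements"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    config: PipelineConfig
    map_sets: list[_io.ElementalMapSet]
    masks: list[_segmentation.SegmentationMask]
    rois: list[_segmentation.ROI]
    feature_table: pd.DataFrame
    pca_model: _pca.PCAModel | None = None
    scores: np.ndarray | None = None
    hard: _clustering.HardClustering | None = None
    fuzzy: _clustering.FuzzyClustering | None = None
    type_mapping: dict[int, str] | None = None
    predicted_type: np.ndarray | None = None
    recommendations: list[_recommend.Recommendation] = field(default_factory=list)


def roi_table(rois: Sequence[_segmentation.ROI]) -> pd.DataFrame:
    """Bookkeeping CSV: one row per kept ROI with bbox and centroids."""
    return pd.DataFrame([
        {
            "scan_id": r.scan_id,
            "roi_id": r.roi_id,
            "n_pixels": r.n_pixels,
            "bbox_r0": r.bbox[0], "bbox_c0": r.bbox[1],
            "bbox_r1": r.bbox[2], "bbox_c1": r.bbox[3],
            "centroid_row": r.centroid_px[0], "centroid_col": r.centroid_px[1],
            "x_um": r.centroid_um[0], "y_um": r.centroid_um[1],
        }
        for r in rois
    ], columns=["scan_id", "roi_id", "n_pixels", "bbox_r0", "bbox_c0",
                "bbox_r1", "bbox_c1", "centroid_row", "centroid_col",
                "x_um", "y_um"])


def run_pipeline(scans: Sequence, config: PipelineConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Segment, featurize, embed, cluster and recommend, in one pass.

    ``scans`` may be HDF5 paths or in-memory ``ElementalMapSet`` objects.
    With ``out_dir`` given, stage artifacts are written there under stable
    filenames (masks, ``rois.csv``, ``features.csv``, ``pca_model.json``,
    ``clustering.csv``, ``recommendations.json``, ``config.yaml``).
    Scans with zero detected cells are tolerated; clustering is skipped
    with a warning when fewer than k cells are found in total.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    logger.info("pipeline config: %s", config)

    map_sets, masks, all_rois, tables = [], [], [], []
    for scan in scans:
        ms = scan if isinstance(scan, _io.ElementalMapSet) else _io.read_scan(scan)
        map_sets.append(ms)
        seg, rois = _segmentation.segment_scan(
            ms, channels=config.segmentation_channels,
            otsu_multiplier=config.otsu_multiplier,
            min_pixels_exclusive=config.min_pixels)
        masks.append(seg)
        all_rois.extend(rois)
        tables.append(_features.build_feature_table(
            rois, ms, elements=config.feature_elements,
            aggregator=config.aggregator))
        if out is not None:
            from skimage.io import imsave
            imsave(out / f"mask_{ms.metadata.scan_id}.png",
                   seg.mask.astype(np.uint8), check_contrast=False)

    feature_table = (pd.concat(tables, ignore_index=True) if tables
                     else pd.DataFrame())
    if out is not None:
        roi_table(all_rois).to_csv(out / "rois.csv", index=False)
        _io.write_feature_table(feature_table, out / "features.csv")

    result = PipelineResult(config=config, map_sets=map_sets, masks=masks,
                            rois=all_rois, feature_table=feature_table)
    n = len(feature_table)
    if n < max(config.k, 2):
        logger.warning("only %d cell(s) detected; clustering skipped", n)
        return result

    X = _features.feature_matrix(feature_table)
    names = _features.feature_columns(config.feature_elements, config.aggregator)
    model = _pca.fit_pca(X, feature_names=names)
    scores = model.scores[:, :config.n_components]
    fuzzy = _clustering.fuzzy_kmeans(scores, k=config.k, m=config.m,
                                     seed=config.seed)
    hard = _clustering.kmeans(scores, k=config.k, seed=config.seed)
    result.pca_model, result.scores = model, scores
    result.hard, result.fuzzy = hard, fuzzy

    predicted = None
    if config.k == 2:
        try:
            result.type_mapping, predicted = _clustering.assign_treatment_labels(
                fuzzy, feature_table,
                aggregator_prefix=config.aggregator)
            result.predicted_type = predicted
        except (ValueError, KeyError) as exc:
            logger.warning("treatment labeling skipped: %s", exc)

    for j in range(config.k):
        result.recommendations.append(_recommend.recommend_from_cluster(
            fuzzy, j, min_confidence=config.confidence_threshold,
            rois=all_rois))

    if out is not None:
        _pca.save_model(model, out / "pca_model.json")
        pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
                     ).to_csv(out / "scores.csv", index=False)
        _clustering.clustering_table(
            feature_table, fuzzy, threshold=config.confidence_threshold,
            predicted_type=predicted).to_csv(out / "clustering.csv", index=False)
        for j, rec in enumerate(result.recommendations):
            _recommend.write_scan_request(
                rec, out / f"recommendations_cluster{j}.json")
    logger.info("pipeline done: %d scans, %d cells kept", len(map_sets), n)
    return result
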