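"""Ranked fine-scan recommendations with stage coordinates.

Two criteria: the nearest neighbor of a user selection in the 2D PC plane
(Euclidean distance), or the most confidently clustered members of a target
cluster.  Either way the product is an ordered list of ROIs with stage
coordinates that a scan-control system can consume as its next fine-scan
targets.

Stage-coordinate convention (configurable at the beamline-integration
layer): x runs along columns, y along rows, origin at the scan's top-left
pixel center.  The interactive lasso selection of scatter points is
replaced by an index-set / polygon-containment API so everything runs
headless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .clustering import FuzzyClustering
from .io import ScanMetadata
from .segmentation import ROI

logger = logging.getLogger(__name__)


@dataclass
class RecommendedROI:
    scan_id: str
    roi_id: int
    centroid_um: tuple[float, float] | None
    score: float  # distance (nearest_neighbor) or confidence
    index: int  # row index into the clustered/scored table


@dataclass
class Recommendation:
    """Ordered fine-scan targets produced by one criterion."""

    criterion: str  # "nearest_neighbor" | "cluster_confidence"
    source_selection: list[int] = field(default_factory=list)
    recommended: list[RecommendedROI] = field(default_factory=list)

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.recommended]


def nearest_neighbor(selected: Iterable[int], scores2d: np.ndarray,
                     exclude: Iterable[int] = (),
                     rois: Sequence[ROI] | None = None) -> Recommendation:
    """Nearest unselected neighbor of each selected cell in the PC plane.

    For each selected index, the non-selected, non-excluded row minimizing
    Euclidean distance in the 2-PC plane is recommended (ties broken toward
    the lower row index).  Results are de-duplicated and sorted by distance.
    """
    scores2d = np.asarray(scores2d, dtype=np.float64)
    selected = sorted(set(int(i) for i in selected))
    excluded = set(int(i) for i in exclude) | set(selected)
    if not selected:
        raise ValueError("selection is empty")
    candidates = [i for i in range(scores2d.shape[0]) if i not in excluded]
    if not candidates:
        raise ValueError("no candidate cells remain after exclusion")
    cand_pts = scores2d[candidates]
    best: dict[int, float] = {}
    for i in selected:
        d = np.linalg.norm(cand_pts - scores2d[i], axis=1)
        j = candidates[int(np.argmin(d))]  # argmin is first-of-ties -> lower index
        dist = float(d.min())
        if j not in best or dist < best[j]:
            best[j] = dist
    ordered = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    recommended = [
        RecommendedROI(
            scan_id=rois[j].scan_id if rois is not None else "",
            roi_id=rois[j].roi_id if rois is not None else j,
            centroid_um=rois[j].centroid_um if rois is not None else None,
            score=dist,
            index=j,
        )
        for j, dist in ordered
    ]
    return Recommendation(criterion="nearest_neighbor",
                          source_selection=selected, recommended=recommended)


def recommend_from_cluster(fc: FuzzyClustering, target_cluster: int,
                           n_recommend: int | None = None,
                           min_confidence: float = 0.0,
                           rois: Sequence[ROI] | None = None,
                           ) -> Recommendation:
    """Most confident members of one cluster, ranked for fine scanning."""
    if not 0 <= target_cluster < fc.k:
        raise ValueError(f"cluster {target_cluster} does not exist (k={fc.k})")
    conf = fc.confidence
    members = np.flatnonzero((fc.hard_labels == target_cluster)
                             & (conf >= min_confidence))
    if members.size == 0:
        logger.warning("cluster %d has no members with confidence >= %g",
                       target_cluster, min_confidence)
    order = members[np.lexsort((members, -conf[members]))]
    if n_recommend is not None:
        order = order[:n_recommend]
    recommended = [
        RecommendedROI(
            scan_id=rois[j].scan_id if rois is not None else "",
            roi_id=rois[j].roi_id if rois is not None else int(j),
            centroid_um=rois[j].centroid_um if rois is not None else None,
            score=float(conf[j]),
            index=int(j),
        )
        for j in order
    ]
    return Recommendation(criterion="cluster_confidence",
                          source_selection=[], recommended=recommended)


def select_in_polygon(scores2d: np.ndarray,
                      polygon: Sequence[tuple[float, float]]) -> list[int]:
    """Indices of scatter points inside a polygon drawn in the PC plane.

    Headless stand-in for an interactive lasso selector.
    """
    path = MplPath(polygon)
    inside = path.contains_points(np.asarray(scores2d, dtype=np.float64))
    return [int(i) for i in np.flatnonzero(inside)]


def roi_to_stage(roi: ROI, metadata: ScanMetadata) -> tuple[float, float]:
    """Stage coordinates (x, y) in µm of an ROI's centroid.

    ``x = origin_x + centroid_col * pixel_step`` and
    ``y = origin_y + centroid_row * pixel_step``.
    """
    row, col = roi.centroid_px
    ox, oy = metadata.origin
    return (ox + col * metadata.pixel_step, oy + row * metadata.pixel_step)


def write_scan_request(rec: Recommendation, path,
                       suggested_window_um: float = 5.0) -> None:
    """Minimal JSON hand-off for a scan-control system."""
    payload = [
        {
            "scan_id": r.scan_id,
            "roi_id": r.roi_id,
            "x_um": None if r.centroid_um is None else r.centroid_um[0],
            "y_um": None if r.centroid_um is None else r.centroid_um[1],
            "score": r.score,
            "criterion": rec.criterion,
            "suggested_window_um": suggested_window_um,
        }
        for r in rec.recommended
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
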