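"""Cell segmentation: composite map, Otsu thresholding, ROI extraction.

The segmentation route: sum the K, P, S and Ca channels into one composite
intensity image, smooth it with a 3x3 median filter, threshold at 1.25x the
Otsu value, then keep 8-connected components larger than 8 pixels (regions
of <= 8 pixels are image-processing artifacts, not cells).

Conventions, stated once and tested everywhere: pixel indexing is 0-based,
row-major, (row, col); bounding boxes are half-open [r0, r1) x [c0, c1);
connectivity is 8-neighbor so diagonal cell boundaries stay intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.measure import label, regionprops

from .errors import DegenerateImageError
from .io import ElementalMapSet, ScanMetadata

logger = logging.getLogger(__name__)

#: channels summed into the segmentation composite
DEFAULT_COMPOSITE_CHANNELS = ("K", "P", "S", "Ca")
#: multiplier applied to the Otsu threshold of the filtered composite
DEFAULT_OTSU_MULTIPLIER = 1.25
#: components with <= this many pixels are rejected as artifacts
DEFAULT_MIN_PIXELS_EXCLUSIVE = 8


@dataclass
class SegmentationMask:
    """Binary cell mask (1 inside a cell, 0 background) with provenance."""

    mask: np.ndarray
    threshold_used: float
    otsu_raw: float


@dataclass
class ROI:
    """One detected cell: an 8-connected pixel component.

    ``pixels`` is an (n, 2) int array of (row, col) coordinates; ``bbox`` is
    half-open ``(r0, c0, r1, c1)``; ``centroid_um`` is the stage coordinate
    (x, y) of the centroid, with x along columns and y along rows.
    """

    roi_id: int
    scan_id: str
    pixels: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of this ROI on a grid of the given shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


def composite_map(map_set: ElementalMapSet,
                  channels=DEFAULT_COMPOSITE_CHANNELS) -> np.ndarray:
    """Element-wise sum of the named channels (K+P+S+Ca by default)."""
    grids = [map_set.channel(name) for name in channels]
    return np.sum(grids, axis=0)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold over an ``n_bins`` equal-width histogram.

    Returns the bin edge maximizing the between-class variance; ties are
    broken toward the lower threshold for determinism.  The histogram spans
    [min, max] of the image with equal-width bins, which keeps the value
    reproducible across platforms.

    Raises
    ------
    DegenerateImageError
        If the image is constant (no two classes to separate).
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise DegenerateImageError("image is constant; cannot threshold")
    counts, edges = np.histogram(image.ravel(), bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    # candidate thresholds are the interior bin edges; class 0 = bins below
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    centers = (edges[:-1] + edges[1:]) / 2.0
    cum_mass = np.cumsum(counts * centers)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mass / w0
        mu1 = (cum_mass[-1] + counts[-1] * centers[-1] - cum_mass) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    best = int(np.argmax(between))  # argmax takes the first max -> lower edge
    return float(edges[best + 1])


def binarize(image: np.ndarray,
             otsu_multiplier: float = DEFAULT_OTSU_MULTIPLIER,
             n_bins: int = 256) -> SegmentationMask:
    """Median-filter (3x3, reflect borders) then threshold at 1.25x Otsu.

    A constant (degenerate) image yields an all-background mask with a
    warning instead of an error, so background-only scans pass through the
    pipeline cleanly.
    """
    image = np.asarray(image, dtype=np.float64)
    filtered = median_filter(image, size=3, mode="reflect")
    try:
        otsu_raw = otsu_threshold(filtered, n_bins=n_bins)
    except DegenerateImageError:
        logger.warning("composite is constant after filtering; "
                       "treating scan as background-only")
        return SegmentationMask(
            mask=np.zeros_like(filtered, dtype=bool),
            threshold_used=float("nan"),
            otsu_raw=float("nan"),
        )
    threshold_used = otsu_multiplier * otsu_raw
    return SegmentationMask(
        mask=filtered > threshold_used,
        threshold_used=threshold_used,
        otsu_raw=otsu_raw,
    )


def extract_rois(seg: SegmentationMask | np.ndarray,
                 metadata: ScanMetadata,
                 min_pixels_exclusive: int = DEFAULT_MIN_PIXELS_EXCLUSIVE,
                 ) -> list[ROI]:
    """Connected components of the mask, rejecting small artifacts.

    Components are 8-connected; any component with ``n_pixels <=
    min_pixels_exclusive`` is rejected (the filter is exclusive: <= 8
    rejected, >= 9 kept).  ROI ids are assigned in raster order of each
    component's first pixel.  Stage centroids are ``origin + centroid_px *
    pixel_step`` with x along columns, y along rows.
    """
    mask = seg.mask if isinstance(seg, SegmentationMask) else np.asarray(seg)
    mask = mask.astype(bool)
    labeled = label(mask, connectivity=2)  # 2 = 8-connectivity in 2D
    rois: list[ROI] = []
    regions = regionprops(labeled)
    # regionprops orders by label; skimage labels in raster order of first pixel
    n_rejected = 0
    for region in regions:
        if region.num_pixels <= min_pixels_exclusive:
            n_rejected += 1
            continue
        r0, c0, r1, c1 = region.bbox
        cr, cc = region.centroid
        ox, oy = metadata.origin
        rois.append(ROI(
            roi_id=len(rois),
            scan_id=metadata.scan_id,
            pixels=region.coords.copy(),
            bbox=(r0, c0, r1, c1),
            centroid_px=(cr, cc),
            centroid_um=(ox + cc * metadata.pixel_step,
                         oy + cr * metadata.pixel_step),
        ))
    logger.info("scan %s: %d regions found, %d rejected (<= %d px), %d kept",
                metadata.scan_id, len(regions), n_rejected,
                min_pixels_exclusive, len(rois))
    return rois


def segment_scan(map_set: ElementalMapSet,
                 channels=DEFAULT_COMPOSITE_CHANNELS,
                 otsu_multiplier: float = DEFAULT_OTSU_MULTIPLIER,
                 min_pixels_exclusive: int = DEFAULT_MIN_PIXELS_EXCLUSIVE,
                 ) -> tuple[SegmentationMask, list[ROI]]:
    """Composite -> binarize -> extract ROIs, in one call."""
    comp = composite_map(map_set, channels)
    seg = binarize(comp, otsu_multiplier=otsu_multiplier)
    rois = extract_rois(seg, map_set.metadata,
                        min_pixels_exclusive=min_pixels_exclusive)
    return seg, rois
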