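"""Per-ROI features: morphology plus per-element fluorescence statistics.

Each detected cell is summarized by seven features at the defaults: area
``a`` (pixels), eccentricity ``e`` (unitless, 0 = circle, -> 1 = line), and
the maximum fluorescence count of the K, P, Ca, Zn and Fe channels over the
cell's pixels.  The maximum can be swapped for the cell-averaged count or
any user-supplied reduction; both operate on the raw channel grids, not the
median-filtered composite (the composite exists only for segmentation).

Eccentricity is that of the ellipse with the same normalized second central
moments as the pixel set — the standard region-property definition.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .errors import ChannelNotFoundError
from .io import ElementalMapSet
from .segmentation import ROI

#: element channels used as features at the defaults
DEFAULT_FEATURE_ELEMENTS = ("K", "P", "Ca", "Zn", "Fe")

#: named reductions over an ROI's pixel values
AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "max": lambda v: float(np.max(v)),
    "mean": lambda v: float(np.mean(v)),
}


def roi_area(roi: ROI) -> int:
    """Area of the cell in pixels (its pixel count)."""
    return roi.n_pixels


def roi_eccentricity(roi: ROI) -> float:
    """Eccentricity of the moment-equivalent ellipse, in [0, 1).

    Computed from the normalized second central moments of the binary pixel
    set; a single pixel has eccentricity 0.
    """
    r0, c0, r1, c1 = roi.bbox
    local = np.zeros((r1 - r0, c1 - c0), dtype=np.uint8)
    local[roi.pixels[:, 0] - r0, roi.pixels[:, 1] - c0] = 1
    (region,) = regionprops(local)
    return float(region.eccentricity)


def roi_element_stat(roi: ROI, grid: np.ndarray,
                     aggregator: str | Callable = "max") -> float:
    """Apply a reduction to the channel values at the ROI's pixels.

    ``aggregator`` is ``"max"``, ``"mean"`` or a callable taking the 1D
    array of the ROI's pixel values.
    """
    grid = np.asarray(grid)
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= grid.shape[0] or cols.max() >= grid.shape[1]):
        raise IndexError(
            f"ROI {roi.roi_id} of scan {roi.scan_id} has pixels outside the "
            f"{grid.shape} grid"
        )
    values = grid[rows, cols]
    fn = AGGREGATORS[aggregator] if isinstance(aggregator, str) else aggregator
    return float(fn(values))


def feature_columns(elements: Sequence[str] = DEFAULT_FEATURE_ELEMENTS,
                    aggregator: str | Callable = "max") -> list[str]:
    """Canonical feature column names: (area, eccentricity, elements...)."""
    prefix = aggregator if isinstance(aggregator, str) else getattr(
        aggregator, "__name__", "custom")
    return ["area_px", "eccentricity"] + [f"{prefix}_{el}" for el in elements]


def build_feature_table(rois: Sequence[ROI], map_set: ElementalMapSet,
                        elements: Sequence[str] = DEFAULT_FEATURE_ELEMENTS,
                        aggregator: str | Callable = "max") -> pd.DataFrame:
    """Feature table with one row per ROI in canonical column order.

    Columns: ``scan_id, roi_id, area_px, eccentricity, <agg>_<el>...``
    (7 feature columns at the defaults).  Row order follows roi_id.
    """
    missing = [el for el in elements if el not in map_set.channels]
    if missing:
        raise ChannelNotFoundError(missing[0], map_set.channels)
    cols = feature_columns(elements, aggregator)
    rows = []
    for roi in sorted(rois, key=lambda r: r.roi_id):
        record = {
            "scan_id": roi.scan_id,
            "roi_id": roi.roi_id,
            "area_px": roi_area(roi),
            "eccentricity": roi_eccentricity(roi),
        }
        for el, col in zip(elements, cols[2:]):
            record[col] = roi_element_stat(roi, map_set.channel(el), aggregator)
        rows.append(record)
    return pd.DataFrame(rows, columns=["scan_id", "roi_id"] + cols)


def feature_matrix(table: pd.DataFrame,
                   columns: Sequence[str] | None = None) -> np.ndarray:
    """Numeric n x f matrix from a feature table (identifier columns dropped)."""
    if columns is None:
        columns = [c for c in table.columns
                   if c not in ("scan_id", "roi_id", "true_label")]
    return table[list(columns)].to_numpy(dtype=np.float64)
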