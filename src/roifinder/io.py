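"""Reading and writing XRF scan maps and feature tables.

A coarse scan is a set of per-element fluorescence count maps sharing one
raster grid.  Scans are stored in a small documented HDF5 layout::

    /scan                    group with attributes:
        scan_id       str
        pixel_step_um float
        dwell_time_ms float
        origin_um     float pair (x, y)
    /scan/channels/<NAME>    one 2D float dataset per element channel

Feature tables are plain CSV with columns ``scan_id, roi_id, area_px,
eccentricity, <agg>_K, <agg>_P, ...`` (see :mod:`roifinder.features`).

Fitted count maps coming out of spectrum-fitting software can dip below
zero after background subtraction; negative input counts are clamped to 0
with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, FormatError

logger = logging.getLogger(__name__)

#: fixed identifier columns of a feature-table CSV
ID_COLUMNS = ("scan_id", "roi_id")
MORPHOLOGY_COLUMNS = ("area_px", "eccentricity")


@dataclass(frozen=True)
class ScanMetadata:
    """Acquisition metadata for one coarse scan.

    Parameters
    ----------
    scan_id : str
        Unique identifier of the scan.
    pixel_step : float
        Raster step size in µm (the coarse scans here use 0.25 µm).
    dwell_time : float
        Per-pixel exposure in ms; expected counts scale linearly with it.
    origin : tuple of float
        Stage coordinates (x, y) in µm of the top-left pixel center.
    shape : tuple of int
        Grid shape as (rows, cols).
    """

    scan_id: str
    pixel_step: float
    dwell_time: float
    origin: tuple[float, float]
    shape: tuple[int, int]

    def __post_init__(self):
        if self.pixel_step <= 0:
            raise ValueError("pixel_step must be > 0")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError("shape must be (rows, cols) with dims >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))


@dataclass
class ElementalMapSet:
    """Named per-element count grids for one coarse scan.

    ``channels`` is an ordered mapping of channel name (element symbol) to a
    2D float array of fluorescence counts; all grids share ``metadata.shape``
    and counts are non-negative (negatives are clamped with a warning).
    """

    metadata: ScanMetadata
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, grid in self.channels.items():
            arr = np.asarray(grid, dtype=np.float64)
            if arr.ndim != 2:
                raise FormatError(f"channel {name!r} is not a 2D grid")
            if arr.shape != self.metadata.shape:
                raise FormatError(
                    f"channel {name!r} shape {arr.shape} != metadata shape "
                    f"{self.metadata.shape}"
                )
            if np.any(arr < 0):
                logger.warning(
                    "channel %s of scan %s contains negative counts; clamping to 0",
                    name, self.metadata.scan_id,
                )
                arr = np.clip(arr, 0.0, None)
            clean[name] = arr
        self.channels = clean

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelNotFoundError(name, self.channels) from None

    def select(self, channel_names: Sequence[str]) -> "ElementalMapSet":
        """Subset of channels in the requested order."""
        return ElementalMapSet(
            metadata=self.metadata,
            channels={n: self.channel(n) for n in channel_names},
        )


def write_scan(map_set: ElementalMapSet, path) -> None:
    """Write a scan to the documented HDF5 layout (lossless for float64)."""
    if not map_set.channels:
        raise FormatError("map set has no channels; at least one is required")
    md = map_set.metadata
    with h5py.File(path, "w") as f:
        g = f.create_group("scan")
        g.attrs["scan_id"] = md.scan_id
        g.attrs["pixel_step_um"] = float(md.pixel_step)
        g.attrs["dwell_time_ms"] = float(md.dwell_time)
        g.attrs["origin_um"] = np.asarray(md.origin, dtype=np.float64)
        ch = g.create_group("channels")
        # h5py iterates groups alphabetically; record the caller's order
        ch.attrs["channel_order"] = list(map_set.channels)
        for name, grid in map_set.channels.items():
            ch.create_dataset(name, data=np.asarray(grid, dtype=np.float64))


def read_scan(path, channel_names: Sequence[str] | None = None) -> ElementalMapSet:
    """Read a scan written by :func:`write_scan`.

    With ``channel_names`` given, returns exactly those channels in that
    order; otherwise all stored channels in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "scan" not in f or "scan/channels" not in f:
            raise FormatError(f"{path} does not follow the /scan HDF5 layout")
        g = f["scan"]
        try:
            origin = tuple(np.asarray(g.attrs["origin_um"], dtype=float))
            ch = g["channels"]
            order = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in ch.attrs.get("channel_order", list(ch))]
            stored = {name: np.asarray(ch[name]) for name in order}
            if not stored:
                raise FormatError(f"{path} contains no channels")
            shapes = {a.shape for a in stored.values()}
            if len(shapes) != 1:
                raise FormatError(f"{path}: channel shapes differ: {sorted(shapes)}")
            md = ScanMetadata(
                scan_id=str(g.attrs["scan_id"]),
                pixel_step=float(g.attrs["pixel_step_um"]),
                dwell_time=float(g.attrs["dwell_time_ms"]),
                origin=origin,
                shape=shapes.pop(),
            )
        except KeyError as exc:
            raise FormatError(f"{path} missing required attribute: {exc}") from exc
    if channel_names is not None:
        missing = [n for n in channel_names if n not in stored]
        if missing:
            raise ChannelNotFoundError(missing[0], stored)
        stored = {n: stored[n] for n in channel_names}
    return ElementalMapSet(metadata=md, channels=stored)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with full float precision."""
    _check_feature_schema(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV; numeric round-trip is exact to 1e-12 rel."""
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed feature CSV {path}: {exc}") from exc
    _check_feature_schema(table)
    return table


def _check_feature_schema(table: pd.DataFrame) -> None:
    missing = [c for c in ID_COLUMNS + MORPHOLOGY_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing}")
    element_cols = [
        c for c in table.columns
        if c not in ID_COLUMNS + MORPHOLOGY_COLUMNS + ("true_label",)
    ]
    if not element_cols:
        raise FormatError("feature table has no element feature columns")


def read_maps_scan(path, channel_names: Sequence[str] | None = None,
                   *, pixel_step: float = 0.25, dwell_time: float = 100.0,
                   ) -> ElementalMapSet:
    """Best-effort adapter for MAPS-style fitted .h5 files.

    The internal layout of MAPS output is not publicly documented; this
    reader guesses the common arrangement (a channel-names vector plus a
    stacked ``(n_channels, rows, cols)`` counts array) and should be
    validated against real files before use.  It is excluded from the test
    gate for that reason.
    """
    candidates = [
        ("MAPS/channel_names", "MAPS/XRF_roi"),
        ("MAPS/channel_names", "MAPS/XRF_fits"),
        ("exchange/images_names", "exchange/images"),
    ]
    with h5py.File(path, "r") as f:
        for names_key, data_key in candidates:
            if names_key in f and data_key in f:
                names = [n.decode() if isinstance(n, bytes) else str(n)
                         for n in np.asarray(f[names_key])]
                stack = np.asarray(f[data_key], dtype=np.float64)
                break
        else:
            raise FormatError(
                f"{path}: no recognized MAPS-style layout "
                f"(tried {[c[1] for c in candidates]})"
            )
    channels = {name: stack[i] for i, name in enumerate(names)}
    md = ScanMetadata(
        scan_id=str(Path(path).stem),
        pixel_step=pixel_step,
        dwell_time=dwell_time,
        origin=(0.0, 0.0),
        shape=stack.shape[1:],
    )
    ms = ElementalMapSet(metadata=md, channels=channels)
    return ms.select(channel_names) if channel_names is not None else ms
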