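"""Synthetic coarse XRF scans with known ground truth.

Real beamline scans of the treated *E. coli* populations are not
distributable, so this module emulates them: elliptical cells with
treatment-type-specific elemental rate profiles on a flat background, small
speckle artifacts (1-8 px, which the downstream <= 8 px filter must
remove), and Poisson shot noise whose expected counts scale linearly with
dwell time relative to a 100 ms reference dwell.

The default rate profiles are invented magnitudes (no absolute count
scales are published for these scans) chosen to reproduce the qualitative
chemistry: healthy type A cells retain high intracellular K; ethanol
poisoning (type B) disrupts the inner membrane so K leaks out while Ca, Zn
and P are elevated; azide/copper-treated type C cells carry the highest K.
All rates are configurable via a YAML profile file.

Cells are filled ellipses rasterized by center-of-pixel inclusion, so area
and eccentricity have closed-form continuous counterparts for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.ndimage import binary_dilation

from .errors import ConfigError, PlacementError
from .io import ElementalMapSet, ScanMetadata
from .segmentation import ROI
from . import evaluation as _evaluation
from . import segmentation as _segmentation

#: dwell time (ms) at which the rate profiles are stated
REFERENCE_DWELL_MS = 100.0

#: elements every profile must cover (segmentation + feature channels)
REQUIRED_ELEMENTS = ("K", "P", "S", "Ca", "Zn", "Fe")

#: expected counts per pixel at the reference dwell
DEFAULT_BACKGROUND = {el: 2.0 for el in REQUIRED_ELEMENTS}
DEFAULT_PROFILES = {
    "A": {"K": 60.0, "P": 40.0, "S": 30.0, "Ca": 8.0, "Zn": 6.0, "Fe": 5.0},
    "B": {"K": 15.0, "P": 55.0, "S": 30.0, "Ca": 30.0, "Zn": 20.0, "Fe": 5.0},
    "C": {"K": 90.0, "P": 40.0, "S": 30.0, "Ca": 10.0, "Zn": 8.0, "Fe": 5.0},
}

#: cell semi-axis ranges in pixels at the 0.25 µm coarse step
#: (E. coli is roughly 2 x 0.8 µm, so ~4 x 1.6 px half-sizes)
DEFAULT_MAJOR_RANGE = (3.5, 6.0)
DEFAULT_MINOR_RANGE = (1.5, 2.75)

#: added rate for artifact speckles (per composite channel, ref dwell)
ARTIFACT_RATE = 80.0

_MAX_PLACEMENT_TRIES = 500


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth description of one planted cell."""

    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (major, minor), pixels
    orientation: float  # radians, major axis vs the row axis
    type_label: str
    intensities: Mapping[str, float]  # expected counts/px at reference dwell

    def __post_init__(self):
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("need a_major >= a_minor > 0")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be >= 0")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """(n, 2) array of pixel centers inside the ellipse."""
        r0, c0 = self.center
        a, b = self.semi_axes
        reach = int(math.ceil(a)) + 1
        rows = np.arange(max(0, int(r0) - reach),
                         min(shape[0], int(r0) + reach + 1))
        cols = np.arange(max(0, int(c0) - reach),
                         min(shape[1], int(c0) + reach + 1))
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        dr, dc = rr - r0, cc - c0
        u = dr * math.cos(self.orientation) + dc * math.sin(self.orientation)
        v = -dr * math.sin(self.orientation) + dc * math.cos(self.orientation)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return np.column_stack([rr[inside], cc[inside]])


@dataclass
class GroundTruth:
    """Everything the simulator planted, for parameter-recovery checks."""

    cell_specs: list[CellSpec]
    cell_pixels: list[np.ndarray]  # one (n, 2) array per cell
    true_mask: np.ndarray
    labels: list[str]
    artifact_pixels: np.ndarray  # (n, 2) array of speckle coordinates
    shape: tuple[int, int] = field(init=False)

    def __post_init__(self):
        self.shape = self.true_mask.shape

    def cell_mask(self, i: int) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        px = self.cell_pixels[i]
        m[px[:, 0], px[:, 1]] = True
        return m


def load_profiles(path) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Load a YAML profile config: ``background`` rates and per-type rates."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    background = {str(k): float(v) for k, v in cfg.get("background", {}).items()}
    profiles = {str(t): {str(k): float(v) for k, v in rates.items()}
                for t, rates in cfg.get("types", {}).items()}
    _validate_profiles(background or DEFAULT_BACKGROUND, profiles or DEFAULT_PROFILES)
    return background or DEFAULT_BACKGROUND, profiles or DEFAULT_PROFILES


def _validate_profiles(background: Mapping[str, float],
                       profiles: Mapping[str, Mapping[str, float]]) -> None:
    known = set(background)
    missing = [el for el in REQUIRED_ELEMENTS if el not in known]
    if missing:
        raise ConfigError(f"background profile missing elements: {missing}")
    for t, rates in profiles.items():
        unknown = [el for el in rates if el not in known]
        if unknown:
            raise ConfigError(
                f"type {t!r} profile has unknown element(s): {unknown}")
        # construction guarantee: cells must rise above background everywhere
        weak = [el for el, v in rates.items() if v <= 0]
        if weak:
            raise ConfigError(
                f"type {t!r} has non-positive cell rates for: {weak}")


def _place_cells(shape, n_cells_by_type, rng, major_range, minor_range,
                 profiles, margin: int = 2):
    occupied = np.zeros(shape, dtype=bool)
    specs, pixels = [], []
    for type_label, n in n_cells_by_type.items():
        if type_label not in profiles:
            raise ConfigError(f"no profile for cell type {type_label!r}")
        for _ in range(n):
            for _attempt in range(_MAX_PLACEMENT_TRIES):
                a = rng.uniform(*major_range)
                b = rng.uniform(*minor_range)
                a, b = max(a, b), min(a, b)
                pad = a + 1
                if shape[0] - 2 * pad <= 0 or shape[1] - 2 * pad <= 0:
                    continue
                center = (rng.uniform(pad, shape[0] - pad),
                          rng.uniform(pad, shape[1] - pad))
                spec = CellSpec(center=center, semi_axes=(a, b),
                                orientation=rng.uniform(0, math.pi),
                                type_label=type_label,
                                intensities=profiles[type_label])
                px = spec.rasterize(shape)
                if px.size == 0:
                    continue
                cell_mask = np.zeros(shape, dtype=bool)
                cell_mask[px[:, 0], px[:, 1]] = True
                grown = binary_dilation(cell_mask, iterations=margin)
                if (grown & occupied).any():
                    continue
                occupied |= grown
                specs.append(spec)
                pixels.append(px)
                break
            else:
                raise PlacementError(
                    f"could not place cell {len(specs) + 1} of type "
                    f"{type_label} in shape {shape} after "
                    f"{_MAX_PLACEMENT_TRIES} tries")
    return specs, pixels, occupied


def _plant_artifacts(shape, occupied, artifact_count, rng):
    """Random connected speckles of 1-8 px on free background."""
    coords = []
    free = ~binary_dilation(occupied, iterations=2)
    for _ in range(artifact_count):
        size = int(rng.integers(1, 9))
        for _attempt in range(_MAX_PLACEMENT_TRIES):
            r = int(rng.integers(1, shape[0] - 1))
            c = int(rng.integers(1, shape[1] - 1))
            blob = {(r, c)}
            while len(blob) < size:
                br, bc = list(blob)[int(rng.integers(len(blob)))]
                dr, dc = rng.integers(-1, 2, size=2)
                nr, nc = br + int(dr), bc + int(dc)
                if 0 <= nr < shape[0] and 0 <= nc < shape[1]:
                    blob.add((nr, nc))
            if all(free[p] for p in blob):
                coords.extend(sorted(blob))
                for p in blob:
                    free[p] = False
                break
    if coords:
        return np.array(coords, dtype=int)
    return np.empty((0, 2), dtype=int)


def generate_scan(shape: tuple[int, int],
                  n_cells_by_type: Mapping[str, int],
                  dwell_time: float = REFERENCE_DWELL_MS,
                  profile_config: tuple[Mapping, Mapping] | None = None,
                  artifact_count: int = 0,
                  seed: int = 0,
                  noise_seed: int | None = None,
                  scan_id: str | None = None,
                  pixel_step: float = 0.25,
                  origin: tuple[float, float] = (0.0, 0.0),
                  major_range=DEFAULT_MAJOR_RANGE,
                  minor_range=DEFAULT_MINOR_RANGE,
                  ) -> tuple[ElementalMapSet, GroundTruth]:
    """Simulate one coarse scan and its ground truth.

    Each pixel's count in each channel is a Poisson variate with mean
    ``(background_rate + cell_rate_if_inside) * dwell_time / 100 ms``;
    artifact speckles add a high rate to the four composite channels.
    Deterministic for a fixed seed.  ``noise_seed`` re-draws the shot noise
    on an identical scene (cell placement stays governed by ``seed``).
    """
    if profile_config is None:
        background, profiles = DEFAULT_BACKGROUND, DEFAULT_PROFILES
    else:
        background, profiles = profile_config
        _validate_profiles(background, profiles)
    rng = np.random.default_rng(seed)
    specs, pixels, _ = _place_cells(shape, dict(n_cells_by_type), rng,
                                    major_range, minor_range, profiles)
    true_mask = np.zeros(shape, dtype=bool)
    for px in pixels:
        true_mask[px[:, 0], px[:, 1]] = True
    artifacts = _plant_artifacts(shape, true_mask, artifact_count, rng)

    noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
    scale = float(dwell_time) / REFERENCE_DWELL_MS
    channels: dict[str, np.ndarray] = {}
    for el in background:
        rate = np.full(shape, background[el], dtype=np.float64)
        for spec, px in zip(specs, pixels):
            rate[px[:, 0], px[:, 1]] += spec.intensities.get(el, 0.0)
        if el in _segmentation.DEFAULT_COMPOSITE_CHANNELS and len(artifacts):
            rate[artifacts[:, 0], artifacts[:, 1]] += ARTIFACT_RATE
        channels[el] = noise_rng.poisson(rate * scale).astype(np.float64)

    md = ScanMetadata(
        scan_id=scan_id or f"sim-{seed}",
        pixel_step=pixel_step,
        dwell_time=float(dwell_time),
        origin=origin,
        shape=shape,
    )
    gt = GroundTruth(
        cell_specs=specs,
        cell_pixels=pixels,
        true_mask=true_mask,
        labels=[s.type_label for s in specs],
        artifact_pixels=artifacts,
    )
    return ElementalMapSet(metadata=md, channels=channels), gt


def expected_snr_ordering(scans: Sequence[ElementalMapSet],
                          true_mask: np.ndarray) -> list[float]:
    """SNR of each scan's composite against the true cell mask, in order."""
    if len(scans) < 1:
        raise ValueError("need at least one scan")
    shapes = {s.metadata.shape for s in scans}
    if len(shapes) != 1 or shapes.pop() != true_mask.shape:
        raise ValueError("scans and mask must share one shape")
    return [
        _evaluation.snr(_segmentation.composite_map(s), true_mask)
        for s in scans
    ]


def match_rois_to_cells(rois: Sequence[ROI], gt: GroundTruth,
                        iou_threshold: float = 0.5) -> dict[int, int]:
    """Greedy IoU matching of detected ROIs to planted cells.

    Returns a mapping cell index -> roi index for every planted cell whose
    best-overlap ROI exceeds the IoU threshold.
    """
    matches: dict[int, int] = {}
    roi_sets = [set(map(tuple, r.pixels)) for r in rois]
    for i, px in enumerate(gt.cell_pixels):
        cell = set(map(tuple, px))
        best_j, best_iou = -1, 0.0
        for j, rset in enumerate(roi_sets):
            inter = len(cell & rset)
            if inter == 0:
                continue
            iou = inter / len(cell | rset)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_iou > iou_threshold:
            matches[i] = best_j
    return matches


def sample_feature_table(n_cells_by_type: Mapping[str, int],
                         dwell_time: float = REFERENCE_DWELL_MS,
                         profile_config: tuple[Mapping, Mapping] | None = None,
                         seed: int = 0,
                         elements: Sequence[str] = ("K", "P", "Ca", "Zn", "Fe"),
                         major_range=DEFAULT_MAJOR_RANGE,
                         minor_range=DEFAULT_MINOR_RANGE,
                         ) -> "pd.DataFrame":
    """Feature table drawn directly from the generative cell model.

    Rasterizes each cell on its own small grid and draws the per-pixel
    Poisson counts, yielding exactly the requested number of rows per type
    with a ``true_label`` column — the population-scale counterpart of
    running the full segmentation pipeline, without needing a scan large
    enough to hold every cell.
    """
    import pandas as pd
    from skimage.measure import regionprops

    if profile_config is None:
        background, profiles = DEFAULT_BACKGROUND, DEFAULT_PROFILES
    else:
        background, profiles = profile_config
        _validate_profiles(background, profiles)
    rng = np.random.default_rng(seed)
    scale = float(dwell_time) / REFERENCE_DWELL_MS
    rows = []
    for type_label, n in n_cells_by_type.items():
        if type_label not in profiles:
            raise ConfigError(f"no profile for cell type {type_label!r}")
        for i in range(n):
            a = rng.uniform(*major_range)
            b = rng.uniform(*minor_range)
            a, b = max(a, b), min(a, b)
            side = 2 * (int(math.ceil(a)) + 2)
            spec = CellSpec(center=(side / 2, side / 2), semi_axes=(a, b),
                            orientation=rng.uniform(0, math.pi),
                            type_label=type_label,
                            intensities=profiles[type_label])
            px = spec.rasterize((side, side))
            local = np.zeros((side, side), dtype=np.uint8)
            local[px[:, 0], px[:, 1]] = 1
            (region,) = regionprops(local)
            record = {
                "scan_id": f"synthetic-{type_label}",
                "roi_id": i,
                "area_px": len(px),
                "eccentricity": float(region.eccentricity),
            }
            for el in elements:
                rate = (background[el] + profiles[type_label].get(el, 0.0)) * scale
                counts = rng.poisson(rate, size=len(px))
                record[f"max_{el}"] = float(counts.max())
            record["true_label"] = type_label
            rows.append(record)
    return pd.DataFrame(rows)
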