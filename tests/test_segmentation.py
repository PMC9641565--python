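"""Composite construction, Otsu thresholding and ROI extraction."""

import numpy as np
import pytest

from roifinder.errors import ChannelNotFoundError, DegenerateImageError
from roifinder.io import ScanMetadata
from roifinder.segmentation import (binarize, composite_map, extract_rois,
                                    otsu_threshold, segment_scan)
from roifinder.synthetic import generate_scan, match_rois_to_cells


def brute_force_otsu(image, n_bins=256):
    """Exhaustive search over all histogram bin-edge thresholds.

    Returns (threshold, variance_by_threshold): the maximizing bin edge and
    the achieved between-class variance for every candidate edge.
    """
    lo, hi = image.min(), image.max()
    counts, edges = np.histogram(image.ravel(), bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var, by_edge = None, -1.0, {}
    for split in range(1, n_bins):  # class 0 = bins [0, split)
        w0, w1 = counts[:split].sum(), counts[split:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:split] * centers[:split]).sum() / w0
        mu1 = (counts[split:] * centers[split:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        by_edge[edges[split]] = var
        if var > best_var:  # strict: keeps the lower threshold on ties
            best_var, best_t = var, edges[split]
    return best_t, by_edge


class TestCompositeMap:
    def test_sum_of_named_channels(self, map_set_factory, rng):
        grids = {el: rng.uniform(0, 9, (16, 16)) for el in ("K", "P", "S", "Ca")}
        ms = map_set_factory(grids)
        comp = composite_map(ms)
        # brute-force per-pixel addition oracle
        for r in range(16):
            for c in range(16):
                expected = sum(grids[el][r, c] for el in ("K", "P", "S", "Ca"))
                assert comp[r, c] == pytest.approx(expected)

    def test_constant_grids_additivity(self, map_set_factory):
        grids = {el: np.full((4, 4), v) for el, v in
                 zip(("K", "P", "S", "Ca"), (1.0, 2.0, 3.0, 4.0))}
        np.testing.assert_array_equal(composite_map(map_set_factory(grids)),
                                      np.full((4, 4), 10.0))

    def test_all_zero(self, map_set_factory):
        grids = {el: np.zeros((4, 4)) for el in ("K", "P", "S", "Ca")}
        assert composite_map(map_set_factory(grids)).sum() == 0

    def test_missing_channel(self, map_set_factory):
        ms = map_set_factory({"K": np.ones((4, 4))})
        with pytest.raises(ChannelNotFoundError, match="P"):
            composite_map(ms)


class TestOtsuThreshold:
    def test_two_level_image_separates_classes(self):
        image = np.array([[0.0] * 8, [10.0] * 8] * 4)
        t = otsu_threshold(image)
        assert 0 < t < 10

    @staticmethod
    def _assert_optimal(image):
        """The returned edge achieves the exhaustive-search maximum and
        induces the same pixel partition (plateaus of empty bins make the
        maximizing edge non-unique, but never the classification)."""
        t = otsu_threshold(image)
        t_oracle, by_edge = brute_force_otsu(image)
        best = max(by_edge.values())
        nearest_edge = min(by_edge, key=lambda e: abs(e - t))
        assert nearest_edge == pytest.approx(t)
        assert by_edge[nearest_edge] == pytest.approx(best, rel=1e-9)
        np.testing.assert_array_equal(image > t, image > t_oracle)
        return t

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        image = np.concatenate([rng.normal(10, 2, 600),
                                rng.normal(40, 5, 400)]).reshape(40, 25)
        self._assert_optimal(image)

    def test_single_foreground_pixel(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 1, (100, 100))
        image[50, 50] = 100.0
        t = self._assert_optimal(image)
        assert t < 100.0

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 3.0))


class TestBinarize:
    def test_constant_image_background_only(self, caplog):
        with caplog.at_level("WARNING"):
            seg = binarize(np.full((8, 8), 5.0))
        assert not seg.mask.any()
        assert "background-only" in caplog.text

    def test_bright_square_recovered(self):
        image = np.zeros((20, 20))
        image[5:10, 5:10] = 100.0
        seg = binarize(image)
        square = np.zeros((20, 20), dtype=bool)
        square[5:10, 5:10] = True
        # 3x3 median erodes only the 4 corners of a 5x5 square
        assert (seg.mask & ~square).sum() == 0
        assert seg.mask.sum() >= 9

    def test_threshold_is_1p25_times_otsu(self, rng):
        image = rng.uniform(0, 1, (30, 30))
        image[5:15, 5:15] += 20
        seg = binarize(image)
        assert seg.threshold_used / seg.otsu_raw == pytest.approx(1.25)

    def test_idempotent_on_own_mask(self, rng):
        image = rng.uniform(0, 1, (30, 30))
        image[5:15, 5:15] += 20
        first = binarize(image).mask
        second = binarize(first.astype(float)).mask
        np.testing.assert_array_equal(first, second)


def flood_fill_components(mask):
    """Independent 8-connected component enumeration by explicit flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0]
                                    and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


MD = ScanMetadata("scan", 0.25, 100.0, (100.0, 200.0), (64, 64))


class TestExtractRois:
    def test_empty_mask(self):
        assert extract_rois(np.zeros((64, 64), dtype=bool), MD) == []

    def test_eight_pixel_component_rejected_nine_kept(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[2:4, 2:6] = True     # 8 px -> rejected
        mask[10:13, 10:13] = True  # 9 px -> kept
        rois = extract_rois(mask, MD)
        assert len(rois) == 1
        assert rois[0].n_pixels == 9

    def test_rejected_sizes_match_flood_fill_oracle(self):
        mask = np.zeros((80, 80), dtype=bool)
        row = 2
        for size in range(1, 21):  # horizontal bars of 1..20 px
            mask[row, 2:2 + size] = True
            row += 3
        rois = extract_rois(mask, MD)
        kept_sizes = sorted(r.n_pixels for r in rois)
        oracle = sorted(len(c) for c in flood_fill_components(mask)
                        if len(c) > 8)
        assert kept_sizes == oracle == list(range(9, 21))

    def test_rois_disjoint_and_within_mask(self, rng):
        mask = rng.uniform(0, 1, (64, 64)) > 0.7
        rois = extract_rois(mask, MD)
        seen = set()
        for roi in rois:
            px = set(map(tuple, roi.pixels))
            assert not (px & seen)
            seen |= px
            assert all(mask[r, c] for r, c in px)
            r0, c0, r1, c1 = roi.bbox
            rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
            assert (rows.min(), cols.min()) == (r0, c0)
            assert (rows.max() + 1, cols.max() + 1) == (r1, c1)

    def test_roi_ids_in_raster_order(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[40:44, 2:6] = True
        mask[2:6, 40:44] = True
        rois = extract_rois(mask, MD)
        assert [r.roi_id for r in rois] == [0, 1]
        assert rois[0].bbox[0] < rois[1].bbox[0]  # first = topmost component

    def test_stage_centroid_arithmetic(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:13, 20:23] = True  # centroid (11, 21)
        (roi,) = extract_rois(mask, MD)
        assert roi.centroid_px == pytest.approx((11.0, 21.0))
        assert roi.centroid_um == pytest.approx((100.0 + 21 * 0.25,
                                                 200.0 + 11 * 0.25))


class TestPlantedCellRecovery:
    def test_noise_free_cells_recovered_with_high_iou(self, map_set_factory):
        # deterministic scene: rates as exact counts, no Poisson draw
        from roifinder import synthetic
        rng = np.random.default_rng(7)
        specs, pixels, _ = synthetic._place_cells(
            (96, 96), {"A": 8}, rng, synthetic.DEFAULT_MAJOR_RANGE,
            synthetic.DEFAULT_MINOR_RANGE, synthetic.DEFAULT_PROFILES)
        channels = {}
        for el in ("K", "P", "S", "Ca"):
            grid = np.full((96, 96), synthetic.DEFAULT_BACKGROUND[el])
            for spec, px in zip(specs, pixels):
                grid[px[:, 0], px[:, 1]] += spec.intensities[el]
            channels[el] = grid
        ms = map_set_factory(channels)
        _, rois = segment_scan(ms)
        assert len(rois) == 8
        roi_sets = [set(map(tuple, r.pixels)) for r in rois]
        for px in pixels:
            cell = set(map(tuple, px))
            best = max(len(cell & s) / len(cell | s) for s in roi_sets)
            assert best >= 0.8

    def test_planted_cells_and_artifact_rejection(self):
        ms, gt = generate_scan((128, 128), {"A": 10}, dwell_time=100.0,
                               artifact_count=6, seed=42)
        _, rois = segment_scan(ms)
        assert len(rois) == 10
        matches = match_rois_to_cells(rois, gt, iou_threshold=0.5)
        assert len(matches) == 10
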