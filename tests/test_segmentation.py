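"""Otsu thresholding, half-splitting, pillar detection, V-shape masking
and tissue extraction, each checked against an independent oracle where
one exists."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pillartrack as pt
from pillartrack import errors
from pillartrack.segmentation import (binarize, detect_pillar, extract_tissue,
                                      mask_v_shape, moment_centroid,
                                      otsu_threshold, split_halves)

from conftest import render_disk


def brute_force_otsu(frame: np.ndarray) -> int:
    """Independent exhaustive between-class-variance scan over all 256
    candidate thresholds (smallest maximizer)."""
    hist = np.bincount(frame.ravel(), minlength=256).astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[:t + 1].sum()
        w1 = hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (np.arange(t + 1) * hist[:t + 1]).sum() / w0
        m1 = (np.arange(t + 1, 256) * hist[t + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_bimodal_frame_separates_classes(self):
        frame = np.full((20, 20), 30, dtype=np.uint8)
        frame[:, 10:] = 220
        t = otsu_threshold(frame)
        assert 30 <= t < 220
        assert np.array_equal(binarize(frame).mask, frame > t)

    def test_blurred_bimodal_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(60, 10, 2000),
                               rng.normal(190, 10, 2000)])
        frame = np.clip(vals, 0, 255).astype(np.uint8).reshape(40, 100)
        assert abs(otsu_threshold(frame) - brute_force_otsu(frame)) <= 3

    def test_matches_skimage_class_separation(self):
        # independent library oracle: both must split the pixel classes
        # identically on a clean bimodal frame
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(1)
        frame = np.where(rng.random((50, 50)) < 0.4, 40, 210).astype(np.uint8)
        ours = otsu_threshold(frame)
        theirs = threshold_otsu(frame)
        assert np.array_equal(frame > ours, frame > theirs)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 255), st.integers(1, 30)),
                    min_size=2, max_size=12,
                    unique_by=lambda lc: lc[0]))
    def test_threshold_lies_strictly_inside_value_range(self, level_counts):
        # for any non-degenerate histogram the threshold must separate
        # the extremes: min(values) <= t < max(values)
        frame = np.repeat([lv for lv, _ in level_counts],
                          [c for _, c in level_counts]).astype(np.uint8)
        frame = frame.reshape(1, -1)
        t = otsu_threshold(frame)
        assert frame.min() <= t < frame.max()
        mask = frame > t
        assert mask.any() and not mask.all()

    def test_constant_frame_is_degenerate(self):
        with pytest.raises(errors.DegenerateHistogramError):
            otsu_threshold(np.full((10, 10), 7, dtype=np.uint8))

    def test_manual_override_bypasses_otsu_and_is_recorded(self):
        frame = np.full((10, 10), 7, dtype=np.uint8)  # otsu would raise
        bf = binarize(frame, threshold=100)
        assert bf.manual_override and bf.threshold_used == 100
        auto = binarize(np.where(np.eye(10), 200, 7).astype(np.uint8))
        assert not auto.manual_override


class TestSplitHalves:
    @pytest.mark.parametrize("width,expected", [(738, (369, 369)),
                                                (5, (2, 3)), (4, (2, 2))])
    def test_split_widths(self, width, expected):
        left, right = split_halves(np.zeros((4, width)))
        assert (left.shape[1], right.shape[1]) == expected

    def test_partition_is_lossless(self):
        frame = np.random.default_rng(0).random((6, 11))
        left, right = split_halves(frame)
        assert np.array_equal(np.hstack([left, right]), frame)

    def test_too_narrow_rejected(self):
        with pytest.raises(errors.PillarTrackError):
            split_halves(np.zeros((4, 3)))


class TestDetectPillar:
    def test_disk_centroid_and_radius_recovered(self, circle_config):
        half = render_disk((120, 160), (60.0, 80.0), 12.0)
        rng = np.random.default_rng(4)
        for _ in range(5):  # speckle blobs of <= 4 px2
            r, c = rng.integers(5, 115), rng.integers(5, 155)
            half[r:r + 2, c:c + 2] = True
        shape = detect_pillar(half, circle_config)
        assert shape.centroid == pytest.approx((60.0, 80.0), abs=0.5)
        assert shape.params["radius"] == pytest.approx(12.0, abs=1.0)
        assert abs(shape.contour_area - np.pi * shape.params["radius"] ** 2) \
            <= 0.15 * shape.contour_area

    def test_nearest_area_blob_selected(self):
        cfg = pt.PlatformConfig(pillar_kind="circle", E=1e6, L=300, a=250,
                                diameter_um=2 * np.sqrt(1250 / np.pi),
                                um_per_px=1.0, fps=100)
        half = np.zeros((100, 120), dtype=bool)
        half[10:40, 10:50] = True      # 1200 px2
        half[60:80, 60:80] = True      # 400 px2
        shape = detect_pillar(half, cfg)
        assert shape.contour_area == pytest.approx(1200, abs=1)

    def test_empty_half_raises(self, circle_config):
        with pytest.raises(errors.PillarNotFoundError):
            detect_pillar(np.zeros((50, 50), dtype=bool), circle_config)

    def test_out_of_band_blob_raises(self, circle_config):
        half = np.zeros((80, 80), dtype=bool)
        half[10:70, 10:70] = True  # 3600 px2 >> 3x expected 452 px2
        with pytest.raises(errors.PillarNotFoundError, match="expected"):
            detect_pillar(half, circle_config)


def brute_force_best_window(component, hh, ww):
    """Oracle: literally try every placement of an hh x ww window."""
    h, w = component.shape
    best = (-1, None)
    for r in range(-hh + 1, h):
        for c in range(-ww + 1, w):
            win = component[max(r, 0):r + hh, max(c, 0):c + ww]
            ov = int(win.sum())
            if ov > best[0]:
                best = (ov, (r, c))
    return best


class TestMaskVShape:
    def make_fused(self, wedge_px2=300):
        """40 (rows) x 24 (cols) rectangle with a triangular wedge fused
        to its right (inner) face."""
        comp = np.zeros((90, 120), dtype=bool)
        comp[20:60, 30:54] = True   # 40 x 24 = 960 px2, center (39.5, 41.5)
        if wedge_px2 > 0:
            wh, wl = 24, int(round(2 * wedge_px2 / 24))
            rr, cc = np.mgrid[0:90, 0:120]
            u = cc - 54
            comp |= ((u >= 0) & (u < wl)
                     & (np.abs(rr - 39.5) <= wh / 2 * (1 - u / wl)))
        return comp

    def test_wedge_removed_area_and_centroid_recovered(self):
        comp = self.make_fused(300)
        out = mask_v_shape(comp, (40, 24))
        assert abs(out.sum() - 960) / 960 <= 0.05
        assert moment_centroid(out) == pytest.approx((39.5, 41.5), abs=1.0)

    def test_agrees_with_exhaustive_overlap_oracle(self):
        comp = self.make_fused(300)
        best_ov, _ = brute_force_best_window(comp, 40, 24)
        out = mask_v_shape(comp, (40, 24))
        assert out.sum() == best_ov

    def test_clean_rectangle_survives(self):
        comp = self.make_fused(0)
        out = mask_v_shape(comp, (40, 24))
        assert np.array_equal(out, comp)

    def test_wedge_larger_than_rectangle_still_clipped_to_tip_size(self):
        comp = self.make_fused(1400)
        out = mask_v_shape(comp, (40, 24))
        best_ov, _ = brute_force_best_window(comp, 40, 24)
        assert out.sum() == best_ov
        assert out.sum() <= 40 * 24

    def test_masking_never_increases_area(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            comp = np.zeros((60, 60), dtype=bool)
            r, c = rng.integers(5, 25, 2)
            comp[r:r + rng.integers(10, 30), c:c + rng.integers(10, 30)] = True
            comp |= rng.random((60, 60)) > 0.97
            before = comp.sum()
            try:
                out = mask_v_shape(comp, (15, 10))
            except errors.VShapeMaskingError:
                continue
            assert out.sum() <= before
            assert not (out & ~comp).any()

    def test_insufficient_overlap_raises(self):
        comp = np.zeros((40, 40), dtype=bool)
        comp[10, 10:14] = True   # a 4-px sliver vs a 20x20 expectation
        with pytest.raises(errors.VShapeMaskingError):
            mask_v_shape(comp, (20, 20))


class TestExtractTissue:
    def build_frame(self, circle_config):
        """Bright field, dark elliptical tissue, two bright pillar disks."""
        frame = np.full((160, 320), 200, dtype=np.uint8)
        rr, cc = np.mgrid[0:160, 0:320]
        tissue = ((cc - 160) / 130.0) ** 2 + ((rr - 80) / 55.0) ** 2 <= 1
        frame[tissue] = 50
        for c in (100, 220):
            frame[(rr - 80) ** 2 + (cc - c) ** 2 <= 12 ** 2] = 230
        return frame, tissue

    def test_area_excludes_pillars(self, circle_config):
        frame, tissue_truth = self.build_frame(circle_config)
        det = pt.segment_frame(frame, circle_config)
        expected = tissue_truth.sum() - 2 * np.pi * 12 ** 2
        assert det.tissue.area_px2 == pytest.approx(expected, rel=0.05)

    def test_all_bright_frame_has_no_tissue(self, circle_config):
        binary = binarize(np.full((50, 100), 220, dtype=np.uint8),
                          threshold=100)
        fake = pt.PillarShape(kind="circle", centroid=(25, 25),
                              params={"radius": 5}, contour_area=78)
        with pytest.raises(errors.TissueNotFoundError):
            extract_tissue(binary, (fake, fake), circle_config)

    def test_um_scaling_is_quadratic(self, circle_config):
        import dataclasses
        frame, _ = self.build_frame(circle_config)
        cfg2 = dataclasses.replace(circle_config, um_per_px=2.0,
                                   diameter_um=48.0)
        det1 = pt.segment_frame(frame, circle_config)
        det2 = pt.segment_frame(frame, cfg2)
        assert det2.tissue.area_um2 == pytest.approx(
            4 * det2.tissue.area_px2)
        assert det1.tissue.area_um2 == pytest.approx(det1.tissue.area_px2)
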