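import numpy as np
import pytest

from synedgews import AcquisitionConfig, ParameterError
from synedgews.preprocess import preprocess
from synedgews.segment import (ROI, compute_gradient, compute_size_range,
                               filter_by_size, morph_cleanup, refine_contour,
                               rough_segment, segment, split_watershed,
                               threshold_schedule)
from synedgews import fixtures
from synedgews.simulate import generate_puncta_image


def make_roi(mask, label=1):
    rows, cols = np.nonzero(mask)
    return ROI(label=label, pixels=np.column_stack([rows, cols]),
               centroid=(rows.mean(), cols.mean()), area_px=rows.size)


class TestSizeRange:
    def test_stated_optics_example(self):
        cfg = AcquisitionConfig(camera_pixel_size_um=10, binning=2, magnification=60,
                                min_diameter_um=0.5, max_diameter_um=2.0)
        assert compute_size_range(cfg) == (2, 28)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ParameterError):
            compute_size_range(AcquisitionConfig(
                camera_pixel_size_um=20, binning=4, magnification=10,
                min_diameter_um=0.5, max_diameter_um=0.6))

    def test_binning_shrinks_pixel_areas(self):
        base = dict(camera_pixel_size_um=10, magnification=60,
                    min_diameter_um=0.5, max_diameter_um=2.0)
        _, max1 = compute_size_range(AcquisitionConfig(binning=1, **base))
        _, max2 = compute_size_range(AcquisitionConfig(binning=2, **base))
        assert max2 < max1


class TestGradient:
    def test_constant_image_has_zero_gradient(self):
        assert not compute_gradient(np.full((10, 10), 3.0)).any()

    def test_vertical_step_peaks_on_step_columns(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        g = compute_gradient(img)
        # standard Sobel on a unit step: |Gx| = 4 on the two step columns
        assert np.allclose(g[5, 7:9], 4.0)
        assert not g[:, :6].any() and not g[:, 10:].any()

    def test_magnitude_rotation_equivariant(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        g = compute_gradient(img)
        g_rot = compute_gradient(np.rot90(img))
        assert np.allclose(np.rot90(g), g_rot, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError):
            compute_gradient(np.zeros((2, 5)))


class TestThresholdSchedule:
    def test_geometric_decay(self, rng, acq):
        g = rng.uniform(0, 1, (64, 64))
        t0 = threshold_schedule(g, acq, 0)
        t1 = threshold_schedule(g, acq, 1)
        assert np.isclose(t1, t0 * acq.gradient_decay)
        assert t1 < t0

    def test_quantile_against_uniform_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0, 1, (500, 500))
        cfg = AcquisitionConfig(gradient_quantile_start=0.95)
        assert abs(threshold_schedule(g, cfg, 0) - 0.95) < 0.01

    def test_all_zero_gradient_yields_zero(self, acq):
        assert threshold_schedule(np.zeros((10, 10)), acq, 0) == 0.0

    def test_iteration_out_of_range_rejected(self, acq):
        with pytest.raises(ParameterError):
            threshold_schedule(np.ones((5, 5)), acq, acq.n_iterations)


class TestRoughSegment:
    def test_closed_ring_fills_to_disc(self):
        g = np.zeros((32, 32))
        yy, xx = np.indices(g.shape)
        r = np.hypot(yy - 16, xx - 16)
        g[(r > 5) & (r < 7)] = 1.0
        filled = rough_segment(g, 0.5)
        assert filled[16, 16]
        assert filled[(r <= 5)].all()

    def test_empty_edges_give_empty_map(self):
        assert not rough_segment(np.zeros((16, 16)), 0.5).any()

    def test_two_rings_give_two_components(self):
        from scipy import ndimage
        g = np.zeros((32, 64))
        yy, xx = np.indices(g.shape)
        for cx in (16, 48):
            r = np.hypot(yy - 16, xx - cx)
            g[(r > 4) & (r < 6)] = 1.0
        filled = rough_segment(g, 0.5)
        assert ndimage.label(filled)[1] == 2


class TestSplitWatershed:
    @staticmethod
    def dumbbell(sigma=2.5, dist_sigma=2.5, shape=(40, 48)):
        yy, xx = np.indices(shape, dtype=float)
        c1 = (20.0, 24.0 - dist_sigma * sigma / 2)
        c2 = (20.0, 24.0 + dist_sigma * sigma / 2)
        img = (np.exp(-((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2) / (2 * sigma ** 2))
               + np.exp(-((yy - c2[0]) ** 2 + (xx - c2[1]) ** 2) / (2 * sigma ** 2)))
        return img, c1, c2

    def test_single_punctum_not_split(self):
        yy, xx = np.indices((32, 32), dtype=float)
        img = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 8.0)
        regions = img > 0.1
        labels = split_watershed(regions, img)
        assert len(np.unique(labels)) == 2  # background + one label

    def test_dumbbell_split_into_two_at_saddle(self):
        img, c1, c2 = self.dumbbell()
        regions = img > 0.05
        labels = split_watershed(regions, img)
        l1 = labels[int(c1[0]), int(round(c1[1]))]
        l2 = labels[int(c2[0]), int(round(c2[1]))]
        assert l1 != 0 and l2 != 0 and l1 != l2
        # split runs near the saddle: every pixel is labeled with its nearest center
        rows, cols = np.nonzero(labels)
        for r, c, lab in zip(rows, cols, labels[rows, cols]):
            d1 = (r - c1[0]) ** 2 + (c - c1[1]) ** 2
            d2 = (r - c2[0]) ** 2 + (c - c2[1]) ** 2
            nearest = l1 if d1 < d2 else l2
            if abs(d1 - d2) > 4:  # skip the ambiguous saddle band
                assert lab == nearest

    def test_close_markers_merged_by_size_prior(self):
        img, c1, c2 = self.dumbbell(sigma=1.0, dist_sigma=2.5)
        regions = img > 0.05
        labels = split_watershed(regions, img, min_marker_sep=4.0)
        assert len(np.unique(labels)) == 2  # merged: one label only

    def test_empty_region_map(self):
        assert not split_watershed(np.zeros((8, 8), bool), np.zeros((8, 8))).any()


class TestRefineContour:
    def test_uniform_region_is_fixed_point(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        img = np.where(mask, 1.0, 0.0)
        assert np.array_equal(refine_contour(mask, img), mask)

    def test_dim_rim_removed_bright_core_kept(self):
        core = np.zeros((12, 12), bool)
        core[4:8, 4:8] = True
        from scipy import ndimage
        mask = ndimage.binary_dilation(core)
        img = np.where(core, 1.0, np.where(mask, 0.2, 0.0))
        refined = refine_contour(mask, img)
        assert np.array_equal(refined, core)

    def test_min_size_guard_blocks_shrinking(self):
        mask = np.zeros((8, 8), bool)
        mask[3:5, 3:5] = True
        img = np.where(mask, 0.01, 0.0)
        img[3, 3] = 1.0
        refined = refine_contour(mask, img, min_px=4)
        assert refined.sum() == 4


class TestMorphCleanup:
    def test_one_pixel_filament_discarded(self):
        labels = np.zeros((16, 16), np.int32)
        labels[8, 2:14] = 1
        assert not morph_cleanup(labels, np.ones((16, 16))).any()

    def test_solid_square_preserved(self):
        labels = np.zeros((16, 16), np.int32)
        labels[4:9, 4:9] = 1
        out = morph_cleanup(labels, np.ones((16, 16)))
        assert np.array_equal(out > 0, labels > 0)

    def test_empty_map_passthrough(self):
        assert not morph_cleanup(np.zeros((8, 8), np.int32), np.zeros((8, 8))).any()


class TestFilterBySize:
    def test_inclusive_endpoints(self):
        masks = []
        for area in (1, 5, 30):
            m = np.zeros((40, 40), bool)
            m.flat[:area] = True
            masks.append(make_roi(m))
        kept = filter_by_size(masks, 2, 28)
        assert [r.area_px for r in kept] == [5]
        kept = filter_by_size(masks, 1, 30)
        assert [r.area_px for r in kept] == [1, 5, 30]

    def test_empty_list(self):
        assert filter_by_size([], 1, 10) == []


class TestSegmentEndToEnd:
    def test_blank_image_yields_no_rois(self, acq):
        res = segment(np.zeros((64, 64)), acq)
        assert res.n_rois == 0 and not res.label_map.any()

    def test_determinism(self, acq):
        img, _ = generate_puncta_image(fixtures.well_separated(), seed=11)
        pre = preprocess(img, acq)
        a = segment(pre, acq)
        b = segment(pre, acq)
        assert np.array_equal(a.label_map, b.label_map)

    def test_roi_disjointness_and_size_bounds(self, acq):
        img, _ = generate_puncta_image(fixtures.heterogeneous(), seed=2)
        res = segment(preprocess(img, acq), acq)
        min_px, max_px = compute_size_range(acq)
        seen = np.zeros(res.label_map.shape, bool)
        for roi in res.rois:
            mask = roi.mask(res.label_map.shape)
            assert not (mask & seen).any()
            seen |= mask
            assert min_px <= roi.area_px <= max_px

    def test_label_map_consistent_with_rois(self, acq):
        img, _ = generate_puncta_image(fixtures.well_separated(), seed=12)
        res = segment(preprocess(img, acq), acq)
        rebuilt = np.zeros_like(res.label_map)
        for roi in res.rois:
            rebuilt[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.label
        assert np.array_equal(rebuilt, res.label_map)

    def test_first_iteration_stable_under_more_iterations(self):
        img, _ = generate_puncta_image(fixtures.heterogeneous(), seed=3)
        cfg1 = AcquisitionConfig(n_iterations=1)
        cfg2 = AcquisitionConfig(n_iterations=2)
        pre = preprocess(img, cfg1)
        res1 = segment(pre, cfg1)
        res2 = segment(pre, cfg2)
        it0 = {tuple(map(tuple, sorted(map(tuple, r.pixels))))
               for r in res2.rois if r.iteration == 0}
        all1 = {tuple(map(tuple, sorted(map(tuple, r.pixels)))) for r in res1.rois}
        assert it0 == all1

    def test_roi_count_monotone_in_iterations(self):
        img, _ = generate_puncta_image(fixtures.heterogeneous(), seed=4)
        pre = preprocess(img, AcquisitionConfig())
        counts = [segment(pre, AcquisitionConfig(n_iterations=n)).n_rois
                  for n in (1, 2, 3)]
        assert counts[0] <= counts[1] <= counts[2]
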