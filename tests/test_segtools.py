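import numpy as np
import pytest
from scipy import ndimage

from headforge import segtools
from headforge.grids import ScalarImage


def img_of(values, spacing=(1, 1, 1)):
    return ScalarImage(np.asarray(values, dtype=float), spacing)


class TestGaussianSmooth:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        img = img_of(rng.random((8, 8, 8)))
        out = segtools.gaussian_smooth(img, (0, 0, 0))
        assert np.allclose(out.values, img.values)

    def test_constant_unchanged(self):
        img = img_of(np.full((10, 10, 10), 3.5))
        out = segtools.gaussian_smooth(img, (2, 2, 2))
        assert np.allclose(out.values, 3.5)

    def test_impulse_matches_analytic_gaussian(self):
        # derived oracle: sampled separable Gaussian kernel
        n = 41
        vals = np.zeros((n, n, n))
        vals[20, 20, 20] = 1.0
        img = img_of(vals)
        fwhm = 4.0
        sigma = fwhm * segtools.FWHM_TO_SIGMA
        out = segtools.gaussian_smooth(img, (fwhm,) * 3)
        x = np.arange(n) - 20.0
        g1 = np.exp(-0.5 * (x / sigma) ** 2)
        g1 /= g1.sum()
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        # relative to the kernel peak
        assert np.max(np.abs(out.values - expected)) < 1e-6 * expected.max()
        assert abs(out.values.sum() - 1.0) < 1e-9  # mean preserved

    def test_sigma_convention_wider_than_fwhm(self):
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 10] = 1.0
        img = img_of(vals)
        a = segtools.gaussian_smooth(img, (2.0,) * 3, kernel_convention="fwhm")
        b = segtools.gaussian_smooth(img, (2.0,) * 3, kernel_convention="sigma")
        assert b.values[10, 10, 10] < a.values[10, 10, 10]

    def test_spacing_aware(self):
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 10] = 1.0
        wide = segtools.gaussian_smooth(img_of(vals, (2, 2, 2)), (4.0,) * 3)
        narrow = segtools.gaussian_smooth(img_of(vals, (1, 1, 1)), (4.0,) * 3)
        # same physical kernel on coarser grid concentrates mass per voxel
        assert wide.values[10, 10, 10] > narrow.values[10, 10, 10]


class TestThreshold:
    def test_two_value_image(self):
        # derived: exhaustive threshold search on {10 (40%), 100 (60%)}
        vals = np.full((10, 10, 10), 100.0)
        vals.flat[:400] = 10.0
        img = img_of(vals)
        mask = segtools.threshold_histogram(img)
        assert np.array_equal(mask, vals >= 100.0)

    def test_manual_threshold(self):
        img = img_of(np.arange(27.0).reshape(3, 3, 3))
        mask = segtools.threshold_histogram(img, method="manual", manual=13.0)
        assert np.array_equal(mask, img.values >= 13.0)

    def test_affine_rescale_invariant(self):
        rng = np.random.default_rng(1)
        vals = np.where(rng.random((12, 12, 12)) > 0.5,
                        rng.normal(100, 5, (12, 12, 12)),
                        rng.normal(30, 5, (12, 12, 12)))
        img = img_of(vals)
        m1 = segtools.threshold_histogram(img)
        m2 = segtools.threshold_histogram(img_of(vals * 3.0 + 17.0))
        assert np.array_equal(m1, m2)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError):
            segtools.threshold_histogram(img_of(np.ones((4, 4, 4))))


class TestRegionGrow:
    def test_uniform_image_fills_volume(self):
        img = img_of(np.full((6, 6, 6), 2.0))
        mask = segtools.region_grow(img, [(0, 0, 0)], 1.0, 3.0)
        assert mask.all()

    def test_wall_blocks_growth(self):
        # two same-intensity blobs separated by out-of-band wall
        vals = np.full((9, 5, 5), 10.0)
        vals[4] = 99.0
        img = img_of(vals)
        mask = segtools.region_grow(img, [(0, 2, 2)], 5.0, 20.0)
        # oracle: brute-force connected components of the band
        band = (vals >= 5.0) & (vals <= 20.0)
        comps, _ = ndimage.label(band, segtools.STRUCT_6)
        assert np.array_equal(mask, comps == comps[0, 2, 2])
        assert not mask[5:].any()

    def test_seed_outside_band_empty(self):
        img = img_of(np.full((4, 4, 4), 10.0))
        mask = segtools.region_grow(img, [(1, 1, 1)], 50.0, 60.0)
        assert not mask.any()

    def test_matches_component_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            vals = rng.integers(0, 4, (12, 12, 12)).astype(float)
            img = img_of(vals)
            seed = tuple(rng.integers(0, 12, 3))
            mask = segtools.region_grow(img, [seed], 1.0, 2.0)
            band = (vals >= 1.0) & (vals <= 2.0)
            comps, _ = ndimage.label(band, segtools.STRUCT_6)
            cid = comps[seed]
            expected = (comps == cid) if cid > 0 else np.zeros_like(band)
            assert np.array_equal(mask, expected)

    def test_seed_out_of_grid_errors(self):
        img = img_of(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            segtools.region_grow(img, [(9, 0, 0)], 0.0, 1.0)


class TestKmeans:
    def test_two_value_perfect_split(self):
        vals = np.where(np.indices((8, 8, 8))[0] < 4, 1.0, 9.0)
        lv = segtools.kmeans_labels(img_of(vals), 2, seed=0)
        assert np.array_equal(lv.labels == 1, vals == 1.0)
        assert np.array_equal(lv.labels == 2, vals == 9.0)

    def test_three_gaussians_low_misclassification(self):
        rng = np.random.default_rng(5)
        comps = rng.integers(0, 3, (20, 20, 20))
        means = np.array([0.0, 50.0, 100.0])
        vals = rng.normal(means[comps], 3.0)
        lv = segtools.kmeans_labels(img_of(vals), 3, seed=1)
        mis = np.mean(lv.labels - 1 != comps)
        assert mis < 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (10, 10, 10))
        a = segtools.kmeans_labels(img_of(vals), 3, seed=4)
        b = segtools.kmeans_labels(img_of(vals), 3, seed=4)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_ordered_by_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([5.0, 50.0, 500.0], (10, 10, 10))
        lv = segtools.kmeans_labels(img_of(vals), 3, seed=0)
        m1 = vals[lv.labels == 1].mean()
        m3 = vals[lv.labels == 3].mean()
        assert m1 < m3

    def test_too_many_clusters_errors(self):
        with pytest.raises(ValueError):
            segtools.kmeans_labels(img_of(np.ones((4, 4, 4))), 2)


class TestMorphCleanup:
    def test_closing_convex_solid_unchanged(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[3:9, 3:9, 3:9] = True
        out = segtools.morph_cleanup(mask, "close", radius_vox=1)
        assert np.array_equal(out, mask)

    def test_single_voxel_island_removed(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2, 2, 2] = True
        mask[5:8, 5:8, 5:8] = True
        out = segtools.morph_cleanup(mask, "remove_islands", min_island_size=2)
        assert not out[2, 2, 2]
        assert out[6, 6, 6]

    def test_hole_fill_restores_cube(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        mask[4, 4, 4] = False
        out = segtools.morph_cleanup(mask, "fill_holes")
        expected = np.zeros_like(mask)
        expected[2:7, 2:7, 2:7] = True
        assert np.array_equal(out, expected)

    def test_hole_fill_idempotent(self):
        rng = np.random.default_rng(9)
        mask = rng.random((10, 10, 10)) > 0.5
        once = segtools.morph_cleanup(mask, "fill_holes")
        twice = segtools.morph_cleanup(once, "fill_holes")
        assert np.array_equal(once, twice)

    def test_opening_idempotent(self):
        rng = np.random.default_rng(8)
        mask = rng.random((14, 14, 14)) > 0.4
        once = segtools.morph_cleanup(mask, "open", radius_vox=1)
        twice = segtools.morph_cleanup(once, "open", radius_vox=1)
        assert np.array_equal(once, twice)

    def test_border_background_not_filled(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        out = segtools.morph_cleanup(mask, "fill_holes")
        assert np.array_equal(out, mask)


class TestInterslice:
    def test_identical_endpoints(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 3:7] = True
        stack = segtools.interslice_interpolate(mask, mask, 3)
        assert len(stack) == 5
        for s in stack:
            assert np.array_equal(s, mask)

    def test_concentric_disks_midslice_radius(self):
        yy, xx = np.indices((32, 32))
        d2 = (yy - 15.5) ** 2 + (xx - 15.5) ** 2
        small = d2 <= 4.0**2
        big = d2 <= 8.0**2
        mid = segtools.interslice_interpolate(small, big, 1)[1]
        # analytic blend: disk radius ~ 6 px; allow a 1-px ring of slack
        r6 = d2 <= 6.0**2
        area_lo = np.pi * 5.0**2
        area_hi = np.pi * 7.0**2
        assert area_lo <= mid.sum() <= area_hi
        assert (mid & ~big).sum() == 0
        assert (small & ~mid).sum() == 0
        assert abs(mid.sum() - r6.sum()) < (d2 <= 7**2).sum() - (d2 <= 5**2).sum()

    def test_zero_between_returns_endpoints(self):
        a = np.zeros((5, 5), dtype=bool)
        a[1, 1] = True
        b = np.zeros((5, 5), dtype=bool)
        b[3, 3] = True
        stack = segtools.interslice_interpolate(a, b, 0)
        assert len(stack) == 2
        assert np.array_equal(stack[0], a)
        assert np.array_equal(stack[1], b)

    def test_empty_endpoint_errors(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.ones((5, 5), dtype=bool)
        with pytest.raises(ValueError):
            segtools.interslice_interpolate(a, b, 1)
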