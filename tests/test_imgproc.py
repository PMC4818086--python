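"""Tier-1 filters: background removal, rank filters, blur, depth gain, holes."""

import numpy as np
import pytest

from sama3d.core import ImageStack
from sama3d.imgproc import (
    Tier1Config,
    compensate_depth,
    fill_holes_2d,
    gaussian_blur_3d,
    gradient_separation,
    rank_filter_3d,
    run_tier1,
    subtract_background,
)


def _stack(arr, spacing=(1, 1, 1)):
    return ImageStack(np.asarray(arr, dtype=np.float32), spacing)


class TestSubtractBackground:
    def test_constant_background_removed(self, flat_stack):
        out = subtract_background(flat_stack, radius=8)
        assert np.allclose(out.data, 0.0)

    def test_small_peak_retained_on_flat_background(self):
        data = np.full((3, 64, 64), 30.0)
        data[1, 32, 32] = 130.0
        out = subtract_background(_stack(data), radius=10)
        # opening removes the impulse from the background estimate,
        # so the peak keeps its height above the removed baseline
        assert out.data[1, 32, 32] == pytest.approx(100.0, abs=1.0)
        assert out.data.min() >= 0.0

    def test_radius_larger_than_slice_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="window"):
            subtract_background(flat_stack, radius=40)


class TestRankFilters:
    def test_variance_of_constant_is_zero(self, flat_stack):
        assert np.allclose(rank_filter_3d(flat_stack, "variance", 1).data, 0.0)

    def test_order_statistic_bounds(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.uniform(0, 255, size=(8, 24, 24)))
        lo = rank_filter_3d(stack, "minimum", 1).data
        hi = rank_filter_3d(stack, "maximum", 1).data
        assert (lo <= stack.data).all() and (stack.data <= hi).all()

    def test_median_removes_single_voxel_impulse(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 255.0
        out = rank_filter_3d(_stack(data), "median", 1)
        assert out.data.max() == 0.0

    def test_unknown_kind_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="kind"):
            rank_filter_3d(flat_stack, "mode", 1)


class TestGaussianBlur:
    def test_zero_sigma_is_identity(self, flat_stack):
        out = gaussian_blur_3d(flat_stack, sigma=0.0)
        assert np.array_equal(out.data, flat_stack.data)

    def test_constant_stack_unchanged(self, flat_stack):
        out = gaussian_blur_3d(flat_stack, sigma=2.0)
        assert np.allclose(out.data, flat_stack.data, atol=1e-4)

    def test_impulse_mass_conserved(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1000.0
        out = gaussian_blur_3d(_stack(data), sigma=1.5)
        assert out.data.sum() == pytest.approx(1000.0, rel=0.01)

    def test_sigma_is_physical_units(self):
        # anisotropic spacing: same physical sigma, narrower voxel kernel in z
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1000.0
        iso = gaussian_blur_3d(_stack(data, (1, 1, 1)), sigma=2.0)
        aniso = gaussian_blur_3d(_stack(data, (2, 1, 1)), sigma=2.0)
        assert aniso.data[9:12, 10, 10].sum() > iso.data[9:12, 10, 10].sum()


class TestCompensateDepth:
    def test_uniform_stack_untouched(self, flat_stack):
        out = compensate_depth(flat_stack)
        assert np.allclose(out.data, flat_stack.data, atol=1e-4)

    def test_geometric_decay_equalized(self):
        # closed form: interior slices share r_i = m_i (1/d + 1 + d)/3, so
        # their compensated maxima are exactly equal; the first/last slice
        # use a truncated 2-member window and sit within (1/d+1+d)/3 - 1
        # (~0.4% at d = 0.9) ... (1+d)/2 of the interior level (~5%)
        base = np.full((12, 16, 16), 200.0)
        decayed = base * (0.9 ** np.arange(12))[:, None, None]
        out = compensate_depth(_stack(decayed))
        maxima = out.data.reshape(12, -1).max(axis=1)
        interior = maxima[1:-1]
        assert interior.max() / interior.min() < 1.001
        assert maxima.max() / maxima.min() < 1.12  # ends: truncation bias
        # the 22x spread of the input is gone
        assert maxima.max() / maxima.min() < (0.9 ** -11) / 2

    def test_gain_capped_on_empty_slice(self):
        data = np.full((6, 16, 16), 100.0)
        data[5] = 0.0
        out = compensate_depth(_stack(data))
        assert np.isfinite(out.data).all()
        assert out.data[5].max() == 0.0


class TestFillHoles:
    def test_annulus_becomes_disk(self):
        yy, xx = np.mgrid[:21, :21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        annulus = (r2 <= 64) & (r2 >= 16)
        out = fill_holes_2d(annulus[None])
        assert np.array_equal(out[0], r2 <= 64)

    def test_solid_and_open_shapes_unchanged(self):
        yy, xx = np.mgrid[:21, :21]
        disk = ((yy - 10) ** 2 + (xx - 10) ** 2 <= 64)[None]
        assert np.array_equal(fill_holes_2d(disk), disk)
        c_shape = disk.copy()
        c_shape[0, 10, 10:] = False  # channel from center to border
        c_shape[0, 9:12, 10:] = False
        assert np.array_equal(fill_holes_2d(c_shape), c_shape)

    def test_idempotent(self, small_c1):
        _, truth = small_c1
        mask = truth.structure_labels > 0
        once = fill_holes_2d(mask)
        assert np.array_equal(fill_holes_2d(once), once)


class TestGradientSeparation:
    def test_constant_unchanged(self, flat_stack):
        out = gradient_separation(flat_stack)
        assert np.allclose(out.data, flat_stack.data)

    def test_interior_of_large_object_unchanged(self):
        data = np.zeros((11, 21, 21))
        data[2:9, 4:17, 4:17] = 180.0
        out = gradient_separation(_stack(data))
        assert np.allclose(out.data[4:7, 7:14, 7:14], 180.0)

    def test_touching_pair_separates(self):
        from scipy import ndimage as ndi
        from sama3d.phantom import rasterize_ellipsoid

        shape = (21, 40, 21)
        img = np.zeros(shape, dtype=np.float32)
        a = rasterize_ellipsoid((10, 12, 10), (6, 6, 6), None, shape)
        b = rasterize_ellipsoid((10, 25, 10), (6, 6, 6), None, shape)
        img[a | b] = 200.0
        img[10, 18:20, 10] = 120.0  # dim 1-voxel-wide bridge
        before, n_before = ndi.label(img > 100, np.ones((3, 3, 3)))
        assert n_before == 1
        out = gradient_separation(_stack(img))
        _, n_after = ndi.label(out.data > 100, np.ones((3, 3, 3)))
        assert n_after == 2


class TestRunTier1:
    def test_minimal_config_is_composition(self, small_c1):
        stack, _ = small_c1
        cfg = Tier1Config(
            subtract_background_on=False, median_on=False,
            depth_compensation_on=False, threshold=100.0,
        )
        res = run_tier1(stack, cfg)
        expect = gaussian_blur_3d(stack, cfg.gaussian_sigma)
        assert np.array_equal(res.for_lumen.data, expect.data)

    def test_branches_share_threshold_and_mask(self, small_c1):
        stack, truth = small_c1
        res = run_tier1(stack)
        # re-binarizing the morphometrics branch reproduces the filled mask
        assert np.array_equal(res.for_morphometrics.data > res.structure_threshold,
                              res.structure_mask)

    def test_stage_failure_names_stage(self, flat_stack):
        cfg = Tier1Config(background_radius=40)
        with pytest.raises(RuntimeError, match="subtract_background"):
            run_tier1(flat_stack, cfg)

    def test_filters_preserve_geometry(self, flat_stack):
        res = run_tier1(flat_stack, Tier1Config(background_radius=8))
        assert res.for_lumen.shape == flat_stack.shape
        assert res.for_lumen.spacing == flat_stack.spacing
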