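"""Focus measures, selective fusion, calibration and 3D reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transillum3d import deconv as dc, phantom as ph, stacking as stk
from transillum3d.core import ImageGrid, OpticalProperties, TransilluminationImage
from transillum3d.errors import CalibrationError, InvalidParameterError, NoPeakError

from conftest import STACK_GRID, STACK_KERNEL_CAP

TISSUE = OpticalProperties(1.0, 0.01)


class TestFocusFunction:
    def test_constant_window_scores_zero(self):
        assert stk.focus_function(np.full((9, 9), 2.5)) == 0.0

    def test_hand_computed_two_by_two(self):
        # {1, 3, 1, 3}: mean 2, sum of squared deviations = 4
        assert stk.focus_function(np.array([[1.0, 3.0], [1.0, 3.0]])) == 4.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(-10, 10))
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(0)
        w = rng.random((5, 5))
        assert stk.focus_function(w + c) == pytest.approx(
            stk.focus_function(w), abs=1e-8)

    def test_focus_maps_match_per_window_evaluation(self):
        rng = np.random.default_rng(1)
        im = rng.random((20, 20))
        fc = stk.focus_maps(im, 5)
        direct = stk.focus_function(im[8:13, 8:13])
        assert fc[10, 10] == pytest.approx(direct, rel=1e-9)


class TestFitFocusGaussian:
    depths = dc.default_depth_grid()

    def test_exact_gaussian_recovered(self):
        fc = 2.0 * np.exp(-0.5 * ((self.depths - 7.0) / 3.0) ** 2) + 0.1
        curve = stk.fit_focus_gaussian(self.depths, fc)
        assert curve.d_max == pytest.approx(7.0, abs=1e-6)

    def test_noisy_gaussian_peak_located(self):
        # median error over 100 seeds stays within 0.3 mm of mu = 7.3
        rng = np.random.default_rng(42)
        base = np.exp(-0.5 * ((self.depths - 7.3) / 3.0) ** 2)
        errs = []
        for _ in range(100):
            fc = base + 0.05 * rng.standard_normal(len(self.depths))
            curve = stk.fit_focus_gaussian(self.depths, fc - fc.min() + 1e-6)
            errs.append(abs(curve.d_max - 7.3))
        assert np.median(errs) <= 0.3

    def test_flat_curve_raises_no_peak(self):
        with pytest.raises(NoPeakError):
            stk.fit_focus_gaussian(self.depths, np.ones_like(self.depths))

    def test_d_max_clamped_to_grid_span(self):
        fc = np.exp(-0.5 * ((self.depths - 0.1) / 0.5) ** 2)
        curve = stk.fit_focus_gaussian(self.depths, fc)
        assert curve.d_max >= self.depths[0] - (self.depths[1] - self.depths[0])


class TestSelectivity:
    def test_twenty_db_ratio(self):
        assert stk.selectivity_value(10.0, 1.0) == pytest.approx(20.0)

    def test_perfect_fit_hits_cap(self):
        assert stk.selectivity_value(10.0, 0.0) == 120.0

    def test_scale_invariance(self):
        fc = np.exp(-0.5 * ((dc.default_depth_grid() - 7.0) / 3.0) ** 2) + 0.01
        a = stk.fit_focus_gaussian(dc.default_depth_grid(), fc)
        b = stk.fit_focus_gaussian(dc.default_depth_grid(), 10.0 * fc)
        assert stk.selectivity(b) == pytest.approx(stk.selectivity(a), abs=1e-6)


class TestSharpeningParam:
    def test_threshold_gives_half_over_alpha(self):
        assert stk.sharpening_param(15.0, 2.0, 15.0) == pytest.approx(0.25)

    def test_limit_is_one_over_alpha(self):
        assert stk.sharpening_param(1e6, 2.0, 15.0) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # alpha = 2, s_th = 10, s = 11 -> (1 + tanh 2)/4
        assert stk.sharpening_param(11.0, 2.0, 10.0) == pytest.approx(
            0.49100689501895422, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(s=st.floats(8, 22), ds=st.floats(0.1, 5))
    def test_strictly_increasing(self, s, ds):
        # strict away from tanh saturation, never decreasing anywhere
        assert stk.sharpening_param(s + ds, 1.0, 15.0) > stk.sharpening_param(
            s, 1.0, 15.0)
        assert stk.sharpening_param(200.0, 1.0, 15.0) >= stk.sharpening_param(
            100.0, 1.0, 15.0)

    def test_alpha_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            stk.sharpening_param(10.0, 0.0, 15.0)


class TestFusionWeights:
    def test_unit_normalised_peak_gets_half(self):
        fc = np.array([0.1, 0.5, 1.0, 0.4])
        w = stk.fusion_weights(fc, phi=0.7)
        assert w[2] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 1000), phi=st.floats(0.01, 10))
    def test_weights_in_unit_interval(self, seed, phi):
        fc = np.random.default_rng(seed).random(16)
        w = stk.fusion_weights(fc, phi=phi)
        assert np.all(w >= 0) and np.all(w <= 1)

    def test_sharp_peak_with_large_phi_dominates(self):
        fc = np.zeros(31)
        fc[12] = 1.0
        w = stk.fusion_weights(fc, phi=10.0)
        wn = w / w.sum()
        assert wn[12] > 0.95

    def test_all_zero_curve_falls_back_to_uniform(self):
        w = stk.fusion_weights(np.zeros(8), phi=1.0)
        assert np.allclose(w, 0.5)

    def test_monotone_in_focus_score(self):
        fc = np.linspace(0, 1, 11)
        w = stk.fusion_weights(fc, phi=0.9)
        assert np.all(np.diff(w) > 0)


class TestFuse:
    def test_single_layer_unchanged(self):
        layer = np.random.default_rng(0).random((1, 8, 8))
        out = stk.fuse(layer, np.array([0.3]))
        assert np.allclose(out, layer[0])

    def test_uniform_weights_give_plain_mean(self):
        stack = np.random.default_rng(1).random((5, 8, 8))
        out = stk.fuse(stack, np.full(5, 0.4))
        assert np.allclose(out, stack.mean(axis=0))

    def test_identical_layers_unchanged_by_any_weights(self):
        layer = np.random.default_rng(2).random((8, 8))
        stack = np.stack([layer] * 4)
        out = stk.fuse(stack, np.array([0.1, 0.9, 0.5, 0.2]))
        assert np.allclose(out, layer)

    def test_output_within_stack_envelope(self):
        stack = np.random.default_rng(3).random((6, 10, 10))
        w = np.random.default_rng(4).random((6, 10, 10))
        out = stk.fuse(stack, w)
        assert np.all(out <= stack.max(axis=0) + 1e-12)
        assert np.all(out >= stack.min(axis=0) - 1e-12)


class TestCalibration:
    def test_perfect_pairs_identity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        cal = stk.calibrate_depths(x, x)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_affine_distortion_recovered_exactly(self):
        x = np.linspace(1, 12, 8)
        y = 0.8 * x + 1.0
        cal = stk.calibrate_depths(x, y)
        assert cal.slope == pytest.approx(0.8, abs=1e-12)
        assert cal.intercept == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(cal.corrected, x, atol=1e-10)

    def test_single_point_rejected(self):
        with pytest.raises(CalibrationError):
            stk.calibrate_depths([3.0], [3.1])


class TestBlurMetricProfile:
    def test_unblurred_bar_width_equals_diameter(self):
        grid = ImageGrid(40, 200, 0.1)
        vals = np.ones((40, 200))
        vals[:, 95:125] = 0.0          # 30 px = 3 mm wide bar
        m = stk.blur_metric_profile(TransilluminationImage(vals, grid),
                                    smoothing_sigma=0.0)
        assert abs(m[20] - 3.0) <= 0.2

    def test_constant_image_fully_masked(self):
        grid = ImageGrid(20, 64, 0.1)
        m = stk.blur_metric_profile(
            TransilluminationImage(np.ones((20, 64)), grid))
        assert m.mask.all()


class TestPipeline:
    def test_single_depth_phantom_modal_depth_recovered(self, optics,
                                                        bar_image):
        p, img = bar_image
        res = stk.estimate_depth_map(img, optics)
        depths = res.depth_map.depth[p.occupancy & res.depth_map.valid]
        assert len(depths) > 0.9 * p.occupancy.sum()
        assert np.median(depths) == pytest.approx(5.0, abs=1.0)

    def test_fused_image_inside_stack_envelope(self, optics, bar_image):
        _, img = bar_image
        res = stk.estimate_depth_map(img, optics)
        lo = res.stack.images.min(axis=0)
        hi = res.stack.images.max(axis=0)
        assert np.all(res.fused.values >= lo - 1e-9)
        assert np.all(res.fused.values <= hi + 1e-9)

    def test_pure_noise_image_rejected_by_validity_and_selectivity(self,
                                                                   optics):
        rng = np.random.default_rng(7)
        img = TransilluminationImage(
            1.0 + 0.02 * rng.standard_normal((128, 128)),
            ImageGrid(128, 128, 0.5))
        res = stk.estimate_depth_map(img, optics)
        assert res.depth_map.valid.mean() < 0.1
        assert (res.depth_map.selectivity < res.params.s_th).mean() >= 0.9

    def test_fusion_preserves_restored_contrast_and_width(self, optics,
                                                          bar_image):
        # fusion must keep the deblurring gains: the fused bar's dip is
        # nearly as deep as the matched layer's, much deeper than the
        # blurred input's, and no row gets wider than the input
        p, img = bar_image
        res = stk.estimate_depth_map(img, optics)
        i5 = int(np.argmin(np.abs(res.stack.depths - 5.0)))
        amp_blur = 1.0 - img.values[128, 128]
        amp_fused = 1.0 - res.fused.values[128, 128]
        amp_matched = 1.0 - res.stack.images[i5, 128, 128]
        assert amp_fused >= 0.8 * amp_matched
        assert amp_fused >= 1.5 * amp_blur
        w_blur = stk.blur_metric_profile(img)
        w_fused = stk.blur_metric_profile(
            TransilluminationImage(res.fused.values, STACK_GRID))
        both = ~w_blur.mask & ~w_fused.mask
        assert np.all(w_fused[both] <= 1.05 * w_blur[both])


class TestReconstruct3D:
    def _depth_map(self, depth_vals, valid, grid):
        return stk.DepthMap(depth=depth_vals,
                            selectivity=np.zeros(grid.shape),
                            valid=valid, grid=grid)

    def test_flat_disk_voxels_at_constant_depth(self, optics):
        grid = ImageGrid(160, 160, 0.5)
        sil = ph.disk_silhouette(grid, (40.0, 40.0), 8.0)
        p = ph.make_volumetric_phantom(sil, 5.0, grid)
        img = ph.blur_image(p, optics, max_kernel_radius_mm=39.5)
        res = stk.estimate_depth_map(img, optics)
        rec = stk.reconstruct_3d(res.depth_map, res.fused,
                                 segmentation_threshold=0.6)
        assert len(rec.points) > 0
        # judge the depth on voxels over the true silhouette; thresholded
        # halo pixels carry the neighbouring-depth estimates
        r = np.hypot(rec.points[:, 0] - 40.0, rec.points[:, 1] - 40.0)
        inside = rec.points[r <= 4.0]
        assert len(inside) > 0
        assert abs(np.median(inside[:, 2]) - 5.0) <= 1.0

    def test_empty_depth_map_gives_empty_reconstruction(self):
        grid = ImageGrid(16, 16, 0.5)
        dm = self._depth_map(np.full((16, 16), np.nan),
                             np.zeros((16, 16), bool), grid)
        fused = stk.FusedImage(values=np.ones((16, 16)), grid=grid)
        rec = stk.reconstruct_3d(dm, fused, 0.8)
        assert rec.points.shape == (0, 3)

    def test_two_blob_phantom_separates_in_depth(self):
        grid = ImageGrid(32, 32, 0.5)
        depth = np.full((32, 32), np.nan)
        depth[4:12, 4:12] = 3.0
        depth[20:28, 20:28] = 9.0
        valid = np.isfinite(depth)
        fused = np.where(valid, 0.2, 1.0)
        rec = stk.reconstruct_3d(self._depth_map(depth, valid, grid),
                                 stk.FusedImage(fused, grid), 0.8)
        zs = np.sort(np.unique(rec.points[:, 2]))
        assert set(zs) == {3.0, 9.0}

    def test_point_cloud_exports(self, tmp_path):
        grid = ImageGrid(16, 16, 0.5)
        depth = np.full((16, 16), 4.0)
        rec = stk.reconstruct_3d(
            self._depth_map(depth, np.ones((16, 16), bool), grid),
            stk.FusedImage(np.zeros((16, 16)), grid), 0.5)
        rec.save_xyz(tmp_path / "out.xyz")
        rec.save_ply(tmp_path / "out.ply")
        assert (tmp_path / "out.xyz").exists()
        assert (tmp_path / "out.ply").stat().st_size > 0
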