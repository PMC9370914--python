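"""Phantom construction and the forward blur/noise/background model."""

import numpy as np
import pytest

from transillum3d import phantom as ph, profiles, psf
from transillum3d.core import ImageGrid, OpticalProperties, TransilluminationImage
from transillum3d.errors import GeometryError, InvalidParameterError

TISSUE = OpticalProperties(1.0, 0.01)


class TestCylinderPhantom:
    def test_inclined_bar_band_and_depth_span(self):
        grid = ImageGrid(360, 640, 0.1)
        p = ph.make_cylinder_phantom(3.0, 30, 5, 2.2, 5.0, grid)
        assert p.occupancy.any(axis=0).sum() == 30          # 3 mm / 0.1 mm
        depths = p.true_depth[p.occupancy]
        assert depths.min() == pytest.approx(2.2, abs=0.02)
        assert depths.max() == pytest.approx(5.0, abs=0.02)

    def test_degenerate_tilt_gives_constant_depth(self):
        grid = ImageGrid(100, 100, 0.1)
        p = ph.make_cylinder_phantom(2.0, 8.0, 0, 4.0, 4.0, grid)
        assert np.allclose(p.true_depth[p.occupancy], 4.0)

    @pytest.mark.parametrize("tilt", [0.0, 5.0, 30.0])
    def test_projected_footprint_length(self, tilt):
        grid = ImageGrid(400, 100, 0.1)
        p = ph.make_cylinder_phantom(2.0, 30.0, tilt, 3.0, 4.0, grid)
        expected = 30.0 * np.cos(np.radians(tilt)) / 0.1
        assert abs(p.occupancy.any(axis=1).sum() - expected) <= 1

    def test_band_outside_grid_rejected(self):
        grid = ImageGrid(50, 20, 0.1)
        with pytest.raises(GeometryError):
            ph.make_cylinder_phantom(5.0, 4.0, 0, 3.0, 3.0, grid)


class TestVolumetricPhantom:
    def test_constant_depth_disk(self):
        grid = ImageGrid(80, 80, 0.1)
        sil = ph.disk_silhouette(grid, (4.0, 4.0), 3.0)
        p = ph.make_volumetric_phantom(sil, 5.0, grid)
        assert np.allclose(p.true_depth[p.occupancy], 5.0)

    def test_two_blobs_give_bimodal_depth_map(self):
        grid = ImageGrid(120, 120, 0.1)
        sil = (ph.disk_silhouette(grid, (3.0, 3.0), 2.0)
               | ph.disk_silhouette(grid, (9.0, 9.0), 2.0))
        depth = np.where(ph.disk_silhouette(grid, (3.0, 3.0), 2.0), 3.0, 9.0)
        p = ph.make_volumetric_phantom(sil, depth, grid)
        assert set(np.unique(p.true_depth[p.occupancy])) == {3.0, 9.0}

    def test_empty_silhouette_rejected(self):
        grid = ImageGrid(10, 10, 0.1)
        with pytest.raises(GeometryError):
            ph.make_volumetric_phantom(np.zeros((10, 10), bool), 5.0, grid)

    def test_mask_round_trips_through_tiff(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(3)
        mask = rng.random((32, 32)) > 0.6
        path = tmp_path / "mask.tif"
        tifffile.imwrite(path, mask.astype(np.uint8))
        assert np.array_equal(tifffile.imread(path).astype(bool), mask)


class TestBlurImage:
    def test_empty_phantom_blurs_to_unit_background(self):
        grid = ImageGrid(64, 64, 0.2)
        p = ph.Phantom(np.zeros((64, 64), bool), np.full((64, 64), np.nan),
                       {}, grid)
        img = ph.blur_image(p, TISSUE)
        assert np.allclose(img.values, 1.0, atol=1e-6)

    def test_single_dark_pixel_reproduces_kernel(self):
        grid = ImageGrid(81, 81, 0.2)
        occ = np.zeros((81, 81), bool)
        occ[40, 40] = True
        p = ph.Phantom(occ, np.where(occ, 5.0, np.nan), {}, grid)
        img = ph.blur_image(p, TISSUE, max_kernel_radius_mm=7.9)
        kernel = psf.rasterize_kernel(5.0, TISSUE, 0.2, support_radius_mm=7.9,
                                      strict=False)
        r = kernel.radius_px
        expected = 1.0 - kernel.values[r - 40:r + 41, r - 40:r + 41]
        assert np.allclose(img.values, expected, atol=1e-12)

    def test_contrast_decreases_with_depth(self):
        # oracle: direct forward convolution at each depth
        cms = []
        for depth in [2.0, 4.0, 6.0, 8.0]:
            x, prof = ph.bar_profile(3.0, depth, TISSUE)
            cms.append((prof.max() - prof.min()) / (prof.max() + prof.min()))
        assert np.all(np.diff(cms) < 0)

    def test_intensity_conservation(self):
        grid = ImageGrid(200, 301, 0.1)
        p = ph.make_cylinder_phantom(3.0, 10, 0, 5.0, 5.0, grid)
        img = ph.blur_image(p, TISSUE)
        io_mean = (1.0 - p.occupancy.astype(float)).mean()
        assert abs(img.values.mean() - io_mean) < 1e-6

    def test_single_depth_identical_to_plain_convolution(self):
        grid = ImageGrid(120, 120, 0.2)
        sil = ph.disk_silhouette(grid, (12.0, 12.0), 4.0)
        p = ph.make_volumetric_phantom(sil, 5.0, grid)
        img = ph.blur_image(p, TISSUE, max_kernel_radius_mm=11.0)
        kernel = psf.rasterize_kernel(5.0, TISSUE, 0.2, support_radius_mm=11.0,
                                      strict=False)
        direct = 1.0 - ph._convolve_reflect(sil.astype(float), kernel.values)
        assert np.array_equal(img.values, np.clip(direct, 0.0, None))

    def test_1d_fast_path_matches_2d_blur(self):
        # a bar spanning the full image height is effectively infinite
        # under the mirrored boundary extension
        grid = ImageGrid(64, 601, 0.1)
        p = ph.make_cylinder_phantom(3.0, 12.0, 0, 5.0, 5.0, grid,
                                     top_row_mm=-0.5)
        img = ph.blur_image(p, TISSUE)
        x = (np.arange(601) + 0.5) * 0.1 - 300 * 0.1
        _, prof = ph.bar_profile(3.0, 5.0, TISSUE, x=x)
        assert np.max(np.abs(img.values[32] - prof)) < 2e-3


@pytest.fixture(scope="module")
def clean():
    grid = ImageGrid(200, 301, 0.1)
    p = ph.make_cylinder_phantom(3.0, 15, 0, 4.0, 4.0, grid)
    return ph.blur_image(p, TISSUE)


class TestNoise:
    def test_infinite_snr_is_identity(self, clean):
        out = ph.add_noise(clean, np.inf, seed=0)
        assert np.array_equal(out.values, clean.values)

    def test_same_seed_reproduces(self, clean):
        a = ph.add_noise(clean, 10.0, seed=42)
        b = ph.add_noise(clean, 10.0, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_empirical_snr_matches_request(self, clean):
        # oracle: recompute the SNR from the known injected noise field
        noisy = ph.add_noise(clean, 21.0, seed=1)
        noise = noisy.values - clean.values
        dev = np.abs(clean.values - 1.0)
        region = dev > 0.01 * dev.max()
        signal_rms = np.sqrt(np.mean((clean.values[region] - 1.0) ** 2))
        measured = 20 * np.log10(signal_rms / noise.std())
        assert measured == pytest.approx(21.0, abs=0.5)


class TestRemoveBackground:
    def grid(self):
        return ImageGrid(50, 50, 0.1)

    def test_identical_inputs_give_unit_field(self):
        img = TransilluminationImage(np.full((50, 50), 0.7), self.grid())
        out = ph.remove_background(img, img)
        assert np.allclose(out.values, 1.0)

    def test_constant_ratio(self):
        g = self.grid()
        a = TransilluminationImage(np.full((50, 50), 0.4), g)
        b = TransilluminationImage(np.full((50, 50), 0.8), g)
        assert np.allclose(ph.remove_background(a, b).values, 0.5)

    def test_vignetting_cancels_exactly(self):
        g = self.grid()
        yy, xx = np.mgrid[0:50, 0:50]
        vignette = 1.0 - 0.3 * ((yy - 25) ** 2 + (xx - 25) ** 2) / 25**2
        flat = np.ones((50, 50))
        flat[20:30, 20:30] = 0.5
        with_abs = TransilluminationImage(flat * vignette, g)
        without = TransilluminationImage(vignette, g)
        out = ph.remove_background(with_abs, without)
        assert np.max(np.abs(out.values - flat)) < 1e-9
        assert out.provenance == "background_removed"

    def test_floor_pixels_masked_and_counted(self, caplog):
        g = self.grid()
        bg = np.ones((50, 50))
        bg[0, :3] = 0.0
        a = TransilluminationImage(np.ones((50, 50)), g)
        b = TransilluminationImage(bg, g)
        import logging

        with caplog.at_level(logging.WARNING):
            out = ph.remove_background(a, b)
        assert out.mask.sum() == 3
        assert "3 background pixels" in caplog.text

    def test_absorptance_bounds_validated(self):
        grid = ImageGrid(20, 20, 0.1)
        sil = ph.disk_silhouette(grid, (1.0, 1.0), 1.0)
        p = ph.make_volumetric_phantom(sil, 3.0, grid)
        with pytest.raises(InvalidParameterError):
            ph.blur_image(p, TISSUE, absorptance=1.5)
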