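"""Ground-truth phantoms and the forward transillumination simulator.

Absorbers are modelled multiplicatively on a unit background: the
unblurred shadow image is ``Io = 1 - a * occupancy`` with absorptance
``a`` (1 for a matte-black object).  Blur is convolution with the
depth-dependent PSF kernel.  For phantoms whose depth varies across the
footprint (an inclined bar, a volumetric object), the true depth map is
quantised into strata, each stratum's shadow is convolved with its own
kernel, and the per-stratum transmittances are multiplied — a phantom at
a single constant depth trivially reduces to the plain convolution
model.

The module also provides the exact 1D fast path used by the lookup-table
machinery: the blurred cross-profile of an infinite straight cylinder,
computed by 1D convolution with the line spread function of the kernel
(the rect profile makes this a difference of the LSF's CDF at the two
cylinder edges).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .core import ImageGrid, TransilluminationImage, as_optical
from .errors import GeometryError, InvalidParameterError
from . import psf as _psf

__all__ = [
    "Phantom",
    "make_cylinder_phantom",
    "make_volumetric_phantom",
    "disk_silhouette",
    "blob_silhouette",
    "blur_image",
    "add_noise",
    "remove_background",
    "bar_profile",
    "bar_profiles",
]

log = logging.getLogger(__name__)


@dataclass
class Phantom:
    """Occupancy map + per-pixel true depth (mm, NaN where empty)."""

    occupancy: np.ndarray
    true_depth: np.ndarray
    geometry: dict = field(default_factory=dict)
    grid: ImageGrid = None

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.true_depth = np.asarray(self.true_depth, dtype=float)
        occ_depths = self.true_depth[self.occupancy]
        if occ_depths.size and not np.all(occ_depths > 0):
            raise InvalidParameterError("true_depth must be > 0 where occupied")


def make_cylinder_phantom(diameter: float, length: float, tilt_deg: float,
                          depth_top: float, depth_bottom: float,
                          grid: ImageGrid, center_col_mm: float | None = None,
                          top_row_mm: float | None = None) -> Phantom:
    """A straight cylindrical bar, axis vertical in the image plane,
    inclined in depth.

    The image-plane footprint is a vertical band of projected width
    ``diameter`` and projected length ``length * cos(tilt)``; the true
    depth varies linearly along the axis from ``depth_top`` at the top of
    the footprint to ``depth_bottom`` at the bottom.  The band is
    centered on a pixel edge so that an integer ``diameter / pitch``
    projects to exactly that many pixels.
    """
    if diameter <= 0 or length <= 0:
        raise InvalidParameterError("diameter and length must be positive")
    if depth_top <= 0 or depth_bottom <= 0:
        raise InvalidParameterError("depths must be positive")
    pitch = grid.pitch
    proj_len = length * math.cos(math.radians(tilt_deg))
    if center_col_mm is None:
        center_col_mm = round(grid.n_cols / 2) * pitch  # a pixel edge
    if top_row_mm is None:
        top_row_mm = (grid.height_mm - proj_len) / 2.0
    x = grid.x_centers()
    y = grid.y_centers()
    in_band = np.abs(x - center_col_mm) < diameter / 2.0
    in_axis = (y >= top_row_mm) & (y < top_row_mm + proj_len)
    if not in_band.any() or not in_axis.any():
        raise GeometryError("cylinder footprint misses the grid entirely")
    if (center_col_mm - diameter / 2.0 < -pitch / 2
            or center_col_mm + diameter / 2.0 > grid.width_mm + pitch / 2):
        raise GeometryError("cylinder band exceeds the image grid transversely")
    occupancy = np.outer(in_axis, in_band)
    if proj_len > 0:
        frac = np.clip((y - top_row_mm) / proj_len, 0.0, 1.0)
    else:
        frac = np.zeros_like(y)
    depth_along = depth_top + frac * (depth_bottom - depth_top)
    true_depth = np.where(occupancy, depth_along[:, None], np.nan)
    geometry = dict(kind="cylinder", diameter=diameter, length=length,
                    tilt_deg=tilt_deg, depth_top=depth_top,
                    depth_bottom=depth_bottom, center_col_mm=center_col_mm,
                    top_row_mm=top_row_mm)
    return Phantom(occupancy, true_depth, geometry, grid)


def make_volumetric_phantom(silhouette: np.ndarray, depth, grid: ImageGrid,
                            geometry: dict | None = None) -> Phantom:
    """A phantom from an arbitrary binary silhouette.

    ``depth`` may be a scalar (constant depth), an array matching the
    grid, or a callable ``f(y_mm, x_mm) -> depth`` evaluated on the
    pixel-center mesh.
    """
    silhouette = np.asarray(silhouette, dtype=bool)
    if silhouette.shape != grid.shape:
        raise GeometryError("silhouette shape does not match grid")
    if not silhouette.any():
        raise GeometryError("empty silhouette")
    if callable(depth):
        yy, xx = np.meshgrid(grid.y_centers(), grid.x_centers(), indexing="ij")
        depth_map = np.asarray(depth(yy, xx), dtype=float)
    elif np.isscalar(depth):
        depth_map = np.full(grid.shape, float(depth))
    else:
        depth_map = np.asarray(depth, dtype=float)
        if depth_map.shape != grid.shape:
            raise GeometryError("depth map shape does not match grid")
    true_depth = np.where(silhouette, depth_map, np.nan)
    return Phantom(silhouette, true_depth,
                   geometry or dict(kind="volumetric"), grid)


def disk_silhouette(grid: ImageGrid, center_mm: tuple[float, float],
                    diameter: float) -> np.ndarray:
    """Binary disk mask; ``center_mm`` is (y, x) in mm."""
    yy, xx = np.meshgrid(grid.y_centers(), grid.x_centers(), indexing="ij")
    cy, cx = center_mm
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= (diameter / 2.0) ** 2


def blob_silhouette(grid: ImageGrid, seed: int = 0, n_lobes: int = 4,
                    scale: float = 0.25) -> np.ndarray:
    """Synthetic irregular silhouette (union of overlapping ellipses),
    standing in for an arbitrarily shaped volumetric absorber."""
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(grid.y_centers(), grid.x_centers(), indexing="ij")
    cy0, cx0 = grid.height_mm / 2, grid.width_mm / 2
    mask = np.zeros(grid.shape, dtype=bool)
    for _ in range(n_lobes):
        cy = cy0 + rng.uniform(-0.5, 0.5) * scale * grid.height_mm
        cx = cx0 + rng.uniform(-0.5, 0.5) * scale * grid.width_mm
        ry = rng.uniform(0.4, 1.0) * scale * grid.height_mm / 2
        rx = rng.uniform(0.4, 1.0) * scale * grid.width_mm / 2
        th = rng.uniform(0, np.pi)
        u = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        v = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        mask |= (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    return mask


def _convolve_reflect(field: np.ndarray, kernel: np.ndarray,
                      boundary: str = "symmetric") -> np.ndarray:
    """'same'-size convolution with reflective (or periodic) boundaries."""
    # half-sample symmetric extension: with an even-symmetric kernel this
    # is a mirrored torus, so the image mean is conserved exactly
    r = kernel.shape[0] // 2
    padded = np.pad(field, r, mode=boundary)
    out = fftconvolve(padded, kernel, mode="same")
    return out[r:r + field.shape[0], r:r + field.shape[1]] if r else out


def blur_image(phantom: Phantom, optical, absorptance: float = 1.0,
               depth_step: float = 0.1, parse: str = "r",
               tail_tol: float = 1e-4,
               max_kernel_radius_mm: float | None = None,
               boundary: str = "symmetric") -> TransilluminationImage:
    """Forward-simulate the blurred transillumination image of a phantom.

    ``depth_step`` quantises the true depth map into strata (mm); each
    stratum is blurred with its own kernel and the per-stratum
    transmittances are multiplied.  ``max_kernel_radius_mm`` caps the
    kernel support (the kernel is renormalised after truncation); by
    default the cap is twice the larger image dimension, which keeps the
    convolution cost bounded while leaving the unit-sum blur model
    intact.
    """
    optical = as_optical(optical)
    if not (0.0 < absorptance <= 1.0):
        raise InvalidParameterError("absorptance must be in (0, 1]")
    grid = phantom.grid
    if max_kernel_radius_mm is None:
        max_kernel_radius_mm = 2.0 * max(grid.height_mm, grid.width_mm)
    # The strata of a phantom are disjoint in the image plane (every line
    # of sight crosses the absorber at a single depth), so their blurred
    # shadow deficits superpose linearly; a single-depth phantom reduces
    # exactly to the plain convolution model.
    shadow = np.zeros(grid.shape)
    if phantom.occupancy.any():
        quant = np.round(phantom.true_depth / depth_step) * depth_step
        strata = np.unique(quant[phantom.occupancy])
        for d in strata:
            mask = (phantom.occupancy & (quant == d)).astype(float)
            try:
                radius = min(_psf.support_radius(d, optical, tail_tol=tail_tol,
                                                 parse=parse),
                             max_kernel_radius_mm)
            except Exception:
                radius = max_kernel_radius_mm
            kernel = _psf.rasterize_kernel(d, optical, grid.pitch,
                                           support_radius_mm=radius,
                                           tail_tol=tail_tol, strict=False,
                                           parse=parse)
            shadow += _convolve_reflect(mask, kernel.values, boundary)
    out = np.clip(1.0 - absorptance * shadow, 0.0, None)
    return TransilluminationImage(values=out, grid=grid, provenance="synthetic")


def add_noise(image: TransilluminationImage, snr_db: float,
              seed: int | np.random.Generator | None = None
              ) -> TransilluminationImage:
    """Add zero-mean Gaussian sensor noise at a prescribed SNR.

    SNR (dB) is referenced to the absorber's contrast amplitude:
    ``20 log10(RMS(clean - 1) over the absorber-affected region / sigma)``.
    ``snr_db = inf`` returns the image unchanged.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return image.copy_with(image.values.copy())
    if not np.isfinite(snr_db):
        raise InvalidParameterError(f"snr_db must be finite or +inf, got {snr_db}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    contrast = np.abs(image.values - 1.0)
    region = contrast > 0.01 * contrast.max() if contrast.max() > 0 else None
    if region is None or not region.any():
        raise InvalidParameterError("image has no contrast to reference SNR to")
    signal_rms = np.sqrt(np.mean((image.values[region] - 1.0) ** 2))
    sigma = signal_rms / 10.0 ** (snr_db / 20.0)
    noisy = image.values + rng.normal(0.0, sigma, size=image.values.shape)
    return image.copy_with(noisy)


def remove_background(with_absorber: TransilluminationImage,
                      without_absorber: TransilluminationImage,
                      floor: float = 1e-6) -> TransilluminationImage:
    """Divide out background non-uniformity (vignetting, illumination).

    Background pixels below ``floor`` are masked (set to 1) and counted
    in the log.
    """
    if with_absorber.grid.shape != without_absorber.grid.shape:
        raise InvalidParameterError("images must share the same grid")
    bg = without_absorber.values
    bad = ~(bg > floor)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("remove_background: %d background pixels below floor "
                    "%.1e were masked", n_bad, floor)
    safe = np.where(bad, 1.0, bg)
    ratio = np.where(bad, 1.0, with_absorber.values / safe)
    return TransilluminationImage(values=ratio, grid=with_absorber.grid,
                                  provenance="background_removed",
                                  mask=bad if n_bad else None)


# ---------------------------------------------------------------------------
# Exact 1D fast path for infinite straight cylinders
# ---------------------------------------------------------------------------

def _lsf_cdfs(depths, optical, parse: str = "r"):
    """Half-line CDFs S(x) = integral_0^x LSF of the unit-integral LSF,
    one row per depth, normalised so S(inf) = 1/2 exactly."""
    xg, lsf = _psf.line_spread_functions(depths, optical, parse=parse)
    areas = 0.5 * (lsf[:, 1:] + lsf[:, :-1]) * np.diff(xg)[None, :]
    s = np.concatenate([np.zeros((lsf.shape[0], 1)), np.cumsum(areas, axis=1)],
                       axis=1)
    s *= 0.5 / s[:, -1:]
    return xg, s


def bar_profiles(diameters, depths, optical, x: np.ndarray,
                 absorptance: float = 1.0, parse: str = "r") -> np.ndarray:
    """Blurred cross-profiles of infinite vertical cylinders.

    Returns an array of shape ``(len(depths), len(diameters), len(x))``
    where ``x`` are signed sample positions (mm) across the cylinder,
    centered on its axis.  This is the exact 1D reduction of the 2D blur
    model and is cross-checked against :func:`blur_image` in the tests.
    """
    diameters = np.atleast_1d(np.asarray(diameters, dtype=float))
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    x = np.asarray(x, dtype=float)
    xg, s = _lsf_cdfs(depths, optical, parse=parse)

    def cdf(row, q):
        return 0.5 + np.sign(q) * np.interp(np.abs(q), xg, row, right=0.5)

    out = np.empty((len(depths), len(diameters), len(x)))
    for ti in range(len(depths)):
        row = s[ti]
        for di, diam in enumerate(diameters):
            shadow = cdf(row, x + diam / 2.0) - cdf(row, x - diam / 2.0)
            out[ti, di] = 1.0 - absorptance * shadow
    return out


def bar_profile(diameter: float, depth: float, optical,
                x: np.ndarray | None = None, pitch: float = 0.1,
                half_length: float = 30.0, absorptance: float = 1.0,
                parse: str = "r") -> tuple[np.ndarray, np.ndarray]:
    """Single blurred cylinder cross-profile sampled at detector pitch."""
    if x is None:
        n = int(round(half_length / pitch))
        x = np.arange(-n, n + 1) * pitch
    prof = bar_profiles([diameter], [depth], optical, x,
                        absorptance=absorptance, parse=parse)[0, 0]
    return x, prof
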