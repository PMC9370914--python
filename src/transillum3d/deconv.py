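"""Deblurring by deconvolution with the depth-dependent PSF.

If the depth of an absorber is known, the blurred shadow image can be
restored by inverting the convolution with the kernel at that depth.
When the depth is unknown, the same operation is swept over a grid of
hypothesis depths, producing a stack of images each "in focus" at a
different depth — the input to the focus-stacking stage.

The default method is Wiener deconvolution with a flat noise-to-signal
power ratio (NSR).  The filter is normalised to unit DC gain so that a
flat field (and the background level of a shadow image) is preserved
exactly regardless of the regularisation strength.  Richardson-Lucy is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .core import TransilluminationImage, as_optical
from .errors import InvalidParameterError, SizeError
from . import psf as _psf

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionStack",
    "deconvolve",
    "sweep_deconvolve",
    "default_depth_grid",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    method: str = "wiener"        # "wiener" | "richardson_lucy"
    nsr: float = 1e-3             # Wiener noise-to-signal power ratio
    iterations: int = 30          # Richardson-Lucy iteration count
    pad_mode: str = "symmetric"

    def __post_init__(self):
        if self.method not in ("wiener", "richardson_lucy"):
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if self.method == "wiener" and not self.nsr > 0:
            raise InvalidParameterError("wiener nsr must be > 0")
        if self.method == "richardson_lucy" and self.iterations < 1:
            raise InvalidParameterError("richardson_lucy needs >= 1 iteration")


def _wiener(padded: np.ndarray, kernel: np.ndarray, nsr: float) -> np.ndarray:
    shape = padded.shape
    kpad = np.zeros(shape)
    kr = kernel.shape[0] // 2
    kc = kernel.shape[1] // 2
    kpad[:kernel.shape[0], :kernel.shape[1]] = kernel
    kpad = np.roll(kpad, (-kr, -kc), axis=(0, 1))
    h = sfft.rfft2(kpad)
    g = np.conj(h) / (np.abs(h) ** 2 + nsr)
    g *= 1.0 + nsr          # unit DC gain for a unit-sum kernel
    return sfft.irfft2(sfft.rfft2(padded) * g, s=shape)


def deconvolve(image: TransilluminationImage, kernel,
               config: DeconvolutionConfig | None = None
               ) -> TransilluminationImage:
    """Deblur ``image`` with the given :class:`~transillum3d.psf.PSFKernel`.

    The image is padded by the kernel radius (``pad_mode``) before the
    frequency-domain division, then cropped, which suppresses wraparound
    ringing.  Deterministic for a fixed configuration.
    """
    config = config or DeconvolutionConfig()
    k = kernel.values
    if k.shape[0] > image.values.shape[0] or k.shape[1] > image.values.shape[1]:
        raise SizeError(
            f"kernel {k.shape} larger than image {image.values.shape}")
    # pad_mode "none": invert the periodic operator on the raw domain
    r = 0 if config.pad_mode == "none" else k.shape[0] // 2
    padded = np.pad(image.values, r, mode=config.pad_mode) if r else image.values
    if config.method == "wiener":
        out = _wiener(padded, k, config.nsr)
    else:
        from skimage.restoration import richardson_lucy
        out = richardson_lucy(padded, k, num_iter=config.iterations,
                              clip=False)
    if r:
        out = out[r:-r, r:-r]
    return image.copy_with(out)


def default_depth_grid() -> np.ndarray:
    """The standard hypothesis-depth sweep {0.1, 1, 2, ..., 30} mm
    (31 deconvolutions)."""
    return np.concatenate([[0.1], np.arange(1.0, 31.0)])


@dataclass
class DeconvolutionStack:
    """Depth-ordered stack of deblurred images."""

    depths: np.ndarray            # (m,), strictly increasing, mm
    images: np.ndarray            # (m, H, W)
    config: DeconvolutionConfig
    grid: object = None

    def __len__(self) -> int:
        return len(self.depths)


def sweep_deconvolve(image: TransilluminationImage, depths, optical,
                     config: DeconvolutionConfig | None = None,
                     parse: str = "r", tail_tol: float = 1e-4,
                     max_kernel_radius_mm: float | None = None
                     ) -> DeconvolutionStack:
    """Deconvolve one image with kernels for every hypothesis depth.

    Deep kernels whose tail-complete support would exceed the image are
    truncated to ``max_kernel_radius_mm`` (default: just under half the
    smaller image extent) and renormalised; the truncation is benign for
    the smooth kernel tails and keeps every kernel applicable to the
    image.
    """
    config = config or DeconvolutionConfig()
    optical = as_optical(optical)
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise InvalidParameterError("depths must be non-empty")
    if np.any(np.diff(depths) <= 0):
        raise InvalidParameterError("depths must be strictly increasing")
    grid = image.grid
    if max_kernel_radius_mm is None:
        max_kernel_radius_mm = (min(grid.n_rows, grid.n_cols) // 2 - 1) \
            * grid.pitch
    out = np.empty((len(depths),) + grid.shape)
    for i, d in enumerate(depths):
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
        out[i] = deconvolve(image, kernel, config).values
    return DeconvolutionStack(depths=depths, images=out, config=config,
                              grid=grid)
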