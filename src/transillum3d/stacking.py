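"""Focus stacking over a depth-swept deconvolution stack.

Each r x r window of every deconvolved layer is scored with the
gray-level variance focus function

    fc(d_i) = sum_k (i_k - mean)^2          (sum over the window)

A Gaussian fitted to the focus curve across hypothesis depths gives the
best-focus depth ``d_max`` per window; the quality of the curve is
summarised by the selectivity

    s = 20 log10( max fc / RMS(fc - g) )    [dB]

which gates the fusion sharpness: trustworthy windows (high s) get
narrow weights concentrated at the focus peak, noise-dominated windows
get wide, averaging weights,

    phi(s) = (1 + tanh(alpha (s - s_th))) / (2 alpha)
    w(d_i) = (1 + tanh(phi (fc_bar(d_i) - 1))) / 2
    fused  = sum w(d_i) I_db(d_i) / sum w(d_i).

``fc_bar`` is the focus curve normalised to unit peak by default (the
literal sum-normalisation, which collapses the weight function because
``fc_bar - 1`` is then always close to -1, is available behind
``normalization="sum"``).

Numerical note: the focus curves of deconvolution sweeps are intrinsically
asymmetric — variance decays slowly on the over-deconvolution side — so
the Gaussian is fitted to the contiguous peak region (fc within 10% of
the peak, at least 5 samples) rather than the full curve; a full-curve
fit shifts d_max deep by several millimetres even without noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._fitting import batch_gaussian_fit
from .core import ImageGrid, TransilluminationImage, as_optical
from .errors import CalibrationError, InvalidParameterError, NoPeakError
from .deconv import (DeconvolutionConfig, DeconvolutionStack,
                     default_depth_grid, sweep_deconvolve)

__all__ = [
    "FocusCurve",
    "FusionParams",
    "DepthMap",
    "FusedImage",
    "CalibrationResult",
    "StackingResult",
    "focus_function",
    "focus_maps",
    "fit_focus_gaussian",
    "selectivity",
    "sharpening_param",
    "fusion_weights",
    "fuse",
    "estimate_depth_map",
    "calibrate_depths",
    "blur_metric_profile",
    "reconstruct_3d",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Focus measurement
# ---------------------------------------------------------------------------

def focus_function(window: np.ndarray) -> float:
    """Gray-level variance focus score: sum of squared deviations from
    the window mean (a sum, not a mean, over the window)."""
    w = np.asarray(window, dtype=float)
    return float(((w - w.mean()) ** 2).sum())


def focus_maps(images: np.ndarray, window_r: int = 9) -> np.ndarray:
    """Per-pixel focus score of each layer with a sliding r x r window
    (reflective boundaries): ``out[i, y, x]`` is the focus function of
    the window centered on (y, x) in layer i."""
    if window_r < 3:
        raise InvalidParameterError("window_r must be >= 3")
    images = np.asarray(images, dtype=float)
    single = images.ndim == 2
    if single:
        images = images[None]
    n = window_r * window_r
    out = np.empty_like(images)
    for i, im in enumerate(images):
        m1 = ndimage.uniform_filter(im, window_r, mode="reflect")
        m2 = ndimage.uniform_filter(im * im, window_r, mode="reflect")
        out[i] = n * np.maximum(m2 - m1 * m1, 0.0)
    return out[0] if single else out


@dataclass
class FocusCurve:
    depths: np.ndarray
    fc: np.ndarray
    d_max: float = np.nan
    amplitude: float = np.nan
    sigma: float = np.nan
    offset: float = np.nan
    resid_rms: float = np.nan
    s: float = np.nan            # selectivity, dB
    used_fallback: bool = False
    fit_slice: tuple[int, int] = (0, 0)


def _peak_regions(y: np.ndarray, fit_fraction: float, min_pts: int):
    """Contiguous sample range around each row's peak where the curve
    stays within ``fit_fraction`` of its range, widened to ``min_pts``."""
    n, m = y.shape
    j = np.argmax(y, axis=1)
    lo = y.min(axis=1)
    thr = lo + fit_fraction * (y.max(axis=1) - lo)
    below = y < thr[:, None]
    idx = np.arange(m)
    bl = below & (idx[None, :] <= j[:, None])
    a = np.where(bl.any(axis=1), m - np.argmax(bl[:, ::-1], axis=1), 0)
    br = below & (idx[None, :] > j[:, None])
    b = np.where(br.any(axis=1), np.argmax(br, axis=1) - 1, m - 1)
    # widen symmetrically to min_pts, spilling across the ends if clamped
    need = np.maximum(min_pts - (b - a + 1), 0)
    ext = (need + 1) // 2
    a = a - ext
    b = b + ext
    b = np.minimum(b - np.minimum(a, 0), m - 1)   # spill left clamp to right
    a = np.maximum(a, 0)
    a = np.maximum(np.minimum(a, b - min_pts + 1), 0)
    return a, b


def _fit_curves(depths: np.ndarray, y: np.ndarray, fit_fraction: float = 0.9,
                min_pts: int = 5):
    """Peak-region Gaussian fit of many focus curves at once.

    Rows are grouped by identical fit range so each group is one batch
    least-squares call.  Returns arrays (d_max, amplitude, sigma, offset,
    resid_rms, converged, a, b).
    """
    n, m = y.shape
    min_pts = min(min_pts, m)
    a, b = _peak_regions(y, fit_fraction, min_pts)
    d_max = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    sig = np.full(n, np.nan)
    off = np.full(n, np.nan)
    rms = np.full(n, np.nan)
    conv = np.zeros(n, dtype=bool)
    keys = a * m + b
    for key in np.unique(keys):
        rows = np.flatnonzero(keys == key)
        aa, bb = int(key // m), int(key % m)
        fit = batch_gaussian_fit(depths[aa:bb + 1], y[rows, aa:bb + 1],
                                 peak_sign=1, baseline="min")
        d_max[rows] = fit.center
        amp[rows] = fit.amplitude
        sig[rows] = fit.sigma
        off[rows] = fit.offset
        rms[rows] = fit.resid_rms
        conv[rows] = fit.converged
    return d_max, amp, sig, off, rms, conv, a, b


def fit_focus_gaussian(depths, fc, fit_fraction: float = 0.9,
                       min_pts: int = 5, clamp: bool = True) -> FocusCurve:
    """Fit one focus curve; ``d_max`` is the fitted Gaussian mean,
    clamped to the hypothesis grid span plus one step.

    Raises :class:`NoPeakError` for a flat curve; a non-converged fit
    falls back to the discrete argmax with ``used_fallback=True``.
    """
    depths = np.asarray(depths, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if len(depths) < 4:
        raise InvalidParameterError("need >= 4 depth samples")
    if np.ptp(fc) == 0:
        raise NoPeakError("focus curve is flat; no peak to fit")
    d_max, amp, sig, off, rms, conv, a, b = _fit_curves(
        depths, fc[None, :], fit_fraction, min_pts)
    curve = FocusCurve(depths=depths, fc=fc, amplitude=float(amp[0]),
                       sigma=float(sig[0]), offset=float(off[0]),
                       resid_rms=float(rms[0]),
                       fit_slice=(int(a[0]), int(b[0])))
    if not conv[0] or not np.isfinite(d_max[0]) or amp[0] <= 0:
        curve.d_max = float(depths[np.argmax(fc)])
        curve.used_fallback = True
        log.info("focus fit did not converge; using discrete argmax")
    else:
        curve.d_max = float(d_max[0])
    if clamp:
        lo = depths[0] - (depths[1] - depths[0])
        hi = depths[-1] + (depths[-1] - depths[-2])
        curve.d_max = float(np.clip(curve.d_max, lo, hi))
    curve.s = selectivity_value(np.max(fc), curve.resid_rms)
    return curve


# ---------------------------------------------------------------------------
# Selectivity and fusion weights
# ---------------------------------------------------------------------------

def selectivity_value(fc_max: float, resid_rms: float,
                      cap_db: float = 120.0) -> float:
    """s = 20 log10(max fc / RMS residual), capped for perfect fits."""
    if not np.isfinite(resid_rms) or resid_rms <= 0 or fc_max <= 0:
        return cap_db
    return float(min(20.0 * np.log10(fc_max / resid_rms), cap_db))


def selectivity(curve: FocusCurve, cap_db: float = 120.0) -> float:
    """Selectivity (dB) of a fitted focus curve."""
    return selectivity_value(float(np.max(curve.fc)), curve.resid_rms,
                             cap_db=cap_db)


def sharpening_param(s, alpha: float = 1.0, s_th: float = 15.0):
    """phi(s) = (1 + tanh(alpha (s - s_th))) / (2 alpha); strictly
    increasing in s with range (0, 1/alpha)."""
    if not alpha > 0:
        raise InvalidParameterError("alpha must be positive")
    return (1.0 + np.tanh(alpha * (np.asarray(s, dtype=float) - s_th))) \
        / (2.0 * alpha)


def fusion_weights(fc: np.ndarray, phi, normalization: str = "max"
                   ) -> np.ndarray:
    """Per-depth weights w(d_i) = (1 + tanh(phi (fc_bar - 1))) / 2.

    ``normalization="max"`` (default) scales the curve to unit peak so
    the peak depth always gets w = 0.5 and off-peak depths are
    suppressed according to phi; ``"sum"`` is the literal
    sum-normalisation.  An all-zero curve yields uniform weights (with a
    warning).
    """
    fc = np.asarray(fc, dtype=float)
    if normalization not in ("max", "sum"):
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    denom = fc.max(axis=0) if normalization == "max" else fc.sum(axis=0)
    denom = np.asarray(denom, dtype=float)
    zero = ~(denom > 0)
    if np.any(zero):
        log.warning("fusion_weights: %s all-zero focus curve(s); uniform "
                    "weights used", np.count_nonzero(zero))
    fbar = fc / np.where(zero, 1.0, denom)
    w = (1.0 + np.tanh(np.asarray(phi, dtype=float) * (fbar - 1.0))) / 2.0
    return np.where(zero, 0.5, w)


def fuse(stack: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-pixel weighted mean of the stack (weights per layer, either
    scalars per layer or full per-pixel maps)."""
    stack = np.asarray(stack, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim == 1:
        weights = weights[:, None, None]
    wsum = weights.sum(axis=0)
    bad = ~(wsum > 0)
    if np.any(bad):
        log.warning("fuse: %d pixels with zero weight sum; unweighted mean "
                    "used there", np.count_nonzero(bad))
    num = (weights * stack).sum(axis=0)
    out = np.where(bad, stack.mean(axis=0), num / np.where(bad, 1.0, wsum))
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionParams:
    window_r: int = 9
    alpha: float = 1.0
    s_th: float = 15.0          # dB
    s_cap: float = 120.0        # dB
    normalization: str = "max"
    stride: int = 1
    fit_fraction: float = 0.9
    min_fit_points: int = 5

    def __post_init__(self):
        if self.window_r < 3:
            raise InvalidParameterError("window_r must be >= 3")
        if not self.alpha > 0:
            raise InvalidParameterError("alpha must be positive")
        if self.stride < 1:
            raise InvalidParameterError("stride must be >= 1")


@dataclass
class DepthMap:
    depth: np.ndarray           # mm, NaN where invalid
    selectivity: np.ndarray     # dB
    valid: np.ndarray           # bool
    grid: ImageGrid


@dataclass
class FusedImage:
    values: np.ndarray
    grid: ImageGrid


@dataclass
class StackingResult:
    depth_map: DepthMap
    fused: FusedImage
    stack: DeconvolutionStack
    params: FusionParams
    focus: np.ndarray | None = None   # (m, H, W) focus maps, optional


def estimate_depth_map(image: TransilluminationImage, optical,
                       params: FusionParams | None = None,
                       depths=None,
                       deconv_config: DeconvolutionConfig | None = None,
                       parse: str = "r", keep_focus: bool = False
                       ) -> StackingResult:
    """Run the full 2D pipeline on a background-removed image:
    depth-swept deconvolution, per-window focus curves, Gaussian-fit
    depth map, selectivity-gated fusion into an all-in-focus image.

    The default deconvolution regularisation here (NSR 5e-3) is stronger
    than the single-shot deblurring default: depth discrimination by
    windowed variance needs over-deconvolution to be penalised.
    """
    params = params or FusionParams()
    if deconv_config is None:
        deconv_config = DeconvolutionConfig(nsr=5e-3)
    optical = as_optical(optical)
    if depths is None:
        depths = default_depth_grid()
    depths = np.asarray(depths, dtype=float)
    stack = sweep_deconvolve(image, depths, optical, deconv_config,
                             parse=parse)
    fc = focus_maps(stack.images, params.window_r)
    m, H, W = fc.shape
    ys, xs = np.mgrid[0:H:params.stride, 0:W:params.stride]
    curves = fc[:, ys.ravel(), xs.ravel()].T          # (npix, m)
    d_max, amp, sig, off, rms, conv, a, b = _fit_curves(
        depths, curves, params.fit_fraction, params.min_fit_points)
    lo = depths[0] - (depths[1] - depths[0])
    hi = depths[-1] + (depths[-1] - depths[-2])
    d_max = np.clip(d_max, lo, hi)
    fc_max = curves.max(axis=1)
    # a focus peak at the sweep boundary means no best-focus depth was
    # found inside the hypothesis range: the window is noise-dominated
    # (deconvolution-sweep noise curves peak at the shallow end) or the
    # true depth is outside the grid; either way the window is invalid
    # and gets zero selectivity, hence maximally smoothing weights
    j = np.argmax(curves, axis=1)
    interior = (j > 0) & (j < curves.shape[1] - 1)
    valid = (conv & np.isfinite(d_max) & (amp > 0)
             & (np.ptp(curves, axis=1) > 0) & interior)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 20.0 * np.log10(fc_max / rms)
    s = np.where(np.isfinite(s), np.minimum(s, params.s_cap), params.s_cap)
    s = np.where(valid & (fc_max > 0), s, 0.0)

    phi = sharpening_param(s, params.alpha, params.s_th)
    w = fusion_weights(curves.T, phi[None, :], params.normalization)  # (m, npix)
    layers = stack.images[:, ys.ravel(), xs.ravel()]
    fused_flat = fuse(layers, w)

    shape = ys.shape
    depth_map = np.where(valid, d_max, np.nan).reshape(shape)
    sel_map = s.reshape(shape)
    valid_map = valid.reshape(shape)
    fused_img = fused_flat.reshape(shape)
    if params.stride > 1:
        depth_map = np.kron(depth_map, np.ones((params.stride,) * 2))[:H, :W]
        sel_map = np.kron(sel_map, np.ones((params.stride,) * 2))[:H, :W]
        valid_map = np.kron(valid_map,
                            np.ones((params.stride,) * 2, dtype=bool))[:H, :W]
        fused_img = np.kron(fused_img, np.ones((params.stride,) * 2))[:H, :W]
    result = StackingResult(
        depth_map=DepthMap(depth=depth_map, selectivity=sel_map,
                           valid=valid_map, grid=image.grid),
        fused=FusedImage(values=fused_img, grid=image.grid),
        stack=stack, params=params,
        focus=fc if keep_focus else None)
    return result


# ---------------------------------------------------------------------------
# Calibration, blur metric, 3D export
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    corrected: np.ndarray


def calibrate_depths(given, estimated) -> CalibrationResult:
    """First-order linear calibration of estimated against given depths:
    OLS fit ``estimated ~ slope * given + intercept`` and the corrected
    estimates ``(estimated - intercept) / slope``."""
    given = np.asarray(given, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if given.size < 2 or np.ptp(given) == 0:
        raise CalibrationError("need >= 2 distinct given depths")
    fit = stats.linregress(given, estimated)
    if fit.slope == 0:
        raise CalibrationError("zero slope; cannot invert calibration")
    corrected = (estimated - fit.intercept) / fit.slope
    return CalibrationResult(slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             r_squared=float(fit.rvalue ** 2),
                             corrected=corrected)


def blur_metric_profile(image: TransilluminationImage, axis: int = 0,
                        min_rel_dip: float = 0.05,
                        smoothing_sigma: float = 1.0) -> np.ma.MaskedArray:
    """Per-row FWHM (mm) of the absorption dip, for before/after blur
    comparisons.  Rows without a detectable dip are masked."""
    vals = image.values if axis == 0 else image.values.T
    sm = (ndimage.gaussian_filter1d(vals, smoothing_sigma, axis=1,
                                    mode="nearest")
          if smoothing_sigma > 0 else vals)
    pitch = image.grid.pitch
    n_rows, m = sm.shape
    out = np.ma.masked_all(n_rows)
    for r in range(n_rows):
        row = sm[r]
        base = row.max()
        dip = base - row.min()
        if dip <= min_rel_dip * max(base, 1e-300):
            continue
        half = base - dip / 2.0
        jmin = int(np.argmin(row))
        below = row < half
        if not below[jmin]:
            continue
        left = jmin
        while left > 0 and below[left - 1]:
            left -= 1
        right = jmin
        while right < m - 1 and below[right + 1]:
            right += 1
        xl = float(left)
        if left > 0:
            xl = left - 1 + (row[left - 1] - half) / (row[left - 1] - row[left])
        xr = float(right)
        if right < m - 1 and row[right + 1] != row[right]:
            xr = right + (half - row[right]) / (row[right + 1] - row[right])
        out[r] = (xr - xl) * pitch
    return out


@dataclass
class Reconstruction3D:
    points: np.ndarray          # (N, 3): x, y, z in mm

    def save_xyz(self, path) -> None:
        np.savetxt(path, self.points, fmt="%.6f", header="x_mm y_mm z_mm")

    def save_ply(self, path) -> None:
        import trimesh

        trimesh.PointCloud(self.points).export(str(path))


def reconstruct_3d(depth_map: DepthMap, fused: FusedImage,
                   segmentation_threshold: float = 0.8) -> Reconstruction3D:
    """Place absorber pixels (fused intensity below threshold) at their
    estimated depths as a 3D point cloud (x, y in the image plane, z =
    depth below the observation surface)."""
    grid = depth_map.grid
    mask = (fused.values < segmentation_threshold) & depth_map.valid \
        & np.isfinite(depth_map.depth)
    if not mask.any():
        log.warning("reconstruct_3d: empty segmentation; no points emitted")
        return Reconstruction3D(points=np.empty((0, 3)))
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([(cols + 0.5) * grid.pitch,
                           (rows + 0.5) * grid.pitch,
                           depth_map.depth[rows, cols]])
    return Reconstruction3D(points=pts)
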