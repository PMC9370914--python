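# transillum3d

Reconstruction of a deblurred 3D absorber structure in a turbid medium
from a **single blurred 2D near-infrared transillumination image**.

Near-infrared light (700–1200 nm) passes through centimetres of body
tissue, so shining a wide beam through a body part and imaging the
transmitted light reveals internal light-absorbing structures — blood
vessels, lesions — as shadows.  Strong scattering, however, blurs any
structure more the deeper it lies, and a plain transillumination image
is 2D.  This package turns that curse into the measurement: the blur of
a shadow is a calibrated function of the absorber's depth, so a single
image carries the third dimension.

## The model

A point absorber at depth `d` below the observation surface of a
diffusive medium casts the shadow kernel (diffusion approximation)

    PSF(ρ; d) ∝ [ μt + (κd + 1/r) · d/r ] · exp(−κd·r) / r,
    r = √(ρ² + d²),  μt = μs′ + μa,  κd = √(3 μa (μs′ + μa))

with reduced scattering coefficient `μs′` (≈1.0 mm⁻¹ in tissue) and
absorption coefficient `μa` (≈0.01 mm⁻¹).  A blurred image is the
convolution `Ib = Io ∗ PSF(·; d)`; kernels are normalised to unit sum.

Two techniques invert this model:

1. **1D lookup-table method** (`transillum3d.profiles`) — for
   curvilinear absorbers (vessels).  Each cross-profile is reduced to
   its Michelson contrast `CM = (Imax − Imin)/(Imax + Imin)` and the
   FWHM of a Gaussian fitted to the absorption dip.  A precomputed
   table over a (depth × diameter) grid is inverted by enclosing-cell
   bilinear interpolation, returning depth *and* diameter per slice;
   with known circular cross-section this yields a 3D reconstruction.
2. **2D focus stacking** (`transillum3d.stacking`) — for volumetric
   absorbers.  The image is Wiener-deconvolved with kernels for a sweep
   of hypothesis depths (default {0.1, 1, 2, …, 30} mm).  Each 9×9
   window's gray-level variance across the stack is fitted with a
   Gaussian whose peak is the window's depth; selectivity-gated weights
   `w(dᵢ) = (1 + tanh[φ(f̄c(dᵢ) − 1)])/2`,
   `φ(s) = (1 + tanh[α(s − s_th)])/(2α)` fuse the stack into an
   all-in-focus image plus a per-pixel depth map, smoothing where the
   focus curve is untrustworthy.

A forward simulator (`transillum3d.phantom`) generates ground-truth
phantoms, blurred images, sensor noise at prescribed SNR, and
background removal, so every stage is testable without instrumentation.

## Worked example

`examples/03_lookup_table_depth.py` builds a coarse table and estimates
an off-grid cylinder:

```
lookup table: 17 depths x 9 diameters
measured features: CM = 0.1148, FWHM = 11.744 mm
true depth     4.330 mm -> estimated 4.331 mm
true diameter  3.000 mm -> estimated 3.000 mm
```

One blurred profile pins the cylinder's depth to ~1 µm and its diameter
to ~1 µm — the (CM, FWHM) pair is in one-to-one correspondence with
(depth, diameter) over the working range.

`examples/04_focus_stacking.py` runs the 2D pipeline on a bar at 5 mm
depth in a 128 mm field:

```
hypothesis depths: 31 (0.1 ... 30.0 mm)
valid windows over the absorber: 1536 / 1536
median estimated depth: 4.84 mm (true 5.0)
windows within one grid step of the truth: 100.0%
dip amplitude, blurred input: 0.211; fused: 0.489
```

The other examples cover kernel rasterisation, the forward simulator
with noise and background removal, and volumetric 3D reconstruction.

A thin CLI mirrors the library:
`transillum3d psf|simulate|lut-build|depth-1d|study|deconvolve|stack|reconstruct`
(see `transillum3d --help`).

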