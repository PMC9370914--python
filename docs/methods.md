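# Methods

This note records the scientific model the package implements, the
numerical choices behind it, and what the synthetic experiments do and
do not demonstrate.

## Light transport model

The medium is characterised by the reduced scattering coefficient
`μs′` (default 1.0 mm⁻¹) and the absorption coefficient `μa` (default
0.01 mm⁻¹), typical of soft tissue in the near-infrared window.  The
depth-dependent point spread function of a point shadow at depth `d`
follows the diffusion approximation,

    PSF(ρ; d) = C [ μt + (κd + 1/r) d/r ] e^{−κd r} / r,
    r = √(ρ²+d²),  μt = μs′+μa,  κd = √(3 μa μt),

with `C` absorbed by unit-sum kernel normalisation.  The typeset source
of this expression is ambiguous about whether the geometric factor and
the outer envelope carry `r` or `r²`; both parses are implemented
(`parse="r"`, the literal reading, is the default; `parse="r2"`
matches the classical diffusion-dipole transmittance and has a much
lighter halo).  Both parses satisfy the properties the methods rely on:
radially monotone decay, kernel width strictly increasing with depth,
and relative width changes smaller than ±20% changes in either optical
coefficient.  Nothing downstream assumes a particular parse; it is a
configuration switch everywhere.

With `κd ≈ 0.174 mm⁻¹` the default kernel has a very broad multiple-
scattering halo: the radius enclosing all but 10⁻⁴ of the kernel mass
is 50–70 mm at all relevant depths.  Consequences are drawn in several
places below.  At `μa = 0` the kernel is not normalisable and
rasterisation refuses with a truncation error.

Kernels are sampled at pixel centers (4×4 supersampling when
`d < 2·pitch`), rasterised on odd-sized grids, and normalised to unit
sum so blurring conserves total intensity.  The default support radius
meets a tail tolerance of 10⁻⁴; an explicit smaller radius either
raises a truncation error (strict mode) or truncates and renormalises
(used by the 2D pipeline, where kernels are capped near the image
half-extent).

## Forward simulator

Phantoms are binary occupancy maps with a per-pixel true depth.
Absorbers act multiplicatively on a unit background, `Io = 1 − a·occ`
with absorptance `a = 1` by default (matte black).  For depth-varying
phantoms the depth map is quantised into 0.1 mm strata and each
stratum's shadow is blurred with its own kernel; because the strata are
disjoint in the image plane (each line of sight meets the absorber at
one depth), the blurred shadow *deficits superpose linearly* and the
single-depth case reduces exactly to one convolution.  Boundaries use a
half-sample-symmetric extension, under which a symmetric kernel
conserves the image mean exactly; a periodic option exists for tests
that invert the exact discrete operator.

Sensor noise is additive white Gaussian, scaled so that
`20·log₁₀(RMS contrast of the clean image over the absorber-affected
region / σ)` equals the requested SNR in dB (the experimental range
0.8–21 dB is the default sweep in noisy studies).  Background
non-uniformity is removed by dividing by an absorber-free reference
image, with sub-floor reference pixels masked and counted.

For infinite straight cylinders the 2D blur collapses exactly to a 1D
convolution with the kernel's line spread function, the Abel transform
of the radial profile.  The LSF is computed with a quadrature matrix
(piecewise-linear radial profile, closed-form segment integrals), so
the full profile databank is two matrix products; the tests verify the
LSF against column sums of the brute-force 2D kernel (≲10⁻³ relative).

## 1D lookup-table depth estimation

Profile features: the profile is low-pass filtered (Gaussian, σ = 2
samples) and an offset Gaussian dip is fitted by least squares.  The
Michelson contrast uses `Imax = min(fitted plateau, smoothed max)` and
`Imin = max(fitted dip bottom, smoothed min)` — the fit is the robust
side under noise, the smoothed extremes are the robust side for
flat-bottomed (rect-like) dips where a Gaussian overshoots.  The dip
width is `FWHM = 2√(2 ln 2)·σ_fit`.  Both indices are therefore smooth
functions of (depth, diameter), which is what the table inversion
needs; their absolute bias against other width conventions is
irrelevant because the table and the queries share one extractor.

The table spans depth and diameter 1.0–10 mm at 0.1 mm steps by
default (91×91); the full-scale error study extends the depth axis down
to 0.1 mm (100×91) because the method is exercised over 0.1–10 mm.
Construction verifies that CM strictly decreases and FWHM strictly
increases along depth for every diameter and records violations.

Inversion: features are rescaled by their table-wide standard
deviations; the enclosing grid cell in feature space is found from the
query's nearest nodes (k-d tree) and inverted with a 2×2 Newton
iteration of the bilinear map; the four cell corners are the "four
closest grids" whose depths/diameters are interpolated.  Queries on the
mapped region's outer boundary can fall outside every bilinear cell by
the chord-vs-arc gap; a boundary tolerance of 5% of a cell clamps such
queries onto the edge cell.  Queries inside the convex hull for which
no cell inverts fall back to inverse-distance weighting of the four
nearest nodes (logged); queries outside the hull are *inestimable* — a
value, never an exception.

Full-scale study (19 diameters × 991 depths = 18,829 noise-free
profiles at 0.1 mm/px): 0.02% inestimable, mean |depth error| ≈ 0.1 µm,
worst case ≈ 5 µm.  The test grid's 1,900 (diameter, depth) pairs that
coincide with table nodes are counted separately and the error mean is
reported with and without them (0.11 µm vs 0.12 µm).  Depth accuracy is
essentially independent of the absorber diameter (per-diameter means
0.05–0.17 µm), the operational meaning of "no cross-talk": the diameter
need not be known a priori.

Slice-wise cylinder reconstruction estimates each image row's profile
independently.  Slices within ~2 mm of a bar's ends are not straight-
line pieces of an infinite cylinder and their features are biased by
the end transition; interior slices of a 21 dB inclined bar (3 mm
diameter, depths 2.2–5.0 mm) recover depths within 0.3 mm wherever the
true depth is ≤ 4 mm, with the deeper part increasingly overestimated
as contrast fades — at lower SNR the error grows with depth.

## Deconvolution

Wiener deconvolution with a flat noise-to-signal power ratio (NSR) is
the default; the filter is scaled to exact unit DC gain, so flat fields
and background levels are preserved at any regularisation strength.
Richardson–Lucy is available as an alternative.  Images are padded by
the kernel radius (symmetric by default) before the frequency-domain
division and cropped afterwards.

Two regularisation regimes are deliberate:

* deblurring at a known depth uses a light NSR (10⁻³ default, 10⁻⁵ in
  the width-halving checks): matched deconvolution then halves the
  profile FWHM for depths 2–10 mm, and inverting the exact periodic
  operator recovers the unblurred image to <5% relative L2;
* the depth-sweeping estimator uses NSR 5·10⁻³: depth discrimination
  by windowed variance requires over-deconvolution to be penalised.  A
  noise-free phantom sweep fixed this default — at 10⁻³ the variance
  peak drifts several millimetres deep (d = 12 mm reads ≈19 mm), at
  ≥10⁻² it drifts shallow; 5·10⁻³ puts the peak at the true depth
  across 2–12 mm.

The standard hypothesis grid is {0.1, 1, 2, …, 30} mm (31 images).

## Focus stacking

Focus is the gray-level variance of a 9×9 window (a sum, not a mean,
of squared deviations); window maps are computed with sliding uniform
filters, stride 1, reflective borders.  The focus curves of a
deconvolution sweep are intrinsically asymmetric — variance decays
slowly on the over-deconvolution side — so the Gaussian is fitted to
the contiguous peak region (samples within 10% of the peak, at least
5 points, widened symmetrically); a full-curve fit biases the peak
location by millimetres even without noise.  `d_max` is the fitted
mean, clamped to the grid span ± one step.

Validity and selectivity: in a deterministic sweep of a single noisy
image, noise-dominated windows produce *smooth* curves peaking at the
shallow end of the sweep (shallow kernels pass the high-frequency noise
essentially unfiltered; deep Wiener kernels suppress it), so
goodness-of-Gaussian-fit alone does not separate noise from structure.
A window is therefore valid only if its focus peak is interior to the
sweep; invalid windows get selectivity `s = 0`, otherwise
`s = 20 log₁₀(max fc / RMS residual)` (capped at 120 dB).  On a
pure-noise image essentially every window is invalid and below the
15 dB threshold.

Fusion: `φ(s) = (1 + tanh[α(s−s_th)])/(2α)` with defaults `α = 1`,
`s_th = 15 dB` (the fused-image metrics below are insensitive to α over
0.25–1), and weights `w = (1 + tanh[φ(f̄c − 1)])/2` with the
focus curve normalised to unit peak (`normalization="max"`).  The
literal sum-normalisation is available behind a switch but collapses
the weight function (all `f̄c − 1 ≈ −1`); this inconsistency in the
source formulas is resolved in favour of the working variant.  Invalid
windows get `φ ≈ 0` and hence near-uniform weights: the fused value
there is close to the plain stack mean, which suppresses the amplified
noise of any single deconvolved layer.  On a 10 dB inclined bar the
fused background noise is ~5× below that of the single best-focus
layer.  Fusion restores dip contrast (≈2.3× the blurred input on the
standard bar, matching the matched layer) and never widens a profile
beyond the blurred input; it does not narrow the FWHM below the input,
because halo pixels flanking an absorber select deep layers where the
halo persists — a known limitation of variance-based focus around
smooth shoulders.

Depth maps over single-depth phantoms at 2–12 mm recover `d_max`
within one grid step for ≥95% of absorber windows.  Remaining
systematic bias grows with depth (and with flat absorber interiors);
`calibrate_depths` fits the first-order linear relation between given
and estimated depths (OLS, reported with R²) and inverts it, mirroring
the calibration step of the physical experiments.

## Working scales

The 1D machinery works at 0.1 mm/px with 30 mm profile half-lengths.
The 2D pipeline experiments run at 0.5 mm/px on 256² images (a 128 mm
field): the kernel halo must fit the field, and at 0.1 mm/px a 256²
image (25.6 mm) truncates the kernels so severely that deconvolution
and focus selection degrade.  These sizes keep the full test suite and
the acceptance run to a few minutes on one CPU while exercising the
methods at their full depth ranges.

## What the synthetic experiments do not show

The forward model is the same closed-form PSF the estimators invert —
model error of the diffusion approximation against real tissue is not
probed.  Sensor noise is white and Gaussian; real cameras add
structured noise, and real backgrounds are only approximately removed
by reference division.  Absorbers are ideal (full absorptance, crisp
silhouettes); partial absorbers are supported via the absorptance
parameter but untested against data.  The physical-phantom numbers of
the source experiments (R², percent error of calibrated depths, width
suppression at 30 mm depth) depend on that instrumentation and are
replaced here by the synthetic counterparts described above.
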