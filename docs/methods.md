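# Methods

`conemetrics` quantifies the cone photoreceptor mosaic from point patterns
and images, and measures agreement between graders and between imaging
devices. This note records the models, conventions and numerical choices the
package makes, and what its synthetic data can and cannot stand in for.

## Coordinate and image conventions

All point coordinates are continuous micrometres in a y-down image frame
with the origin at the patch's top-left corner. Pixel (row 0, col 0) is
centred at (0.5·scale, 0.5·scale) µm, so a point at (x, y) µm maps to pixel
column `x/scale − 0.5`. Scales are isotropic (one µm/pixel value for both
axes).

## Image scale from ocular biometry

Linear retinal scale is derived from the angular scan geometry via an
assumed retinal magnification factor (RMF) of 291 µm/deg for a reference
eye of 24.0 mm axial length, scaled linearly with the subject's measured
axial length AL:

- scan-angle devices: `scale = (θ/I_s) · RMF · (AL/24)` with θ the scan
  size in degrees and `I_s` the raw pixel count. `I_s` is a required
  parameter, never hard-coded, because device modes (high-speed vs
  high-resolution) change it.
- Ronchi-calibrated AO scanners: `scale = (T/(f₁·T_s)) · (180/π) · RMF ·
  (AL/24)`, where `T/(f₁·T_s)` is the angular subtense of one pixel in
  radians measured by imaging a ruling of period `T` µm/cycle through a
  model eye of focal length `f₁` µm at `T_s` pixels/cycle.

Both RMF and the reference axial length are overridable; other schematic
eyes exist. No refractive-correction magnification model is included.

## Mosaic metrics

Given cone coordinates and an axis-aligned region of interest (ROI,
default 200 × 200 µm = 0.04 mm²):

- **Bound Voronoi density.** All supplied points are tessellated (points
  outside the ROI are required to close the cells of points near its edge).
  A cell is *bound* iff its polygon is finite and every vertex lies inside
  the closed ROI; a vertex exactly on the boundary counts as inside. The
  density is `n_bound / Σ(bound cell areas)` in cones/mm² — dividing by the
  summed cell area, not the ROI area, which makes the hexagonal closed form
  exact: a jitter-free lattice of spacing s gives exactly `2/(√3·s²)`.
- **NND.** Mean, over points inside the ROI, of the distance to the nearest
  other point, with neighbour candidates drawn from all points. No
  tessellation is needed, so all ROI points contribute.
- **ICD.** Per bound cell, the mean distance to its Delaunay (= Voronoi)
  neighbours, bound or not; reported as the mean over bound cells.
  Adjacency of unbounded cells is unreliable, hence the bound-cell
  averaging set. Mean NND can never exceed mean ICD, because the nearest
  neighbour is always a Voronoi neighbour.

Exactly degenerate inputs (cocircular quadruples that break the Qhull
tessellation) are retried after a deterministic 1 nm coordinate nudge
(fixed seed), keeping results reproducible. Reported tables round densities
to whole cones/mm² and spacings to 0.01 µm; the in-memory API keeps full
precision. The hexagonal density↔spacing conversion used throughout is
`s = 1000·√(2/(√3·d))` (d in cones/mm², s in µm).

ROI co-localization between modalities applies a 2×3 affine transform to
the ROI *centre* only and keeps the physical size and axis alignment;
rotation/shear components are discarded and logged, and transforms whose
linear determinant is outside [0.8, 1.25] are flagged as far from rigid.

## Synthetic mosaics and rendering

The generator produces a row-offset hexagonal lattice with spacing set by
the requested density, clipped to the field, then applies isotropic
Gaussian positional jitter (clamped to the field) and Bernoulli dropout.
One global integer seed feeds independent sub-streams for mosaic, render
and grader via `numpy.random.SeedSequence` spawning, so components are
reproducible independently.

Rendering emulates a reflectance image stack: each cone is a Gaussian spot
(σ = `psf_sigma`), with a per-cone per-frame lognormal brightness
multiplier of unit median and coefficient of variation `reflectance_cv`
(short-term variation in cone reflectivity), a rigid per-frame translation
drawn from N(0, `motion_sd`²) per axis (eye motion; intra-frame scanner
distortions are out of scope), an optional central hyperreflective Gaussian
blob (the internal-reflection artifact seen in non-AO scanner images; its
size and amplitude are free parameters, as no quantitative model of the
real artifact exists), and additive Gaussian readout noise. A warning is
issued when `pixel_scale ≥ 2·psf_sigma` (undersampled render).

The default render (psf 1.5 µm, 1 µm/px, cv 0.15, noise SD 2% of spot
peak, 15 frames, motion SD 1 µm) represents a good-quality averaged
acquisition at the analysis scale. Modality presets differ in blur,
reflectance variability and motion (AO-like: psf 1.2 µm at 0.75 µm/px;
non-AO-like: psf 2.5 µm at 1.5 µm/px), emulating the poorer effective
resolution of the non-AO channel after export to a common analysis scale.

What the synthetic data does **not** emulate: optical aberrations and their
field dependence, rods, disease-related mosaic disruption, intra-frame
(sinusoidal/strip) scanner distortion, vignetting, or grader bias that
depends on image content. Passing tests therefore demonstrate the
correctness of the measurement and statistics pipeline under controlled
conditions, not performance on clinical images.

## Grader model

Graders are modelled as: isotropic Gaussian mark jitter, Bernoulli misses
at `miss_rate`, and spurious marks as a spatial Poisson process
(`false_rate` per mm²). In the study runner each grader's miss rate is
redrawn per ROI from a truncated normal (SD 0.10, clipped to [0, 0.5])
around a grader-specific base rate (2% and 5%), representing fluctuating
attention; this per-ROI variability is what sets the inter-grader ICC
scale, while the base-rate difference sets the systematic inter-grader
bias (a few hundred cones/mm², matching the order of real inter-grader
biases).

## Registration, averaging and detection

Frames are aligned by translation-only phase cross-correlation (subpixel by
upsampled correlation): shifts are estimated against frame 0, the reference
is re-chosen as the aligned frame with the highest mean Pearson correlation
to the others, and shifts are re-expressed relative to it. Frames whose
estimated shift exceeds a quarter of the frame are flagged. Frame selection
ranks frames by correlation to the stack median image and averages the top
`keep_frac` (mean projection); averaging n frames with i.i.d. noise reduces
background SD by √n.

Cone detection: optional Wiener (Tikhonov-regularized) deconvolution with a
Gaussian transfer function when the PSF is known or estimable
(`deconv_sigma`, regularizer 3e-4); difference-of-Gaussians band-pass with
sigmas (`lowpass_sigma`, 2·`lowpass_sigma`); local maxima above the
`threshold_quantile` of the band-pass intensity (quantile thresholding makes
detection invariant to positive affine intensity rescaling); greedy
non-maximum suppression within `min_separation` (brighter wins, ties broken
by lower y then lower x); 1-D quadratic subpixel refinement clipped to
±0.5 px; then manual removals (nearest match within a radius) and additions,
in that order — the "semi-automatic" workflow.

The deconvolution step matters near the resolution limit: for a hexagonal
mosaic of spacing s blurred by a Gaussian of width σ, the first-harmonic
contrast falls as `exp(−σ²|G|²/2)` with `|G| = 4π/(√3·s)` — about 1.5% of
the mean at σ = 0.4s — so plain band-pass peak finding fails there while
PSF-matched deconvolution restores per-cone contrast. Beyond σ ≈ 0.45s
detection degrades monotonically as neighbouring cones merge into single
detections; this is the mechanism by which blur depresses measured density.
The `threshold_quantile` default (0.80) suits densely packed mosaics where
spots cover most of the field; sparse patterns need a higher quantile.

## Agreement statistics

- **ICC.** One-way random-effects ANOVA estimator
  `(MS_between − MS_within)/(MS_between + (k−1)·MS_within)` with the
  F-based Searle 95% interval. This is the classical ICC(1) that the
  common R implementations compute; two-way variants are out of scope.
  Zero within- and between-variance makes the estimate undefined; 1 is
  returned with a degenerate CI and a warning.
- **Bland–Altman.** Differences are A − B with A the first-listed rater or
  device; bias = mean difference; limits of agreement use the classical
  1.96 multiplier (not t-based); the bias CI is t-based; each limit's CI
  uses the large-sample variance approximation 3·SD²/n. Whether real
  spreadsheet analyses used t or normal quantiles for the LoA CIs is not
  knowable; the classical choice is documented here.
- **Percent bias** is expressed relative to the grand mean
  `(mean_A + mean_B)/2`, the Bland–Altman convention. Note that a device
  reading lower by a fraction f of the other device's value produces a
  percent bias of `200f/(2−f)`, not 100f.
- **Regression** of paired differences on a covariate is ordinary least
  squares with a two-sided t-test on the slope. Constant differences yield
  slope 0 and r² = 0 by convention.
- **Detectable difference.** Minimum detectable difference as % of the
  mean, via t-quantiles: two-sample
  `δ = (t₁₋α/2,2n−2 + t_power,2n−2)·sd·√(2/n)`; paired
  `δ = (t₁₋α/2,n−1 + t_power,n−1)·sd/√n`. For mean 15,528, SD 1808,
  n = 48, power 0.80, α 0.05 the two-sample form gives 6.73% (paired:
  6.66%); published reports of this design print 6.75%, and the exact
  design behind that figure (paired vs two-sample, t vs normal quantiles)
  is ambiguous — the small residual discrepancy is documented rather than
  resolved.

## Simulated study design

The study runner mirrors a two-device, two-grader comparison: 30
participants, 80% of whom yield analyzable images on the second device
(Bernoulli), two ROIs each (superior eccentricity 6.7° ± 1.6° clipped to
3.0–10.0°, temporal 5.7° ± 1.7° clipped to 2.9–9.1°). Density falls with
eccentricity as a two-parameter power law `d(e) = 15528·(e/6)^−0.7`,
clipped to the observed range [6741, 18798] cones/mm²; the exact normative
curve is out of scope. Mosaic jitter is 0.12× spacing.

The inter-device effect is modelled as the second device failing to resolve
a random fraction f of cones in the *same* mosaic (thinning), with f chosen
from the target grand-mean percent bias p via `f = 2p/(200+p)` (default
p = 24% → f ≈ 0.214). Grader-averaged per-ROI values feed the inter-device
Bland–Altman and the difference-vs-eccentricity regressions, matching the
convention of averaging the two observers before inter-device analysis.

The runner has two observation modes: a coordinate-level mode (graders mark
the resolved ground-truth coordinates directly), used for the statistical
recovery experiments, and a full render mode (render → register → average →
detect → grade) exercised end to end at small problem sizes. Statistical
calibration experiments use 48 ROIs per replicate (24 participants, all
analyzable), the size of the real analyzable sample.

## Problem sizes and numerical tolerances

Closed-form lattice checks use 40×40-spacing fields with a centred ROI of
half that extent (edge cells never touch the ROI). Oracle equivalence is
checked on 200 random patterns of ≤ 40 points against an independent
shapely half-plane-intersection Voronoi oracle (identical bound-cell sets;
values to 1e-9 relative). Percent-bias recovery uses 20 replicates of 48
ROIs; ICC recovery uses 2000 simulated 48×2 tables. The NND ≤ ICD
invariant is checked on 10⁴ random mosaic configurations on a 70 µm field.
These sizes were chosen so the whole suite runs in a few minutes on one
core while keeping Monte-Carlo error well under the asserted tolerances.

## Known limitations

- The bound-cell rule (a cell intersecting the ROI boundary is excluded
  entirely) is one of several conventions in use; whether published NND/ICD
  figures averaged over bound cells only or all ROI cells is generally
  unstated. This package's defaults are: NND over all ROI points, ICD over
  bound cells.
- The detector is a generic spot finder; no claim of equivalence with any
  specific proprietary cone-marking tool is made.
- Registration is translation-only, matched to the synthetic motion model;
  affine registration of real scanner data is an extension point.
- Real-data results (ICC magnitudes, metric ranges, regression r²) depend
  on image banks that cannot be redistributed; the simulation reproduces
  the study's arithmetic and its statistical machinery, not its images.
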