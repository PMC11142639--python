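# Methods

This note documents the measurement models implemented in `gocquant`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic validation does and does not establish.

## Geometry and conventions

Rasters are ordered `(y, x)` (planes) and `(z, y, x)` (volumes); indices
are 0-based and physical coordinates are voxel centers in µm. SWC filament
files keep their native `(x, y, z)` column order; the conversion is
confined to `image_io`. Calibration is mandatory: an image without a pixel
size in its metadata cannot be read without an explicit override — there
is no silent 1 µm default.

The oocyte is modelled as a circle (2D) or sphere (3D) with an explicit
zona-pellucida thickness (default 7 µm, the mature mouse value). All
distances to "the oocyte surface" are signed sphere distances,
‖p − c‖ − r: positive outside, negative inside. TZP measurements only ever
evaluate it outside the oocyte, where the sign question does not arise. A
least-squares (Kåsa) circle fit to the brightest cortical pixels is
provided for images without a user-supplied model; the oocyte is treated
as ideally circular — manual polyline tracing of an irregular contour is
out of scope.

## Equatorial TZP counting

On an equatorial section the TZPs cross the dark zona as thin bright
radial streaks. The counting procedure:

1. **Background**: median intensity over an interior disk of radius
   0.7 × oocyte radius. The median is robust against interior texture and
   the fraction excludes the bright actin cortex; the mean is available as
   a config choice.
2. **Profile**: bilinear interpolation along the closed circle of radius
   r + zona/2 (mid-zona), at uniform arc steps of one pixel by default.
   The sample count is ⌈circumference/step⌉.
3. **Peak rule**: sample *i* counts iff it exceeds the background and is
   *strictly* greater than both circular neighbours. Plateaus therefore
   never count, the first and last samples are neighbours, and at most
   every second sample can be a peak (counts are bounded by ⌊n/2⌋).
4. **Normalization**: raw count / oocyte diameter, in TZPs per µm.

**Smoothing.** By default the profile is smoothed with a 5-sample circular
boxcar before peak calling (0.5 µm at the default sampling — a kernel
matched to the ~0.4 µm TZP width). The strict local-maximum rule is
designed for optically blurred acquisitions; applied to an unblurred
profile it counts single-sample noise excursions as peaks. On synthetic
1024² sections with Gaussian read noise at 20% of the TZP-to-cytoplasm
contrast, the bare rule miscounts by tens of percent, a 3-sample boxcar
still leaves ~6% error, and the 5-sample boxcar brings the mean count
error below 1% while leaving noiseless counts exact. `smooth_width=0`
applies the bare rule (the literal-rule unit tests do).

The guarantee of exact noiseless recovery presumes resolvable structures:
peaks at least ~3 sampling steps apart at the mid-zona radius, which the
generator enforces at construction (and refuses to violate).

## 3D morphometrics

**Cell segmentation.** The membrane channel is thresholded, closed
morphologically (3D cross structuring element), enclosed interiors are
filled, and connected components are labelled. Components with volume
strictly below `min_volume` (default 100 µm³) are discarded — granulosa
cells at this stage are ~150–450 µm³, so the filter removes debris and
membrane fragments. A threshold below the data minimum is rejected (it
would select every voxel).

**Volume, area, sphericity.** V is the voxel count times the voxel
volume. A comes from a marching-cubes mesh of the label mask; voxel-face
counting is rejected because it overestimates the area of smooth shapes by
up to ~50% and makes a sphere score Ψ ≈ 0.75. The binary mask is smoothed
with a Gaussian of one coarse-voxel physical width before meshing: the 0.5
level set of the smoothed field tracks the true boundary, removing the
residual ~8% staircase overestimate (a digitized 5 µm sphere at 0.2 µm
voxels then scores Ψ = 1.001). Sphericity is the Wadell ratio
Ψ = π¹ᐟ³(6V)²ᐟ³/A — 1 for a sphere, decreasing with anisotropy.

**Filaments.** TZP traces enter as ordered polylines (start = cell body,
end = tip) with per-point radii; tracing itself (a semi-automated,
proprietary workflow in practice) is not re-implemented — the measurements
are. Length is the polyline arc length; mean width is the mean of
per-point diameters floored at 0.1 µm (the minimum resolvable TZP
diameter); `filament_to_spots` places points at arc-length multiples of
the spacing (default 0.2 µm, the acquisition z-step), always including
start and tip, so the last interval may be shorter.

**Orientation.** Δ = d(start) − d(tip). Δ > 0: the tip is closer to the
oocyte than the origin ("toward"); Δ < 0: "away"; Δ = 0 exactly is
reported as "neutral" — measure-zero for real traces but reachable for
synthetic tangential ones — and is counted in the denominator of the
per-cell away-proportion. |Δ| ≤ L always, and Δ = L exactly for a straight
radial filament. Per-cell aggregation reports count, mean length/width,
mean Δ, and the away proportion; a cell with no filaments reports missing
(NaN) means and proportions rather than zeros, and filaments without a
parent cell are an error rather than silently dropped.

## FRAP

The coupling assay bleaches calcein in the oocyte over 60 bleach rounds
(one minute) and records the oocyte and surrounding granulosa-ring
intensities before bleaching and after every 10th round, i.e. at
t = 10 … 60 s. The primary statistic is the recovery ratio
R = F_oocyte(final)/F_oocyte(pre-bleach). A second, "double" normalization
([F_gran(t)/F_gran(pre)] / [F_oocyte(t)/F_oocyte(pre)]) is implemented as
an explicitly labelled experimental variant: it is one defensible reading
of a bleaching-depth correction whose published description is not a
well-formed formula, and it is not used by any default path.

The validation simulator is a two-compartment exchange model: the
granulosa reservoir is large and constant, the oocyte relaxes toward it as
F(t) = F_res − (F_res − F₀)e^(−kt), so the normalized curve is
1 − b·e^(−kt) with b the bleached fraction. Consequences used as oracles:
R = 1 − b at k = 0; R → 1 as k → ∞; R is monotone in k; and a
least-squares fit of (k, b) to a noiseless curve recovers k to well under
1%. Per-round bleach physics, intra-compartment diffusion, and dye
photochemistry are deliberately not modelled.

## Statistics

Groups are summarized as mean ± SEM (sample SD, ddof = 1, over √n); SEM
for n = 1 is reported missing, not zero. Percent change is
100·(mean_ref − mean_test)/mean_ref, positive for a reduction — the
direction in which the effects of interest are phrased. The default
two-sample test is Student's pooled-variance t-test (the convention of the
originating analyses); Welch is available by flag. One-sample tests serve
normalized ratios tested against 1. Degenerate zero-variance inputs with
equal means are defined as t = 0, p = 1. No multiple-testing correction is
applied, matching the source workflow. Relative expression is 2^(−ΔΔCt)
with a reference gene (default *Rpl19*) and a calibrator group; the
calibrator's fold changes have geometric mean 1 per gene by construction.
Each input row is treated as one independent observation; pooling across
experiments is left to the caller.

## Synthetic generator

The generator emulates the *geometry and contrast* of the specimens, not
their optics. Defaults describe a mid-growth mouse complex: oocyte radius
30 µm, zona 7 µm, 40 TZPs per equatorial section (~0.67/µm of diameter,
the observed order of magnitude), TZP length 4.6 ± 0.8 µm and width
0.4 µm (the wild-type means), pixel 0.1 µm, voxel 0.1 × 0.1 × 0.2 µm,
granulosa cells of ~320 µm³ (radius ~4.25 µm). Intensities are arbitrary
units with TZP 200, cytoplasm 50, background 10, Gaussian read noise
(default SD 5; Poisson shot noise optional).

Filaments are rendered as capsules with a Gaussian radial profile
(σ = width/2.355, i.e. FWHM = width) composited by maximum; tortuosity is
a seeded small-angle random walk of the heading (rad/√µm). TZP angular
positions are jittered even spacing — jitter bounded to ±30% of the
nominal spacing so the minimum gap is ≥40% of it — with a random global
rotation; surface density and angular distribution are free parameters,
not biological claims. 3D cell bodies are ellipsoids whose membrane is a
Gaussian shell with its ridge pulled half the membrane FWHM inward, so the
half-maximum surface — and hence a half-peak segmentation threshold —
coincides with the true cell boundary; truth volumes are the analytic
4πabc/3.

Two-group experiments impose relative effects by scaling the treated
group's generative means by (1 + effect). Per-cell TZP counts are Poisson
around the group mean (base mean 16, the wild-type per-cell scale; real
per-cell counts are somewhat over-dispersed relative to Poisson, so the
simulated power is an upper end), cell volumes are lognormal with 20% CV,
and per-specimen seeds derive deterministically from the master seed.
Group simulations produce geometric filament datasets (polylines plus
truth volumes) rather than rasterizing dozens of full 3D stacks; the
measurements still flow through the same pipeline functions
(`filament_length`, `orientation_delta`, `aggregate_per_cell`), so what is
bypassed is rendering and re-segmentation, not measurement. Validation
sizes: 1024² sections for counting (20 noise seeds), a few-million-voxel
stack for segmentation, 100 replicates of n = 25/group for effect
recovery, 10,000 replicates for null calibration.

**What passing tests show — and don't.** Ground-truth recovery on this
generator establishes that the measurement code is correct: the peak rule
counts what is there, volumes and Δ match construction, imposed effects
are recovered with calibrated error rates. It does not establish
robustness to everything real acquisitions add — the point-spread
function, depth-dependent attenuation, overlapping granulosa cell bodies
occluding the zona, non-spherical oocytes, or tracing errors upstream of
the polylines. Those belong to acquisition and tracing, which this
package deliberately treats as inputs.

## Numerical choices and edge cases

* Strict inequalities throughout the peak rule; ties (plateaus) never
  count. Background equal to a constant profile yields zero peaks.
* The volume filter is exclusive (`< min_volume` deleted), so a cell at
  exactly the threshold survives.
* `filament_to_spots` pins the first/last spot to the exact endpoints,
  immune to interpolation rounding; a filament shorter than the spacing
  yields exactly two spots.
* Sphericity is capped only by discretization (documented ε ≈ 0.05 above
  1 for near-spheres at coarse voxels; measured ≈ 0.001 at 0.2 µm voxels).
* The FRAP fit is bounded (k ≥ 0, 0 ≤ b ≤ 1) and initialized from the
  first post-bleach sample; for k = 0 the model is flat and k is returned
  at its boundary.
* All generator randomness flows from `numpy.random.default_rng(seed)`;
  identical spec + seed reproduce outputs bit-for-bit, and scaling all
  intensity parameters leaves every geometric truth unchanged.

## Known limitations

* The equatorial counter attributes no peak to a particular granulosa
  cell; per-cell counts require the 3D pathway.
* The sphere oocyte model mis-measures Δ for markedly non-spherical
  oocytes; a mesh-based surface would be needed there.
* Segmentation assumes closed membrane shells; fragmented membranes
  produce under-segmented or leaked components and must be edited
  upstream.
* The double-normalized FRAP curve is experimental and should not be
  compared across studies without checking the intended correction.
* Poisson per-cell counts understate biological over-dispersion; power
  estimates from the group simulator are accordingly optimistic.
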