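# Methods

## Measurement model

A cardiac-gated phase-contrast acquisition is represented as four arrays
`[x, y, z, t]`: three velocity components (cm/s) and a magnitude image, with
a NIfTI affine mapping 0-based voxel indices (voxel-centre convention) to
world mm.  Flow through a vessel is measured on a perpendicular plane
defined by a centre point and a direction vector.  The in-plane basis is
deterministic: with unit direction *u*, the reference axis is world-z unless
|u·ẑ| > 0.9 (then world-x), e₁ = normalize(r × u), e₂ = u × e₁; the basis
is right-handed (e₁ × e₂ = u), so resliced images have a reproducible
orientation.

Velocity components and magnitude are resampled onto the plane by trilinear
interpolation, independently per component and timeframe, *before*
projection onto *u* (for a constant *u* the order is mathematically
irrelevant; interpolating components keeps a slice reusable for other
directions).  Trilinear interpolation is exact at voxel centres and
reproduces linear fields everywhere; its smoothing is absorbed by the
tolerance budget of the validation studies.  Plane pixels default to half
the smallest voxel dimension (0.5 mm at the 4D protocol's 1 mm), which
reduces lumen-boundary quantisation.  Pixels falling outside the volume are
zero-filled and flagged rather than treated as errors, because clinical 4D
volumes routinely clip the desired vessel segments.

## Corrections

**Aliasing.**  True velocities beyond ±v_enc wrap by ±2·v_enc.  The unwrap
rule operates per timeframe on the vessel-ROI pixels: any velocity at or
above the ROI median + v_enc is shifted by −2·v_enc, at or below the median
− v_enc by +2·v_enc, in a single pass (double wrapping is out of scope).
The median is taken over the ROI, not the image — a whole-image median would
be dominated by static tissue.  The rule's guarantee needs the *measured*
median to sit in the un-aliased bulk: when the majority of an ROI aliases,
the median itself wraps and no median-referenced rule can recover the
values.  The validation therefore exercises the clinically relevant regime
(a minority of fast systolic core pixels aliased over a slow bulk).

**Background phase.**  Eddy-current-like phase offsets are modelled static;
the correction subtracts the mean v_∥ over a background ROI averaged across
the cardiac cycle.  A per-frame correction would subtract real pulsatile
signal leakage, so it is deliberately not offered.  For a linear offset
field the residual flow error equals (mean over vessel ROI − mean over
background ROI) × ROI area — exact to numerical precision, verified against
that closed form.

**Order.**  Unwrapping precedes background correction by default (wrapping
is an artefact of the raw values; the offset is small relative to v_enc so
it does not change wrap classifications in practice); the order is a config
switch.

## Flow parameters

Per timeframe, flow is the sum of ROI pixel velocities times pixel area
(cm/s·mm²·0.01 → ml/s).  Summary parameters: mean flow, extremes, and the
adapted Gosling pulsatility index PI = (Q_max − Q_min)/Q_mean computed from
the lumen-summed volumetric waveform — pixelwise PIs averaged over the lumen
would amplify noise.  PI is undefined (reported missing, never infinite)
when mean flow is zero.  Because the spatial-resolution-induced gain on a
steady geometry is constant over the cycle, PI is nearly immune to
resolution bias even where mean flow is not; the validation exploits this.

The mass-conservation check compares summed mean inflow (two carotid-like +
one basilar-like vessel) with summed cerebral outflow; the residual as a
percentage of inflow gauges measurement precision.  Sign convention: inflow
− outflow, negative meaning higher measured cerebral flow.

## Segmentation

The helper segmentation thresholds the time-averaged magnitude at k times a
reference maximum and keeps the 8-connected component containing the seed
(default: brightest) pixel; the background ROI is a surrounding ring
(default gap 1 mm, width 1.5 mm).  The reference maximum is the 99.5th
percentile rather than the literal maximum, which on a noisy image is an
outlier statistic that inflates the threshold and shrinks masks.  For flux
integration the studies dilate the mask by 1 mm (one acquisition voxel):
voxel averaging smears velocity support beyond the lumen, and a mask that
stops at the intensity contour systematically loses flux (several percent at
1 mm for a 3 mm vessel).  Manual-ROI workflows draw similarly generous
contours around the lumen.

## Statistics

ICC is the two-way, absolute-agreement, single-measurement form ICC(A,1),

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)),

computed from the ANOVA mean squares and graded per Koo–Li with boundary
convention [0.5, 0.75) moderate, [0.75, 0.9] good, > 0.9 excellent.
Absolute agreement penalises a constant session offset — the relevant
notion of test-retest bias; the consistency form ICC(C,1) is available
behind a flag.  Bland–Altman uses b − a differences, the sample (n−1) SD
and 1.96·SD limits; percentage differences are normalised per subject by
the first arm (session 1 / 2D), missing where that value is zero.  Paired
t-tests and Pearson r come from scipy; a zero-variance difference vector is
flagged degenerate rather than reported as ±∞.  Group comparisons report
both a paired t (order-paired, as sometimes applied across cohorts) and an
independent-samples Welch t, clearly labelled, because pairing distinct
cohorts is statistically irregular.  Missing pairs are dropped listwise.
No multiple-testing correction is applied; report footers say so.

## Synthetic data

Vessels are straight (or polyline) tubes of radius R carrying
Q(t) = Q̄·[1 + (PI_target/2)·w(t)] with w zero-mean and peak-to-trough 2:
a sinusoid, or a systolic pulse (sin² bump over the first 30% of the
cycle).  The continuous PI equals PI_target exactly; discrete sampling at
the reconstructed frames shifts the extremes, so the generator also reports
the *realized* discrete mean/max/min/PI, which is the recovery target.
Profiles are Poiseuille (v = 2Q/(πR²)·(1 − r²/R²)) or plug; the real study
vessels' profiles are unknown, so laminar profiles are a modelling choice,
not a claim.  Womersley profiles, curved-vessel secondary flow and gating
jitter are out of scope.

Rasterisation averages the analytic field over supersample³ = 64 midpoint
subsamples per voxel (<1% quadrature error for R ≥ 2 mm at 1 mm voxels).
Two intravoxel signal models are provided:

* **ideal** (default): plain volume average.  Flow is conserved — summing
  voxel velocities × area across any perpendicular section reproduces Q(t)
  to quadrature error — the right model for ground-truth conservation
  experiments.
* **complex**: signal-magnitude-weighted average (lumen 10× background),
  emulating how the phase of a complex MR voxel is dominated by the bright
  lumen signal.  Boundary voxels then over-report velocity, reproducing the
  partial-volume flow overestimation of coarse acquisitions (+4–5% at 1 mm,
  <1% at 0.4 mm for R = 3 mm with threshold masks).  A pure volume average
  cannot produce that overestimation: masked sums of a conserved field never
  exceed the total.

Corruption adds a static linear background b(x,y,z) = b₀ + b₁x + b₂y + b₃z
to every component, i.i.d. Gaussian velocity noise per component (the
high-SNR approximation to Rician phase noise — a documented limitation), and
wraps into [−v_enc, +v_enc) via v − 2·v_enc·⌊(v + v_enc)/(2·v_enc)⌋, which
is idempotent, makes the boundary deterministic, and passes in-range values
through bit-exactly.  Magnitude images use a fixed two-level contrast
(lumen 10×background) with noise at the SNR implied by the velocity noise
(σ_v = √2·v_enc/(π·SNR)); MR signal physics is not modelled.  Everything is
bit-reproducible for a fixed seed.

The circle-of-Willis phantom holds nine parallel tubes — inflows ICA_L/R
(R 2.1 mm, 2.5 ml/s each) and BA (1.7 mm, 2.0 ml/s) against six cerebral
outflows (MCA 1.4 mm/1.4 ml/s, ACA 1.2 mm/0.9 ml/s, PCA 1.2 mm/1.2 ml/s,
per side) — with one shared waveform shape and PI, so ground truth
conserves mass at every timeframe.  Tube positions take a seeded sub-mm
jitter.  Radii and flows are typical of the human circle of Willis.

## Validation studies and problem sizes

All studies run in seconds to ~20 s each on one core; seeds parameterise
every random draw.

* **PI recovery** — R = 3 mm systolic-pulse tube, 24×24×12 mm grid, exact
  lumen mask, noise-free, at 1 mm and 0.4 mm.
* **Partial volume** — same phantom under the complex signal model with
  threshold+dilate masks; the signed mean-flow error is positive at 1 mm
  and within a few tenths of a percent at 0.4 mm.
* **Rotation invariance** — tube and plane jointly rotated 30°; flow agrees
  within the trilinear tolerance (≈0.2% observed, 3% budget).
* **Wrap round trip** — 1200 seeded ROIs of 16 pixels: bulk 51–89 cm/s plus
  1–5 aliased core pixels at 101–150 cm/s, v_enc 100.  Velocities are
  quantised to 2⁻¹⁰ cm/s so wrap and unwrap arithmetic is floating-point
  exact; recovery is asserted bit-exact.
* **Mass conservation** — full pipeline on the circle-of-Willis phantom at
  1 mm with threshold segmentation, noise-free and at σ_v = 4.5 cm/s
  (SNR ≈ 10).
* **ICC** — agreement with a scalar-loop ANOVA oracle on five fixed
  datasets (1e−10), and recovery of σ²_s/(σ²_s+σ²_t+σ²_e) with n = 1000,
  k = 2, σ = (1, 0.1, 0.3).  The two session effects are fixed at ±σ_t/√2:
  with k = 2 a *drawn* session effect leaves a χ²(1) fluctuation in the
  realized session variance that growing n never averages away, so the
  convergence claim is only well-posed against an exactly-realized session
  variance.
* **Repeatability study** — 10 subjects × 2 sessions on the phantom at
  σ_v ∈ {2, 10, 30} cm/s.  Geometry is shared across subjects; subjects
  differ in per-vessel mean flow (CV 15%) and PI (CV 10%), sessions only by
  noise draws and re-run segmentation.  Median mean-flow ICC decreases
  strictly with noise (≈0.99 / 0.88 / 0.25).
* **Size vs repeatability** — radii 1.5–5 mm at fixed 30 cm/s peak velocity
  (safely below v_enc even at systole plus noise), σ_v = 18 cm/s,
  14 subjects × 2 sessions; Pearson r between lumen area and mean-flow ICC
  is positive (≈0.6–0.9 across seeds).

## What the phantoms do not show

Synthetic tubes are straight, rigid and laminar, with stationary waveforms
and a two-level magnitude; real vessels curve, pulse radially, sit in
moving tissue, and their signal depends on flow enhancement and sequence
physics.  Passing these studies demonstrates the *pipeline's* correctness
and noise behaviour, not in-vivo accuracy: in particular, absolute flow
accuracy in patients is additionally limited by gating quality, motion,
eddy-current fields beyond linear, and the single-v_enc compromise.
Inter-rater designs, mixed-effects modelling and confounder adjustment are
out of scope.
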