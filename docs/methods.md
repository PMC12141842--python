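# Methods

This note records the models implemented in pellikit, the tunable
parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do
not emulate.

## Particle image velocimetry

**Model.**  An image pair (before/after a deformation increment) is
sliced into interrogation windows of 32 × 32 px matched inside 50 × 50
px search windows of the second image.  The match score is the
normalized cross-correlation (NCC): both windows are zero-meaned and
the score divided by the product of their grey-value norms, so scores
lie in [−1, 1] and are comparable across illumination changes.  The
displacement convention is the motion of matter from image A to image
B, `u` along columns and `v` along rows, in pixels.

**Sub-pixel refinement.**  The integer peak is refined independently
per axis by a three-point Gaussian fit,
`δ = (ln c₋ − ln c₊) / (2 ln c₋ − 4 ln c₀ + 2 ln c₊)`, falling back to
a parabolic fit when a neighbour score is non-positive (the Gaussian
needs positive samples).  The fractional part is clamped to ±0.5 px.
Peaks on the search-window border are returned unrefined and flagged:
the 50/32 window pairing resolves displacements only up to
(50 − 32)/2 = 9 px, and a border peak usually means the true
displacement is at or beyond that range, so such vectors are marked
invalid rather than trusted.

**Grid and validity.**  Window centres sit on a regular grid with
half-search-window margins; the default stride is half the
interrogation window (50 % overlap).  Templates whose grey-value
standard deviation falls below `min_contrast` (default 1 grey level)
are not matched.  Each vector carries a peak-quality ratio
(first/second correlation peak, ≥ 1).

**Outlier validation.**  A vector deviating from its 3 × 3
neighbourhood median by more than `median_k` (default 3) times the
local median absolute deviation is replaced by that median and
flagged.  The MAD is floored at 0.1 px — the typical sub-pixel noise
level — so perfectly uniform neighbourhoods do not flag every tiny
fluctuation.

**Known bias.**  On identical images the sub-pixel estimator leaves a
residual of up to ~0.1 px because the NCC surface is not exactly
symmetric about its peak for finite speckle windows; the zero-field
and translation-equivariance tests budget for this.

## Deformation profiles and segmentation

**Reduction.**  Fields are collapsed to one dimension by taking the
median of valid `u` components per longitudinal station (median rather
than mean to resist edge menisci and residual outliers).  Positions
map to [0, 1] between the plate positions, with the sensor-side plate
shifted toward the mobile one by `force / sensor stiffness` — the
"immobile" plate moves ~0.05 mm per mN and the mapping accounts for
it.  Displacements are divided by the applied elongation.  The
per-point uncertainty is one pixel in relative units (1 / applied
elongation in px).  Only the axial displacement component enters the
profile; the transverse component is discarded, and out-of-plane
(wrinkle-flattening) motion is neglected.

**Piecewise-linear fit.**  The segmentation model is continuous
piecewise-linear in the hinge basis `{1, x, (x − b₁)₊, …}`; free
intercepts per segment are deliberately not allowed, since physical
displacement profiles are continuous.  Interior breakpoints are found
by exhaustive search on a regular grid (default step 0.01 in relative
position), scoring every admissible combination (each open segment
must contain at least two sample points, which keeps the least-squares
problem full rank) and taking the minimum SSE; ties break to the
lexicographically smallest breakpoints.  The search is exact — the
batched Gram-matrix evaluation is algebraically identical to brute
force over the same grid, and a test verifies this equivalence on
small profiles.

**Segment count.**  When not fixed by the caller, segments are added
while the SSE drops by more than 25 % per added segment (up to 4), and
the search stops early once the SSE reaches numerical zero (< 1e-10).
The 25 % threshold is a package choice: it selects 1 segment for
affine (smooth-type) profiles and 4 for the canonical rough profile.

**Region classification.**  Per fitted segment, in order: slope ≤ 0.1
→ rigid translation; width ≤ 0.1 and slope > 1 → quasi-discontinuous
step; first segment with slope > 1 → soft; otherwise central.  The
slope-1 comparisons carry a 1e-6 tolerance so an exactly affine fit
classifies as central.

## Tensile mechanics

**Sensor.**  Force = cantilever stiffness × deflection with the
default 19.5 mN/mm and a 0.40 µm gauge resolution (a ~0.008 mN force
floor).  Pull and push keep their signs.

**Calibration.**  The zero-force value is the mean force over the last
2 s of the record, after the pellicle has failed and the sensor plate
hangs free; the window must lie entirely after the detected failure or
calibration is refused.  Calibration is idempotent up to the noise
mean of the window.

**Failure detection.**  Failure is the first sample where force stays
below `drop_fraction` (default 0.5) of the running maximum for
`window_samples` (default 5) consecutive samples; the running maximum
must first have reached `min_peak_mN` (default 0.5 mN) so baseline
noise before loading cannot trigger.  Deterministic; single-sample
glitches shallower than the drop fraction, or shorter than the
window, do not trip it.

**Elastic fit.**  Least squares of force on elongation over 5–90 % of
the failure elongation by default — the lower cut excludes seating
transients, the upper cut pre-failure crack initiation.  The slope in
mN/mm is reported as N/m (numerically identical).  Replicates are
summarized as unweighted mean ± s.d.

**Strain and length corrections.**  `correct_true_strain` multiplies
the elongation axis by the fraction φ of travel absorbed by the region
of interest (φ = 0.27 for the rough central region, from the
deformation profile).  `rescale_stiffness` implements the
inverse-length law of a uniform strip, `k_full = k_seg · fraction`,
conserving k × L.  Note one internal inconsistency in the reference
numbers this package reproduces: a 5.1 N/m central segment spanning
0.55 of the gap rescales to 5.1 × 0.55 = 2.805 N/m by this law, while
the narrative value is 2.5 N/m; the law is implemented as stated and
the discrepancy left unreconciled.

## Kinetics

Kymographs store one grey profile per frame (row t = frame t), sampled
with bilinear interpolation at pixel-size steps along a probe given in
mm coordinates.  The front is the outermost threshold crossing per
row, refined by linear interpolation between bracketing samples; speed
is the least-squares slope of position on time, and rows without a
crossing are skipped (more than half skipped is an error).  Threshold
crossing on a noisy sharp edge carries a sub-pixel systematic below
1 % of the speed.

Wrinkle wavelength: the profile is detrended by subtracting a
moving-average baseline of window 2 × the band maximum, then the
dominant wavelength is the first autocorrelation peak inside the band
with height ≥ 0.1, parabolically refined; the periodogram maximum in
the band is reported as a consistency check, not used for the
estimate.  Autocorrelation is primary because wrinkle profiles need
not be sinusoidal.  No qualifying peak yields an "aperiodic" status.

Colony expansion rates are computed under an explicit convention —
radius: `(diameter − baseline) / (2t)`; diameter: without the factor
2 — recorded in the output, defaulting to radius with zero baseline.
The literature the diameters are compared against does not fix a
convention, so these rates are reported but not treated as reference
reproductions.

## Synthetic data

The generators define the test conditions; all are pure functions of
their spec (seed included).

* **Speckle** images emulate the optically visible non-uniformities of
  real pellicles as seeded Gaussian blobs (σ = 2 px, expected 5 grains
  per 1000 px², amplitude ±(0.5–1) × contrast × 110 grey levels) on a
  flat background of 128, clipped to [0, 255].  Real pellicle texture
  statistics are unknown; these parameters give a correlation length
  that 32-px windows track well and are documented rather than claimed
  realistic.
* **Warping** is backward (output samples source at `x − u(x)`) with
  bilinear interpolation and clamped edges, avoiding the holes of
  forward splatting.  For non-uniform profiles the displacement PIV
  sees differs from `u` by order `u·u′` (≈ 0.4 px at 12 px elongation
  on an 800 px frame), well inside the recovery tolerances.
* **Force traces** sample plate displacement at the protocol rate
  (160 µm/s, 10 Hz, 0–12 mm); the raw signal is a zero-force offset
  plus the physical force `F₀ + k·φ·d` before failure and the offset
  alone after, with failure rendered as a single-sample drop and
  optional Gaussian noise.  The offset spans the whole record, which
  is what makes post-failure zero calibration meaningful.  The
  generator does not model sensor-plate compliance, so applying the
  plate-deflection correction to a simulated trace raises the fitted
  slope by a known factor `1/(1 − k/k_s)` (~2.6 % for a 0.51 N/m
  pellicle) — inside the recovery tolerances and noted here rather
  than hidden.
* **Time-lapses** render a bright region (160 over background 40)
  whose edge advances at the configured speed from 5 mm, in a
  62 × 46 mm dish at 0.05 mm/px and one frame per 15 min, with an
  optional sinusoidal wrinkle modulation and Gaussian noise.

What passing tests show — and do not.  Recovery on these synthetics
verifies the estimators against known ground truth under controlled
noise; it does not certify performance on real images, which add
menisci, reflections, non-stationary texture, out-of-plane motion and
illumination drift that the generators deliberately omit.

## Problem sizes and runtime choices

The test suite and the acceptance script use 800 × 400 px speckle
pairs (≈ 1100 PIV windows), 600 × 160 px pairs for module tests,
751-sample force traces, and 25–37-frame stacks; the full suite runs
in well under a minute on one CPU.  These sizes were chosen so the
statistical tolerances of the recovery checks are met with margin
while iteration stays fast.

## Known limitations

No iterative window deformation or multi-pass PIV pyramids; the 50/32
window pairing limits detectable displacements to ±9 px.  No 2-D
strain tensors, meniscus modelling or out-of-plane estimation.  No
viscoelasticity, creep or crack-propagation modelling in the tensile
chain.  No buckling theory: wrinkle wavelengths are measured, not
predicted.  Colony-expansion statistics (normality tests, group
comparisons) are out of scope.
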