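# Methods

This note records the models, estimators, numerical choices and known
limitations behind `stereoccm`.

## Coordinate and unit conventions

All geometry lives in continuous µm coordinates, origin at the top-left
image corner, x rightward, y downward.  The default frame is 380 × 380 px
covering 400 × 400 µm², giving a pixel pitch of 400/380 ≈ 1.0526 µm/px.  The
centre of raster pixel (i, j) maps to ((j+0.5)·s, (i+0.5)·s); vertex
coordinates stored in pixel units in annotation files are continuous
positions and convert by plain scaling without the half-pixel shift (so a
vertex at pixel 190 on the default frame is exactly 200 µm).  Both frame
dimensions and field of view are configurable per image.

## Orientation-stratified systematic sampling

Fiber orientation is an axial quantity, so the dominant orientation of an
image is the length-weighted mean of its main-fiber segment angles on the
doubled circle: θ̄ = ½·arg Σ w·e^{2iθ}, w the segment lengths.  The axial
range [0°, 180°) is partitioned into three 60° sectors: vertical = 90° ± 30°,
diagonal-right = [0°, 60°), diagonal-left = (120°, 180°).  The bin width is
a design choice (the three-way split itself is the given design; no numeric
thresholds accompany it); symmetric 60° sectors are the unique unambiguous
exhaustive partition and are configurable.

Within each stratum, selection is systematic uniform random with a
real-valued interval: T = n/k, u ~ U[0, T), indices ⌊u + i·T⌋.  This
guarantees exactly k selections for any k ≤ n (an integer stride cannot when
k ∤ n) with inclusion probability exactly k/n per image.  Items are ordered
by acquisition index, which approximates spatial ordering across the scan —
the property that makes systematic sampling efficient.  The default plan is
4 vertical + 2 diagonal-left + 2 diagonal-right = 8 images per subject.  An
under-populated stratum contributes all its images with a logged warning;
this fallback is this package's policy, as is pooling both eyes by default.
Per-subject, per-stratum random starts derive from the root seed via hashed
spawn keys, so adding or removing a subject never perturbs the others'
selections.

## 2D nucleator

For a region star-shaped about a reference point, the area estimator is
a = π·E[l²] with l the ray length from the point to the boundary along an
isotropic direction.  We use n systematic rays at angles φ₀ + i·2π/n with a
single uniform random phase φ₀ ~ U[0, 2π/n); a_after = π·mean(lᵢ²) is
unbiased for the polygon area and exact on centred circles for every phase.
The single-ray form π·l² is the n = 1 special case; the default is
n = 4 rays (variance reduction at negligible cost; the systematic layout
cancels the 2nd- and 3rd-harmonic boundary perturbations exactly, leaving
only 4th-and-higher harmonics in the estimator variance).

Boundaries may be given as polygons or as (angle, length) ray tables; a
polygon takes precedence so that the nucleator and the clipper see identical
geometry.  Ray tables are interpreted as periodic piecewise-linear radial
functions.  Rays are clamped to the image frame, and the final a_after is
clamped to fov² — the in-focus area cannot exceed the field of view (ray
clamping alone does not imply this: four clamped rays on the full square
frame can average to π·mean(l²) ≈ 1.57·fov²).

The central reference point defaults to the geometric image centre and is
overridable per image.

## Clipping and metrics

Adjusted metrics use the annotation clipped to the focus region polygon:
polylines are intersected segment-wise (a fiber may split into several
retained pieces), and retained pieces carry their original fiber identity so
a split main fiber counts **once** toward CNFD.  Branch points on the
boundary count as inside (closed region, deterministic tie-break).  CNBD
uses the annotated branch points, recounted inside the region — not clipped
branch-polyline counts.  Unadjusted metrics use the full annotation over
exactly fov² (0.16 mm² at defaults).  When the focus region covers the whole
frame the clip is the identity and adjusted equals unadjusted exactly.

Length conservation (inside + outside = total) holds to floating-point
precision because both parts are computed against the same region polygon.

## Automated focus-boundary detection (extension)

Manual delineation is the reference procedure; `estimate_focus_boundary` is
an explicitly labelled automated extension, off by default and never used to
validate the estimator itself.  It computes |Laplacian-of-Gaussian| of the
image, max-pools it over 9-px tiles, smooths (σ = 4 px), and thresholds at
4.0 noise units, where the pixel-noise scale comes from Immerkær's
second-difference estimator (robust to smooth structure) scaled by 0.333 (the
response of the σ=1 LoG to unit white noise).  After binary closing (radius
12 px, edge-padded), the boundary is the outermost above-threshold radius
along 64 systematic rays from the centre — star-shaped by construction.  An
image whose centre window never clears the noise floor raises "center out of
focus".  The detector needs sharp structure to respond to: in sparse-fiber
images the outermost in-focus fiber, not the true defocus boundary, limits
the recovered radius, so its accuracy is validated on dense-fiber synthetics
only.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, not
photorealistic corneal texture.

* **Fibers.**  Main fibers are oriented line processes: orientation from a
  von Mises distribution on the doubled angle (κ = 8) around the stratum
  direction (vertical 90°, diagonal-right 30°, diagonal-left 150°), position
  from the uniform (θ, offset) line parametrization — offset uniform across
  the frame's projection onto the fiber normal — which makes the straight
  process spatially homogeneous.  Waviness is a mean-reverting heading
  process (per-10-µm-step innovation 2.5°, reversion 0.88), chosen over a
  pure heading random walk because unbounded lateral drift (~135 µm over a
  frame crossing) visibly starves the offset-band edges and biases central
  densities by several percent.  Pieces of a fiber that exits and re-enters
  the frame are all kept under one fiber identity for the same reason.
* **Intensity.**  Fibers accumulate until the configured intensity
  (mm of main fiber per mm² of frame) is met exactly; the last fiber is
  trimmed at the target arclength.  Per-image ground-truth CNFL is therefore
  exact at the configured value, and means over images are trivially
  unbiased; a Poisson fiber count would give ~30% per-image CV at this frame
  size, which is not what per-image CCM data look like.
* **Branches.**  Branch points are a Poisson process along fibers
  (2.2 per mm default) with short branch polylines (exponential mean 25 µm,
  clipped to 8–80 µm).
* **Focus region.**  A disk (mean radius 185 µm) perturbed by random 2nd–4th
  harmonics (irregularity 0.15), stored as a 64-gon about the image centre.
  The default radius puts a_after near 2/3 of the frame so the
  adjusted-over-unadjusted inflation lands in the tens of percent, the
  regime the method is designed for.  The *visible* annotation — what a
  tracer can see — is the truth clipped to this region.
* **Rendering** (optional).  Gaussian fiber cross-sections (σ = 1.3 px,
  amplitude 110 over background 30), Gaussian defocus blur outside the
  region (σ = 8 px), additive Gaussian read noise (σ = 10 gray levels),
  8-bit output.
* **Cohorts.**  Default 26 / 45 / 17 subjects (control / DSPN− / DSPN+),
  16 images each (6 vertical, 5 left, 5 right).  Group effects are
  multiplicative on fiber intensity (1.0, 0.83, 0.60) and branch rate
  (1.0, 0.85, 0.72), computed from the ratios of published adjusted group
  means; between-subject variation is log-normal with CV 0.30, matching the
  order of the published group SDs.  Synthetic IENFD is Gaussian per group
  (8.5, 7.0, 4.5 fibers/mm, SD 3) with a configurable correlation ρ to the
  subject's true fiber intensity; ρ = 0 (default) reproduces the
  no-correlation regime between CCM and skin-biopsy measures.

What passing tests on this generator do **not** show: robustness to
real-image artefacts (K-structures, dendritic cells, illumination gradients,
motion), to tracing errors of clinical software, or to non-star-shaped focus
regions.

## Statistics

Group comparison screens each group with Shapiro-Wilk (α = 0.05) and runs
one-way ANOVA when all groups pass, Kruskal-Wallis otherwise ("for unequal
data" is read as "for non-normal data"; either test can be forced).
Post-hocs are Tukey's HSD after ANOVA and Dunn's rank test with Holm
adjustment after Kruskal-Wallis (hand-implemented with tie correction).
All-constant inputs return statistic 0, p = 1 rather than an error.

The paired method comparison reports the paired t-statistic and the mean
percent difference 100·(mean_a − mean_b)/mean_b.  Degenerate all-zero
differences return t = 0, p = 1.

ROC analysis orients nerve-metric scores so that lower values score as
disease-like (AUC ≥ 0.5 means "lower metric ⇒ disease"); the positive class
is DSPN(+) and the negative class pools controls with DSPN(−) by default
(configurable — the pooling choice is not dictated by the design).  The AUC
is the Mann-Whitney concordant-pair fraction with half credit for ties,
identical to the trapezoidal area under the empirical curve; the confidence
interval uses the DeLong variance.  AUC equality across k paired analyses is
the DeLong multi-AUC chi² test with k−1 degrees of freedom, the behaviour of
standard `roccomp`-style routines; identical inputs give chi² = 0 exactly
(the contrast is the zero vector, evaluated before the pseudo-inverse).

Interobserver agreement reports paired t-tests per metric and each
observer's coefficient of variation (SD/mean × 100%), the simplest
per-observer variation summary.  The significance threshold is α = 0.05.
No multiple-testing correction is applied across metrics; Holm applies
only within a post-hoc family.

## Stand-in tracer

`trace_nerves` (Sato multiscale tubularity → Otsu threshold with a
noise-calibrated floor → skeletonization → skeleton graph; longest path per
component = main fiber, hanging chains = branches, junctions on the main
path = branch points; min fiber length 50 µm) exists to close the
image→annotation loop on synthetic data.  It claims no equivalence with
clinical tracing software, and every stereological result in the test suite
uses ground-truth annotations, never traced ones.

## Problem sizes and determinism

Validation sizes were chosen to give comfortable Monte-Carlo margins:
10⁵ rotations for nucleator unbiasedness (SE ≈ 0.07%), 10³ random
fiber/region pairs for clipping conservation, 500 images for estimator
recovery (SE ≈ 1%), 10⁴ replicates for inclusion-probability goodness of
fit, 10³ replicates for the group-test type-I error, and a 28-subject
cohort for the direction-of-effect pipeline run.  Every random quantity in
the package flows from an explicit seed: cohorts from `SynthParams.seed`,
sampling from `SamplingPlan.seed` via hashed per-subject spawn keys,
nucleator phases from per-image child generators.  Re-running any pipeline
or script with the same seed reproduces byte-identical outputs.

## Known limitations

* CNFD runs higher than published clinical values: straight-ish synthetic
  fibers are chord-limited to ≲ 400–560 µm within the frame, whereas real
  sub-basal fibers wander across the image and average longer, so the same
  CNFL maps to more, shorter fibers here.  Ratios between groups and modes
  are unaffected.
* The adjusted-CNFL recovery argument assumes spatial homogeneity of fiber
  intensity; real plexus density varies across the cornea.
* The focus detector and tracer are supporting tools with synthetic-data
  validation only.
* Interobserver analysis operates on externally supplied paired ratings;
  the package does not simulate observers.
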