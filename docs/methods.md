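# Methods

This note documents the models and procedures `ccmorph` implements, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic test bed does and does not establish.

## Imaging model and units

A CCM frame is an 8-bit grayscale raster over a fixed physical field;
the default geometry follows the HRT III convention of 384 × 384 px over
400 × 400 µm (pitch 400/384 ≈ 1.042 µm, field area 0.16 mm²).  The
geometry is configurable (`Calibration`) and travels with every image,
mask and derived quantity.  All endpoints are normalized per mm² of
corneal surface: a count or length measured on one frame is divided by
the field area.  Doubling the pitch at a fixed pixel grid therefore
halves NFL (µm lengths double, mm² area quadruples) and leaves NFA
unchanged — an identity asserted in the tests.

Per-subject values average per-image records two-stage when both eyes
are imaged (mean over images within each eye, then mean of the two
eye-means); a missing eye falls back to the available eye with a
`missing_eye` flag.  Pooled averaging is available for sensitivity
checks.

## Segmentation (pixel-counting nerve fiber area)

The mask pipeline is: (1) Gaussian enhancement, σ = 1 px; (2) adaptive
threshold; (3) tubularity gate; (4) removal of components < 50 px.
NFA = foreground pixels × pitch² / field area.

The threshold is the step that decides what "area" means, so its design
is documented in detail.  The local background is a large-scale Gaussian
blur (σ = 32 px, nearest-edge padding — reflect padding biases the
estimate at the borders when illumination ramps).  A pixel is a
candidate when

    enhanced > background + k · max-filter(enhanced − background, r)

with k = 0.45 and window radius r = 3 px.  The max filter makes the
threshold a fixed fraction of each fiber's *own* local peak amplitude,
i.e. the mask approximates the full-width-at-half-maximum footprint of
every bundle regardless of its absolute brightness.  Two alternatives
were tried and rejected during phantom calibration: a Gaussian-weighted
absolute-deviation spread (a single noise-scaled threshold cannot track
the half-maximum of both thin and wide fibers, whose blurred peak
amplitudes differ 2×, giving +50%/−30% area errors at the extremes), and
a grey-closing envelope (extends each bright structure's plateau ~2r
outward, flooding dim neighbors).  The window radius is kept small so a
bright fiber does not raise the threshold over a dim fiber a few pixels
away.

The tubularity gate keeps candidates whose Frangi-type vesselness —
built from the two Hessian eigenvalues (|λ₁| ≤ |λ₂|, response requires
λ₂ < 0) with σ²-normalized derivatives, maximum over scales {1, 2, 3} px
— exceeds the 85th percentile of the nonzero response.  The blobness
weight uses β = 1.0 rather than the textbook 0.5: at β = 0.5 the gate
suppresses junctions (where both eigenvalues are negative and the
blobness ratio approaches 1), cutting the mask exactly where fibers
cross or branch; on phantoms this split main bundles and detached
branches, and the exact-NFD recovery rate doubled when β was relaxed.
The structureness constant is c = half the maximum Frobenius norm, per
the common convention.

No gap-bridging or hole-filling is applied: the pixel-area endpoint is
meant to preserve fine structure (beading, caliber variation) rather
than produce cosmetically clean masks.

## Skeleton morphometry

The mask is thinned to a one-pixel medial axis; skeleton pixels with one
8-neighbor are endpoints, with ≥ 3 are junctions, and the degree-2 runs
between them are edges with geometric length (axial step = pitch,
diagonal = √2·pitch).  Two graph-level clean-ups matter in practice:

* **spur pruning** (default 6 µm): terminal twigs created by boundary
  roughness otherwise fabricate junctions and inflate NFL;
* **junction-connector contraction** (default 8 µm): a fiber crossing
  skeletonizes as two 3-way junctions joined by a 2–4 px connector;
  contracting it restores the 4-way junction that continuation pairing
  expects.

Main fibers are maximal chains formed by greedy straightest-continuation
pairing at junctions (pairs allowed up to 60° turning), kept when the
chain is ≥ 50 µm.  A chain that hangs off a ≥ 2× longer accepted main at
an end is demoted to a branch — anatomically it emanates from the
bundle rather than traversing the field; without the relative rule,
long branches (or fragments split at shallow crossings) count as
spurious mains.  Remaining chains ≥ 10 µm attached to a main are
branches; the rest are orphans, counted in NFL only.

Width at each skeleton pixel is `2·EDT − 1` px (EDT = Euclidean distance
transform of the mask), rounded and clamped to [1, 8] px — the full
width of the run through that pixel (a 5-row solid bar reads 5, a 1-px
line reads 1).  Because the EDT is a minimum statistic, noise-nibbled
boundaries bias it low; the default estimator therefore closes the mask
with a 3×3 element and max-pools the EDT over the pixel's neighborhood,
which leaves clean bars unchanged.  An explicit perpendicular ray-casting
estimator is provided as a cross-check and agrees within 1 px on bars.

NFA (W×L) integrates the width in µm along the skeleton (trapezoid over
each edge) per field area; the length-weighted mean caliber is then
exactly NFA\_WxL / (1000·NFL).  A "literal product" variant (Σ width
pixels × skeleton pixel count) is retained behind a flag for comparison;
its magnitude is inflated by orders of magnitude and it is not used.
The Σ w·dl reading is corroborated by the normative group tables: mean
NFA\_WxL / NFL ≈ 3.06 µm, matching the reported normal width peak
(~3.1 µm).

## Width distributions

The width histogram is the frequency of integer pixel widths 1–8 over
all skeleton pixels, normalized per image; bin centers convert to µm by
the pitch.  Group curves are unweighted means of per-image normalized
histograms (so each image contributes equally).  Parametric fits
(amplitude-scaled Gaussian or lognormal, least squares, ≥ 4 non-zero
bins) describe the healthy peak near 3.1–3.2 µm.  The mid-width dropout
ratio is the band mass (default [2.8, 4.0) µm, left-inclusive) of a
distribution divided by a reference (control) distribution's band mass;
under the synthetic neuropathy operator at full severity it falls to
roughly half, consistent with the 30–50%-of-normal depletion described
for neuropathic cohorts.

## Study statistics

* **ROC/AUC** — the AUC is the Mann–Whitney concordance probability
  (ties ½), computed by ranks and verified against brute-force pair
  enumeration.  Its SE uses the Hanley–McNeil closed form with
  Q₁ = A/(2−A), Q₂ = 2A²/(1+A).  The cut point maximizes TP + TN over
  observed thresholds (ties toward higher sensitivity); Youden's J is
  reported alongside but the accuracy-based point is canonical here.
  The convention `direction="lower"` reflects that every CCM endpoint
  decreases with disease.
* **Correlated AUC comparison** — z = (A₁−A₂)/√(SE₁²+SE₂²−2r·SE₁·SE₂).
  The correlation r between the two AUC estimates is looked up by
  bilinear interpolation in a grid indexed by the mean within-class
  score correlation and the mean AUC.  The grid is regenerated by Monte
  Carlo from the correlated-binormal rating model (the model the
  classical table was derived from) and frozen in the source; the ρ = 0
  row is exactly zero.  A subject-resampling bootstrap version is
  provided as a cross-check oracle.  The closed-form and resampling
  p-values are both unbiased but are *different* variance estimators;
  at small samples (tens per class) their per-dataset disagreement has
  an irreducible RMS of ~0.03–0.05, which the validation suite measures
  and reports rather than hides.
* **Passing–Bablok** — slope = shifted median of pairwise slopes
  (slopes of exactly −1 excluded, median index offset by the count
  below −1), intercept = median(y − b·x), CIs from the binomial rank
  bounds of Kendall's statistic.  Equivariance under positive affine
  maps of y is exact when no pairwise slope crosses −1, the regime of
  positive-relation method comparison.  Exposed for method comparison;
  the NFL↔NFA curve uses OLS (below) because the relation is quadratic.
* **Quadratic NFL↔NFA model** — ordinary least squares on [1, x, x²]
  with unit-norm column scaling (the raw design is ill-conditioned at
  pixel scales), t-based 95% CIs mapped back exactly, r², and
  out-of-sample r² for cross-validation-style evaluation.  Simulation
  with noise calibrated to r² ≈ 0.8 confirms nominal CI coverage.
* **MDC** — SEM·1.96·√2.  Two SEM definitions are supported: sampling
  (sd/√n) and reliability (sd·√(1−ICC)); published MDC values are
  consistent with the sampling form up to rounding of reported SDs, and
  no attempt is made to force closer agreement.
* **Normalization** — square-root transform for right-skewed area-like
  endpoints, with Shapiro–Wilk W and p before/after (scipy's
  implementation of the standard coefficients; cross-checked against R's
  `shapiro.test` to 1e-6 on frozen fixtures).
* **ANCOVA** — follow-up ~ baseline + arm by OLS; the arm coefficient is
  the baseline-adjusted net change.  Simulations at n = 15/arm show
  nominal 2·SE coverage and a type-I error within the expected band.
* **Group summaries** — n/mean/sd/sem/median/IQR/range per group and
  variable, percent-of-control means, within-group Pearson correlation
  matrices ("interclass correlation" in the clinical usage this package
  follows), and Tukey HSD contrasts via statsmodels.

## Synthetic test bed

Phantoms render each fiber as a cubic-spline curve with a Gaussian
intensity cross-section whose FWHM equals the nominal width
(σ = width/2.355), so "width" is well-defined against the half-maximum
footprint the segmenter recovers and the truth mask (distance ≤ width/2)
is the matching disc.  Branches are straight offshoots at 35–65°;
beading is a ±15% sinusoidal intensity modulation (period 25 µm);
the background adds an optional linear ramp and Gaussian noise.  The
standard study conditions are 2–8 near-parallel field-spanning fibers,
widths 2–6 px, peak amplitude 100 over background 40 with noise sd 20
(SNR 5).  All randomness derives from the spec's seed; the same seed is
bit-reproducible.

The neuropathy operator removes each fiber with probability
severity · exp(−(w − 3.2)²/(2·0.4²)) — a Gaussian kernel in width
centered on the normal mean, from the observed ~2.8–4.0 µm preferential
dropout — and swells survivors by (1 + 0.1·severity).

Cohort tables draw the five endpoints from correlated truncated
multivariate normals whose means/SDs default to published normative
values for controls, NDS-banded diabetic neuropathy and sarcoidosis
(equicorrelation 0.85, inside the reported 0.75–0.96 range).  The
longitudinal simulator regresses follow-up toward the group mean
(tracking 0.8) with change noise 0.25·sd and an additive arm effect.

What passing phantoms shows — and does not.  Recovery tolerances
(NFD exact in ≥ 90% of images, NFL median within 5%, mean width within
0.5 px, NFA within 15% of the analytic Σ w·l area) demonstrate the
pipeline's internal consistency against a known generative model whose
assumptions (Gaussian profiles, additive Gaussian noise, smooth curves)
are idealized.  Real CCM frames add speckle, out-of-focus layers,
dendritic cells and mosaic illumination that the phantoms do not
emulate; absolute endpoint values on real data additionally depend on
the acquisition protocol.  The ~4–5% NFL overestimate is the known
upward bias of √2-diagonal chain length for oblique curves, partly
offset by skeleton end-shortening; the 5% tolerance absorbs it by
design.

## Numerical choices and degenerate inputs

Deterministic throughout: no randomness in segmentation or morphometry;
identical inputs give identical outputs.  Empty masks are valid (all
endpoints zero, empty graph); constant images give zero tubularity;
one-class ROC input, single-arm ANCOVA, all-identical x in regression
and empty aggregation raise `ValueError`.  Width-model non-convergence
is flagged in the result rather than raised.  Greedy pairing ties at
junctions resolve by the largest continuation cosine; cut-point ties
resolve toward higher sensitivity.

## Problem sizes in the validation suite

Validation runs use 50 phantoms (recovery), 200 random datasets (AUC
oracle), 100 fixtures (Passing–Bablok), 100 replicates of n = 192
subjects (quadratic model), 50 cohorts × 5 severities (dropout), 100
effect + 300 null replicates at n = 15/arm (ANCOVA), one 48 + 48 null
study, and 200 paired cohorts of 20 + 20 with 500 bootstrap draws
(AUC-comparison cross-check); these sizes give each Monte-Carlo
estimate a sampling error comfortably below the tolerance it is tested
against.

## Known limitations

* Main-fiber/branch rules reimplement the *definitions* of the clinical
  endpoints; they are not bit-compatible with any proprietary analysis
  chain, and NFD/NBD on real images will differ near the margins of the
  chaining heuristics.
* The width range is clamped at 8 px by convention; bundles wider than
  ~8.3 µm at default pitch saturate.
* The dropout band [2.8, 4.0) µm covers a single integer-px bin at the
  default pitch; at other calibrations it may span several bins.
* Beading is modeled only as intensity modulation; bead size/spacing
  metrics are out of scope.
* Tortuosity, image-quality grading and frame mosaicking are out of
  scope.
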