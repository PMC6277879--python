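# Methods

## Segmentation

Plants are darker than the white baseboard, and most carrot tissue is
saturated (green shoot, orange root). The grayscale image (standard
luminance weights, via `skimage.color.rgb2gray`) minus the HSV saturation
channel (both on the 0–1 scale, so no extra rescaling is needed) therefore
separates plant from background strongly; the difference is clamped at zero
and thresholded by Otsu's method, with polarity chosen so the darker side —
the plant — is foreground (guarded by requiring the foreground to be the
minority class). Connected components (8-connectivity) smaller than a
configurable fraction of the image area (default 0.01 %) are removed:
specks of soil and sensor noise otherwise survive thresholding, and making
the cleanup explicit and configurable is preferable to leaving failures
unexplained.

The divider line is found as the darkest row by **median** intensity: the
line spans most of the image width, so the row median bridges the central
gap where the crown sits, which a mean over a narrow column band would not
reliably do. The line is several pixels thick; contiguous rows at the
minimum darkness are collapsed to their central row, and between separated
equally dark candidates the topmost wins. Detection fails if no row median
is at least `darkness_margin` (default 0.2 on the 0–1 scale) below the
image-wide median.

Splitting excludes a band of ± `band_half_height` rows (default 3, covering
the line thickness) around the divider from both sections. The crown is
placed on the divider row at the midpoint of the foreground span in the
first root row below the band: storage-root tissue is contiguous at the
junction, while petioles may straddle the gap, so the root-top span is the
more stable anchor. Plants whose shoot or root section touches the image
border are rejected (or warned about, per `border_policy`) — such frames
were staging failures at acquisition time and their measurements are not
trustworthy. Coordinates are 0-based with rows increasing downward.

## Biomass profiles

**Shoot.** Every shoot pixel gets a normalized elliptical radius
ρ = √(((x−cx)/a)² + ((y−cy)/b)²) about the crown (cy, cx). The semi-axes
default to the crown-centered half bounding box of the shoot — a is the
largest horizontal distance from the crown column to a shoot pixel, b the
largest vertical distance — so ρ ≤ 1 for every pixel, the grid "just
covers" each plant, and profiles are comparable across plants of different
absolute size. Bins are half-open [i/n, (i+1)/n) with ρ = 1 assigned to the
last bin; conservation (∑ profile = shoot pixel count) is therefore exact
by construction and is property-tested, along with exact equality against
an independently written per-pixel brute-force binning. n = 1000 bins by
default.

**Root.** Row sums of the root mask from its first to last nonzero row
(so stray wisps removed by cleanup cannot stretch the extent), linearly
interpolated onto n points. Shape normalization divides by the profile
maximum, giving values in [0, 1] with max exactly 1; dividing by the
crown-end row sum is available as a switch (`width_by="first"`) since the
original convention is ambiguous, but the maximum is the more robust
denominator when the widest section is not at the crown.

## Morphometrics

`skimage.measure.regionprops` over the full foreground treated as one
region (sections may be disconnected after the band exclusion).
Eccentricity comes from the ellipse with matching second central moments;
the Euler number uses 8-connected foreground / 4-connected holes
(`skimage.measure.euler_number`, connectivity 2); perimeter is the weighted
boundary-length estimator of `regionprops.perimeter`. Calibration is a
config-supplied px/cm scale; automatic reference-marker detection is out of
scope. Pixel quantities divide by px_per_cm (lengths) or its square
(areas).

## Petiole trait models

**Width.** The Euclidean distance transform labels each foreground pixel
with its distance to the nearest background pixel, so at a skeleton
(medial-axis) pixel twice the EDT is the local full width. Skeleton EDT
samples are summarized as a 100-bin histogram (normalized to sum 1) over
[0, cap], with the cap set to the 99.5th percentile of the pooled training
samples — a fixed-length descriptor robust to single outlier blobs — and
fed to PLS regression against ground-truth widths in cm.

**Number.** Digital shoot biomass divided by the predicted width (px)
approximates total petiole length, which grows with leaf count; the ratio
(plus the raw area) feeds PLS against hand counts. Predictions are left
continuous; rounding is the caller's decision.

**Length.** SBPs are reduced by centered PCA to the fewest components
covering 95 % of training variance (capped at 10); standardized scores feed
a feed-forward network with one tanh hidden layer (10 units) and linear
output, trained by L-BFGS (sklearn `MLPRegressor`, alpha 1e-4, tol 1e-7,
max 4000 iterations) with a fixed seed. The trained weights are extracted
and prediction uses a direct forward pass, so a model persisted to JSON
reproduces its outputs bit-exactly. PLS was also tried in the original
two-stage design for length; the network is kept because latent SBP scores
relate to length nonlinearly.

**Component selection.** "One-fold holdout" cross-validation is read as
leave-one-out (every sample serves once as the held-out fold); a single
random 80/20 holdout is available via `cv="holdout"`. The retained
component count is chosen by the one-standard-error rule on CV MSE —
the smallest k within one SE of the minimum — which guards against
near-flat CV curves selecting spuriously large k. With k equal to the
feature rank, PLS predictions coincide with ordinary least squares
(tested to 1e-6 relative).

## Population shape PCA

Centered, unscaled PCA. Shoot PCA runs on raw SBPs, so its first component
captures biomass magnitude; root PCA runs on length/width-normalized
profiles only, so components capture pure contour (taper, tip fill,
mid-root thickening). Component signs are fixed by making each component's
largest-magnitude entry positive. Eigen sweeps reconstruct
mean + k·sd(scores)·component for k in ±2 sd, the standard visualization of
what a component encodes. Percent variance explained is
100·λᵢ/∑λ, non-increasing, summing to ≤ 100.

## Variance components and repeatability

The observation model is y_ijk = μ + G_i + E_j + B_k(j) + GE_ij + R_ijk
with genotype, environment, replication-within-environment, interaction,
and residual all random. On balanced designs the components come from exact
ANOVA expected-mean-squares method-of-moments — unbiased there, and cheap
enough for large simulation studies; REML (statsmodels MixedLM with
variance-component formulas) handles unbalanced data. This inverts the
usual "REML first" preference deliberately: on balanced designs the two
coincide in expectation and MoM is exactly unbiased, which is what the
simulation-recovery tests measure. Negative estimates are truncated at
zero (which induces a small positive bias in near-zero components — visible
but within tolerance in the recovery tests). With a single environment the
GxE component is undefined and flagged (NaN); with a single replication the
residual is confounded with GxE and reported accordingly. Two-way ANOVA
significance for G, E, and GxE uses type-II sums of squares (equivalent to
type I on balanced data, better behaved on unbalanced).

Repeatability: entry-mean R = σ²G/(σ²G + σ²GxE/t + σ²R/rt) and
per-environment R = σ²G/(σ²G + σ²R/r), with t the harmonic mean of
environment counts per genotype and r the harmonic mean of replication
counts per genotype-environment cell — harmonic means tolerate missing
observations in some cells.

## QTL support utilities

PVE = 100·(1 − 10^(−2·LOD/n)) for an n-individual population — strictly
increasing in LOD, mapping [0, ∞) into [0, 100) — and the 1.5-LOD support
interval width in Mb as (right − left)/10⁶ from flanking marker names of
the form `S{chromosome}_{bp}`, rejecting cross-chromosome pairs. A carrot
F₂ QTL input table (names, LOD scores, markers, n = 316) ships as package
data.

## Synthetic plants

The generator renders the staged-photograph geometry: white background,
black divider (half-thickness 2 px) with a gap around the crown, root
below, petiole fan plus leaf-tip blobs above, on a 720 × 600 canvas at a
nominal 10 px/cm. The root silhouette half-width is
w(z) = (W/2)(1 − z/L)^k, blended with an elliptical cap over the last
`tip_bluntness` fraction of the root, so two scalar knobs span the
conical-vs-cylindrical and tapered-vs-blunt-tip axes of shape variation;
rendered root area matches the analytic integral 2∫w(z)dz to within
rasterization error (tested at 2 %). Ground truth (exact per-section pixel
counts, petiole count/width/length, taper, bluntness) comes from a label
canvas painted alongside the image.

Default population ranges: 5–15 petioles, mean petiole length 80–380 px
(± 8 % within-plant jitter), petiole width 4–14 px, root length 120–230 px,
root max width 30–80 px, taper exponent 0.3–2.0, tip bluntness 0.05–0.6.
Petiole count, mean length, and width are coupled through a shared
per-plant vigor factor (mixing weights 0.75/0.75/0.6 with independent
uniform noise): shoot architectural traits covary with overall plant size
in a real crop population (allometric scaling), and fully independent
draws would make the biomass/width count feature uninformative in a way no
real population is. Controlled populations varying a single knob (used by
the PCA-recovery and count-monotonicity tests) are built with `overrides`,
which draws the named parameter independently.

What the generator does **not** emulate: lighting gradients and shadows,
soil debris, leaf-blade texture and lobing, petiole curvature, and
occlusion beyond simple fan overlap. Passing tests therefore demonstrate
the pipeline's logic — segmentation fidelity, profile conservation,
feature/model wiring, recoverability of generative parameters — not
field-photograph accuracy; predictor correlations on synthetic populations
(r ≥ 0.85–0.95) sit above what heavily overlapping real canopies allow.

## Problem sizes and determinism

The standard test fixture is a seeded 100-plant population (80/20
train/test for the predictors); shape-PCA recovery uses 60 plants varying
only the taper exponent; variance-component recovery averages 500 balanced
simulated trials (20 genotypes × 2 environments × 2 replications). All
randomness flows through explicit integer seeds (`numpy.random.default_rng`
and the network's `random_state`); rendering, segmentation, and both
measurement and prediction stages are bit-deterministic given the seed, and
the batch runner guarantees per-image isolation (a failing image is logged
with a reason code — no_contrast, no_plant, no_divider, border_overlap,
one_sided_mask — and never affects other images).

## Known limitations

- The elliptical-grid semi-axes are per-plant, so raw SBP magnitudes mix
  plant size into every bin; the length model relies on this (by design)
  but cross-study comparisons of raw SBPs need a shared calibration.
- The width descriptor pools all skeleton pixels, so leaf blobs and the
  petiole fan contribute alongside petioles; PLS learns to weight the
  relevant histogram region, but a petiole-only instance segmentation would
  be sharper.
- Count prediction degrades under heavy petiole overlap (many petioles at
  similar angles), mirroring the known failure regime of
  biomass-over-width counting.
- REML on severely unbalanced or tiny designs can sit at boundary
  solutions; estimates are truncated, not profiled.
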