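# Methods

This note documents the models, conventions, and numerical choices behind
`mammocad`, and what the synthetic-data experiments do and do not
demonstrate.

## Preprocessing

The ROI is the axis-aligned square of side 2·radius centered on the
annotated lesion, clipped to the image bounds (edge lesions yield smaller
crops).  The square-of-side-2r rule is a declared convention — annotation
formats give a circle's center and radius but no crop geometry — and is
chosen so that the crop always contains the annotated circle.  Annotation
files do not declare their pixel-origin convention, so the reader requires
the caller to state `top_left` or `bottom_left`; everything downstream is
top-left, row-major.  The 3×3 median filter replicates edge pixels at the
borders (avoiding artificial zeros at ROI margins).  Histogram equalization
is the classic integer LUT

    out(v) = round((L−1) · (cdf(v) − cdf_min) / (1 − cdf_min)),  L = 2^bit_depth,

anchored at the lowest occupied bin; a constant image maps to 0.  Linear
min–max stretching is available as a configuration alternative but
equalization is the default.

## Feature extraction

**Texture (88).**  Intensities are uniformly quantized to L_q = 8 levels
(distance d = 1, symmetric accumulation — all configurable; the small
default level count keeps co-occurrence estimates stable on ROIs of a few
thousand pixels).  The angle→offset map in (row, col) is 0°→(0,+d),
45°→(−d,+d), 90°→(−d,0), 135°→(−d,−d); with symmetric accumulation each
matrix equals its transpose, and the four matrices are *concatenated*
(22 stats × 4 angles), not averaged — the 88-feature block size forces
concatenation.  The 22 statistics are the Haralick (1973) set plus the
Soh–Tsatsoulis and Clausi extensions: autocorrelation, contrast, two
correlation variants, cluster prominence/shade, dissimilarity, energy
(angular second moment), entropy, two inverse-difference variants
(`homogeneity` = Σp/(1+(i−j)²), `inverse_difference` = Σp/(1+|i−j|)),
maximum probability, sum-of-squares variance, sum average/variance/entropy,
difference variance/entropy, the two information measures of correlation,
and the normalized inverse-difference pair.  Conventions that matter:

* gray levels are indexed 1..L (MATLAB-style), which affects the
  index-dependent statistics (autocorrelation, cluster shade/prominence,
  sum statistics) but none of the index-difference ones;
* all entropies use the natural logarithm with 0·log 0 ≡ 0;
* sum variance is taken about the *sum average* (the original formulation's
  use of sum entropy there is a widely acknowledged misprint);
* zero-variance marginals define both correlations as 0, and a zero
  marginal entropy defines the first information measure as 0.

The statistics that scikit-image also implements (contrast, dissimilarity,
homogeneity, correlation, ASM) are cross-checked against
`skimage.feature.graycoprops` in the test suite; the co-occurrence counting
itself is cross-checked against `skimage.feature.graycomatrix` (whose angle
labels map to this package's as 0↔0°, 45↔135°, 90↔90° for symmetric
matrices, because its offsets are measured with the row axis pointing the
other way).

**Histogram (6).**  Mean, variance, skewness, kurtosis, energy Σh², and
entropy −Σh·ln h of the normalized full-range intensity histogram.
Skewness and kurtosis are defined as 0 for zero-variance images.

**Shape (10).**  No annotation provides a mass boundary, so the mask is
produced by Otsu thresholding of the preprocessed ROI, keeping the largest
8-connected component and filling holes; a dataset-provided mask can be
substituted.  Descriptors come from `skimage.measure.regionprops`
(area, convex area, solidity, extent, equivalent diameter, perimeter,
moment-ellipse axis lengths and eccentricity).  Orientation is recomputed
from central moments as θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) with x = columns,
y = rows, reported in degrees in (−90°, 90°], so a horizontal structure has
orientation 0° (positive angles tilt toward increasing row index).  A
sample whose ROI cannot be segmented (e.g. constant intensity) is flagged
and excluded rather than zero-filled.

## Feature selection

The dynamic-length annealer treats the subset *size* as the search
variable: features are ranked once per training partition by Fisher score
(ε = 10⁻¹² guard; ties to the lower index; the score is affine-invariant so
the preceding z-scoring only stabilizes the guard), and a solution is the
top-nf ranking prefix.  Each outer temperature level starts by drawing nf
uniformly from [nf_min, nf_max] — a restart that keeps the search global —
and then performs `sub_iter` Metropolis moves, each perturbing nf by a
delta drawn from {±1, ±2} and *clamping* (not reflecting) at the bounds.
The best-so-far solution is tracked across restarts and returned.  An
optional `rank_truncation_plus_swap` move mode additionally swaps one
selected index for an unselected one with probability ½, allowing
composition changes beyond the ranking prefix; the prefix-only mode is the
default.

Defaults: T₀ = 4, decay α = 0.9, 40 levels × 10 sub-iterations, β = 0.01,
nf ∈ [10, 40].  The fitness accuracy term is seeded stratified 5-fold CV of
an RBF-SVM (C = 10, γ = "scale", standardization refitted per training
fold) on the training partition only, so selection never touches test
folds, and (subset, seed) → cost is deterministic and memoized.  In prefix
mode the search space has only nf_max − nf_min + 1 points, so an exhaustive
scan (`brute_force_rank_truncation`) provides the exact optimum as an
independent oracle; the annealer is still exercised faithfully because it
is the procedure under study.

The classic fixed-size baseline anneals at constant nf with single-feature
swap moves, initialized from the top-nf Fisher prefix; its size penalty is
constant, making it accuracy-driven.  On tables where an interacting
feature pair defeats marginal ranking (e.g. XOR-structured labels), swap
moves find combinations the prefix cannot, which the tests demonstrate.

## Classification and evaluation

The SVM is scikit-learn's soft-margin SVC with RBF kernel.  Features are
z-scored with training-partition statistics (RBF distances are
scale-sensitive; the raw blocks span ~6 orders of magnitude).  Grid search
is exhaustive over {10⁻⁴…10²}² with seeded stratified 5-fold CV accuracy
and deterministic tie-breaking (smaller C, then smaller γ).  Evaluation
reports per-fold confusion matrices (malignant positive) and percentage
metrics, aggregated as mean ± sample (n−1) standard deviation — the sample
convention is what reproduces the reference summary table (e.g. fold
accuracies [100, 100, 100, 95, 95] → 98 ± 2.74; the population convention
would give 2.45).  Feature selection defaults to `per_fold` scope
(re-selected inside every fold, the leakage-safe reading); a `global` scope
(one selection on the full table, matching reports of a single selected
subset size) is available but not default.

**F1 variants.**  `compute_metrics` defaults to the textbook
F1 = 2·P·R/(P+R) with P = precision and R = sensitivity.  The bundled
reference summary table, however, is only internally consistent with its
own fold matrices when F1 is computed as the harmonic mean of *sensitivity
and specificity* (every column reproduces to the printed precision under
that variant, several mismatch by up to ~0.3 under precision–recall F1), so
that variant is available as `f1_mode="sensitivity_specificity"` and is
used when reproducing the reference table.  Degenerate 0/0 ratios are
defined as 0 with a runtime warning.

## Synthetic data

**Phantoms.**  A benign phantom is an anti-aliased ellipse (default
major radius 36 px in a 160 px image, axis ratio 0.85, random orientation)
with near-zero boundary jitter and mild internal Gaussian texture
(σ = 4); a malignant phantom adds a low-order Fourier perturbation of the
boundary radius (jitter amplitude 0.2), 12 radial spicules (length ≈ 18 px,
Gaussian-profile width), and stronger texture noise (σ = 18).  Per-sample
cohort generation perturbs radius ±20% and jitter ±30%.  The 160/36 px
scale is deliberate: convex-hull estimates on rasterized shapes are biased
upward by roughly the perimeter-to-area ratio, and below ~30 px radius this
digital-geometry bias alone pushes a perfect ellipse's measured solidity
under 0.98, blurring the intended benign/malignant solidity contrast.
Phantoms model geometry and additive noise only — no mammographic physics,
no pectoral muscle, no density categories, no acquisition artifacts — so a
pipeline that separates them perfectly demonstrates that the feature
blocks, selector, and classifier work in the documented directions, *not*
that real-cohort accuracies are reproduced.  Real-image headline accuracies
require the actual datasets and are out of scope here; the bundled
reference fold matrices cover the metric arithmetic exactly instead.

**Tables.**  Informative columns are N(effect, 1) vs N(0, 1) between
classes (default effect 2, 5 informative of 50 columns, 200 balanced
samples); noise columns are unit-variance with optional equicorrelation via
a shared latent factor.  At effect 2 the Fisher ranking places all planted
columns in the top ranks almost surely, so recovery tests primarily
exercise the annealer's handling of the subset-size trade-off rather than
the ranking itself.

## Determinism and problem sizes

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); repeated runs with the same configuration are
bit-identical, including annealer traces.  The shipped tests and the
acceptance script use cohort sizes of 100 phantom images, 200 × 50 planted
tables, 10-seed oracle comparisons, and 20-run recovery ensembles — sizes
chosen so the full suite completes in about a minute on a single CPU while
keeping every statistical margin comfortable (the checked rates sit at
100% against thresholds of 80–95%).

## Known limitations

* The phantom classes are much easier than real mammographic cohorts;
  end-to-end CV accuracy saturates at 100%, so the "selection ≥ full set"
  comparison is an inequality that is tied at the ceiling rather than a
  strict improvement.
* Prefix-mode selection can only return Fisher-ranking prefixes; features
  informative only through interactions require the swap move mode (or the
  fixed-size baseline) to be reachable.
* DICOM support reads stored pixel values without windowing or rescale
  slope/intercept handling, and there is no DICOM writing.
* Segmentation is a global Otsu threshold; it assumes the mass is the
  largest bright structure in the ROI, which holds for phantoms and
  centered lesion crops but not for arbitrary mammogram patches.
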