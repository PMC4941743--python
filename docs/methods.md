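# Methods

## The problem

Occlusal enamel bands — the exposed ribbons of enamel on the chewing
surface of a high-crowned (hypsodont) horse tooth — differ in complexity
between the two tribes of the subfamily Equinae: Hipparionini carry more
convoluted bands than Equini. Older complexity indices (enamel length
divided by the square root of occlusal area) retain body-size scaling
because enamel length grows allometrically with tooth area. The fractal
dimensionality *D* of the band outline is scale-free, so it separates
complexity from size. This package estimates *D* from binary trace
images by box counting and relates species-mean *D* to occlusal surface
area (cm²) with Welch *t*-tests and phylogenetic generalized least
squares (PGLS) on a time-calibrated tree.

## Box-counting estimator

A trace is a binary raster in which 1 marks trace ink. The estimator:

1. **Border extraction.** The analysis concerns the exterior edge of the
   band, not its thickness, so the trace is reduced to foreground pixels
   with at least one background pixel in their 8-neighborhood (image
   boundary counts as background; morphological erosion with a 3×3
   structuring element implements this). A one-pixel-wide curve passes
   through unchanged; a filled region collapses to its outline.
   4-connectivity is available behind a flag; a diagnostic mode skips
   extraction entirely (useful for the *D* → 2 limit of a filled region).
2. **Counting.** For each box edge length *s* in the ladder
   {2, 3, 4, 6, 8, 12, 16, 32, 64} px (the conventional 2–64 px range on
   a near-geometric grid; configurable), the image is partitioned into an
   axis-aligned grid of *s*×*s* cells anchored at the origin (0, 0), and
   *N*(*s*) is the number of cells containing any foreground pixel.
   Partial cells at the image edges count: this is a covering number.
   An optional mode averages counts over *k* seeded random grid origins.
3. **Fit.** Ordinary least squares of log *N*(*s*) on log *s*;
   *D* = −slope (the log–log slope is negative for any curve, and the
   base of the logarithm is immaterial). The fit's R² is reported as a
   quality diagnostic. At least 3 sizes are required; a constant-count
   series is degenerate and returns *D* = 0 with a warning.

Anchors: a straight line gives *D* ≈ 1, a filled region ≈ 2, the Koch
curve log 4/log 3 ≈ 1.262, the quadric Koch (Minkowski sausage) 3/2,
the Sierpinski arrowhead log 3/log 2 ≈ 1.585.

**Resolution matching.** Box counting reads the scaling regime between
the smallest resolved feature and the image extent. If a generator
curve is rasterized so its unit step spans many pixels, the small boxes
of the ladder see locally straight segments and *D* is biased toward 1.
Validation rasters are therefore built so the minimum feature is ~1–3 px
(e.g. Koch iteration 5 at 729 px, Sierpinski iteration 9 at 729 px);
under that matching the estimator lands within ±0.06 of the analytic
dimension. Real traces should likewise be digitized so the finest enamel
plications span at least a couple of pixels. The count-monotonicity
invariant *N*(*s*) ≥ *N*(2*s*) ≥ ⌈*N*(*s*)/4⌉ is exact on nested
(dyadic) grids; for non-nested size pairs, sparse traces can violate
monotonicity marginally, which raises a warning rather than an error.

## Time calibration from stratigraphic ranges

Input trees (informal supertrees) carry no usable branch lengths. Given
first/last appearance data (FAD/LAD, Ma) per tip:

- each internal node is dated at the oldest FAD among its descendant
  tips;
- each terminal branch ends at the tip's LAD when `add_term` is on
  (tips with LAD = 0 reach the present), else at its FAD;
- any branch whose length would be zero — a tie between a node and its
  child's age or termination time — triggers a shift of the subtending
  node older by `vartime` (default 1 Ma), cascading rootward so no
  branch is negative. The rule is deterministic: ties resolve by the
  max, and permuting the ranges table cannot change the output.

The result is a non-ultrametric tree with strictly positive branch
lengths; fossil tips simply terminate before the present. This is a
faithful-behavior implementation of zero-length-branch-adjusted basic
dating, not a bit-compatible port of any particular R function; the
cascade rule for nested zero branches (each tied node gains exactly one
`vartime` increment) is a documented choice, worth sensitivity checks
when many FAD ties occur. `vartime` must be positive; its value only
pads tied nodes and has no effect on trees whose basic dating is already
strictly positive.

The phylogenetic covariance matrix has V[i,j] = branch length shared by
the root-to-tip paths of tips i and j (the depth of their MRCA) and
V[i,i] = the tip's root-to-tip distance; it is symmetric and PSD by
construction and constant-diagonal only for ultrametric trees.

## PGLS with Pagel's λ

The regression model is y = β₀ + β₁x + ε with
cov(ε) = σ²·V(λ), where V(λ) multiplies the off-diagonal of V by
λ ∈ [0, 1] and leaves the diagonal alone. λ = 1 is the Brownian-motion
expectation; λ = 0 removes all phylogenetic covariance, collapsing PGLS
to a GLS whose residuals are independent with variances equal to the tip
depths (for an ultrametric tree, ordinary least squares up to a scale
that cancels from every reported statistic).

Estimation is by maximum likelihood (not REML): for fixed λ the GLS
estimate is computed by Cholesky whitening, σ² is profiled out
analytically, and λ is maximized on [0, 1] by a 21-point grid followed
by bounded Brent refinement to 1e−6 (the grid guards against local
optima; boundary optima are kept exact). The 95% confidence interval is
the likelihood-ratio set {λ : logL(λ) ≥ logL(λ̂) − 1.92}; an endpoint
that reaches the search boundary is reported as absent, matching the NA
convention of comparative-methods software. ML rather than REML is used
because the 1.92-drop interval convention is defined on the same
likelihood being maximized.

Reported per fit: slope, intercept, their standard errors (from
σ̂² (XᵀV⁻¹X)⁻¹ with σ̂² = RSS/(n−2)), t = slope/se with n−2 df,
two-sided p, and R² (multiple and adjusted) computed in the whitened
space against the GLS intercept-only mean — there is no single canonical
GLS R²; this choice is internally consistent and reduces to the OLS R²
at V = I. Single-trait phylogenetic signal is the same λ profile applied
to an intercept-only model; a constant trait makes λ unidentifiable and
returns 0 with a warning.

The tribe comparison uses Welch's unequal-variance *t* with the
Welch–Satterthwaite df. Specimen-level group statistics can be
reconstructed exactly from species summaries by the sum-of-squares
decomposition pooled var = [Σ(nᵢ−1)sdᵢ² + Σnᵢ(mᵢ−m̄)²]/(Σnᵢ−1); species
with n = 1 contribute only the between-species term. Slopes of two
independent fits are compared with t = (b₁−b₂)/√(se₁²+se₂²) on
n₁+n₂−4 df (the classical parallel-slopes test). Normality and
variance-homogeneity checks are Shapiro–Wilk per group and Bartlett
across groups.

## Synthetic data

- **Curves** are L-systems (Koch: F→F+F−−F+F at 60°; quadric Koch:
  F→F+F−F−FF+F+F−F at 90°; Sierpinski arrowhead: A→B−A−B, B→A+B+A at
  60°) traced by a unit-step turtle and rasterized with Bresenham
  integer line drawing — no anti-aliasing, so outputs are truly binary
  and one pixel wide. Generation is seed-free and bit-stable; a raster
  too small to resolve the requested depth (minimum feature < 1 px) is
  refused.
- **Trees** are Yule (pure-birth) processes: exponential waits with rate
  b·k for k lineages, uniform choice of the splitting lineage, one final
  draw extending tips to the present; ultrametric by construction and
  reproducible under a seed.
- **Traits** are drawn from exactly the model the PGLS assumes:
  x ~ Uniform(2, 9) cm² per tip (the span of occlusal areas in the equid
  sample), ε ~ MVN(0, σ²·V(λ)) via Cholesky, y = β₀ + β₁x + ε. Cohorts
  add Gaussian within-species specimen noise with default SD 0.05, the
  median within-species dispersion of the published sample, and assign
  tribes by the root split.
- The published species summary table (35 species, 98 teeth; per-species
  n/mean/SD of *D* and area) ships as a packaged CSV.

What the generators do **not** emulate: tooth-shaped enamel geometry,
digitization noise, measurement error in areas, non-Gaussian trait
evolution, and correlated x. Passing tests therefore demonstrate
correctness of the estimators under their assumed models, not robustness
of the biological conclusions to violations of those assumptions.

## Defaults and problem sizes

| parameter | default | why |
|---|---|---|
| box ladder | 2,3,4,6,8,12,16,32,64 px | conventional 2–64 px range, near-geometric spacing |
| binarization threshold | 0.5, dark ink = foreground | traces are dark curves on light ground; configurable polarity |
| `vartime` | 1 Ma | minimal positive padding for tied nodes |
| `add_term` | on | fossil tips should span to their LAD |
| λ search | [0, 1], grid 21 + Brent 1e−6 | bounded range of the λ transform; grid defeats multimodality |
| within-species noise SD | 0.05 | median of the published per-species SDs |
| α | 0.05 | reporting threshold; configurable |

Validation problem sizes — 64-tip trees with 100 replicates for λ
recovery, 200 replicates for slope recovery, 1000 samples of n = 50 for
the Shapiro–Wilk calibration, 729–1100 px rasters for the fractal
anchors — were chosen so Monte-Carlo error is small relative to the
tolerances being checked while the whole suite runs in seconds.

## Known limitations

- *D* estimates depend mildly on raster resolution and grid placement;
  the random-origins mode quantifies the latter. Cross-study comparisons
  should hold digitization protocol constant.
- The λ profile on small trees (≲ 25 tips) is heavy at the {0, 1}
  boundaries; single-fit λ̂ values there should be read with the LR
  interval, not alone.
- The calibration's vartime cascade is one of several defensible
  zero-branch rules; trees dense in FAD ties deserve a sensitivity pass.
- Reconstructing specimen-level tests from species summaries is exact
  only if the summaries are themselves exact; rounded published tables
  propagate their rounding into the pooled statistics.
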