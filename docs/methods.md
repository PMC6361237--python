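# Methods

## Problem and model

The package tests whether disk-shaped objects ("cells of interest", COIs) in
a 2D image colocalize with a network structure (e.g. microvasculature) more
often than uniformly random placement predicts. A cell of radius *r* placed
at pixel *(x, y)* overlaps the network by at least one pixel exactly when
its center lies in the network mask morphologically dilated by *r*. The
true-pixel fraction of that dilated mask — the cell-dilated network fraction
(CDNF, *p*) — is therefore the per-cell colocalization probability under
uniform placement, and the colocalized count *c* out of *n* cells is
Binomial(*n*, *p*). The single-image test reports the upper tail
P(X ≥ c); the randomized sweep and the z-scored regression confirm
empirically that the CDNF, and none of the other structural parameters
(cell diameter or number, network radius, fraction, or length density),
determines the Monte-Carlo mean intercellular colocalization fraction
(ICF = c/n).

## Disk rasterization and dilation

One pixelation rule is used everywhere (dilation, placement, packing,
overlap counting): offset (dx, dy) belongs to the disk iff
dx² + dy² ≤ r², with pixel-center coordinates. Dilation is computed as a
threshold on the exact Euclidean distance transform (squared distances of a
boolean grid are integers, so the comparison is exact); tests assert
equality with explicit `binary_dilation` using the same disk. Dilation is
clipped at image bounds — network outside the field of view is unknowable —
and no border exclusion is applied to the CDNF. Cell centers are 0-based
integer pixel sites (x = column, y = row).

## Synthetic vessel networks

Networks are generated by seeding a point cloud by dart throwing with an
enforced minimum inter-point distance (sampling stops after 400 consecutive
rejections), labeling every pixel by its nearest seed, marking pixels whose
4-neighborhood spans ≥ 2 labels, and thinning to a 1-px-wide skeleton (the
pixelated Voronoi/watershed boundary). Skeleton segments — maximal runs
between junction or end pixels — are removed in a seeded uniform random
order until the rasterized network fraction (or centerline length density)
first drops to or below the target; because the measure is monotone along
the removal order, the stopping index is found by bisection, which is
equivalent to one-at-a-time removal and keeps pruning nested across
targets. Connectivity is not enforced during removal. The surviving
centerline is rasterized by disk dilation with the vessel radius.
Centerline length uses the chain convention: 1 per orthogonal adjacency,
√2 per diagonal adjacency; the measured radius estimate assumes ribbon-like
vessels (area ≈ 2·radius·length). Default minimum point distance is 24 px
at 512×512 (≈ 450 seeds), giving capillary-bed-like meshes whose mask
fractions span roughly 0.05–0.6 across the sweep targets.

## Random placement models

* **Monte Carlo (MCMRP).** Per trial, *n* centers are drawn uniformly over
  all pixels (overlap allowed); the ICF is the fraction of centers on the
  dilated mask. Counts are Binomial(n, CDNF) by construction.
* **Non-overlapping placement / packing.** Cells must be fully contained
  and pairwise disjoint as pixelated disks (disjointness means no shared
  pixel, equivalently the center offset lies outside the Minkowski sum of
  the disk with itself). Placement processes every admissible center pixel
  in one seeded uniform permutation, accepting candidates still free when
  reached — distributionally identical to dart throwing, with exact
  saturation detection (the candidate list is exhausted iff no admissible
  center remains). The packing ratio η (covered fraction at saturation) is
  tabulated per (diameter, width, height); it sits near the random
  sequential adsorption jamming limit (~0.52–0.56 here) and always below
  the hexagonal bound 0.901. Diameters below 5 px are rejected as
  unresolvable.
* **Hypergeometric model (HMRP).** N = round(A·η/(π r²)) placeable cells,
  K = round(N·p) colocalizing; rounding is half-away-from-zero and K is
  clamped to [0, N]. Its mean ICF K/N equals the binomial p up to the 1/N
  rounding quantum. It is provided for model comparison only; the binomial
  model is used for hypothesis testing.
* **Clumps.** Overlapping clumps jitter members uniformly within one radius
  of a uniformly placed anchor; non-overlapping clumps place members at the
  smallest disjoint offsets from the anchor (falling back to earlier
  members when the anchor ring is full). Pixelation means the minimal
  disjoint center separation can slightly exceed one diameter, so
  "touching" is defined as within one pixel of the minimal disjoint offset.
  Mean ICF is unchanged relative to individually placed cells, which is the
  property the tests assert.

## Statistical pipeline

* **Replicate pooling.** CDNF pools as the area-weighted pixel ratio
  (identical to the whole-image value when an image is dilated first and
  then split); cell counts sum. Pooling unequal-sized images is therefore
  well defined. The pooled binomial tail is the replicate p-value. The
  upper tail is summed directly in log space (not 1 − CDF) to avoid
  cancellation; c = 0 returns exactly 1.
* **One-sample test.** Under the null each replicate p-value is
  Uniform(0, 1); the null mean of N replicates follows the Bates
  distribution. The default simulates the pseudo-null (10⁷ trials by
  default, chunked; add-one correction so p > 0) and `method="analytic"`
  evaluates the exact Irwin–Hall sum, which is numerically sound in double
  precision to N ≈ 100. The left tail (small mean p-value ⇒ enrichment) is
  reported.
* **Two-sample test.** The observed statistic is the p-value of a Wilcoxon
  rank-sum (default; normal approximation without tie correction) or
  pooled t-test on the two groups' replicate p-values. Group labels are
  permuted; with at most `permutations` distinct splits all are enumerated
  (exact fraction of permuted p ≤ observed, ties counted as printed),
  otherwise labels are resampled with the add-one correction. Default
  granularity is per-replicate pooled p-values (independent units);
  per-image p-values can be passed instead where a design treats images as
  units.
* **Generic metrics.** Colocalized count per field of view, per mm of
  vessel centerline, and colocalized fraction, compared by unpaired
  t-tests. These are intentionally provided as the density-confounded
  baseline.

## In-silico experiments and problem sizes

All experiments derive every random stream from one integer seed via
`SeedSequence` spawning and are bit-reproducible.

* **Sweep** (CDNF identity, z-scored MVLR): 300 images at 512×512 with
  uniform draws — cell diameter 6–30 px, cell number 50–300, vessel radius
  2–10 px, pruning target fraction 0.05–0.6 — and 2,000 placement trials
  per image. At these sizes the Monte-Carlo error of a per-image mean ICF
  is ≤ ~2·10⁻³, two orders below the CDNF spread, so the CDNF–ICF Pearson
  correlation and the CDNF regression coefficient round to 1.000 and R² to
  1.00. The sweep parameter ranges are this package's reconstruction of
  typical vascularized-tissue conditions and are configurable.
* **Model comparison**: 100 sweep images at 10⁴ trials; Bland–Altman mean
  difference and limits, paired t-test, the fraction of discrepancies
  within ±1.96·sqrt(p(1−p)/(n·trials)), and a z-scored regression of the
  discrepancy on all parameters (expected non-significant).
* **Density confound**: two groups of 6 replicates (one 256×256 image
  each), dense (200 cells, network target 0.35) vs sparse (80 cells,
  0.15), cells placed uniformly in both; 100 seeded repetitions report
  rejection rates at α = 0.05. The permutation-calibrated comparison stays
  at ~5% while the per-FOV count t-test rejects in most runs.
* **Miscount**: 50 groups × 20 images at 256×256, 60 cells of diameter
  12 px (chosen a priori to merge roughly 20% of cells into connected
  components), vessels at fraction 0.25. Quantification by 8-connected
  components (count, mean area); an observed component colocalizes when
  any of its pixels overlap the network, so merged components — covering
  more area than one cell — colocalize more often than the single-cell
  CDNF predicts, which is the false-positive mechanism. Conditions:
  component counts modeled at the nominal diameter; at the effective
  mean-area diameter (d = 2·sqrt(mean area/π)) mitigation; ground truth.
  Group-level one-sample p-values use the analytic Bates CDF over each
  group's images.
* **Heterogeneous diameters**: per-cell diameters Uniform(low, high) vs a
  single mean-diameter disk, evaluated on shared placement draws (common
  random numbers), reporting the absolute mean-ICF difference and Cohen's
  d.

## What the synthetic data does and does not emulate

The generator reproduces arborized, wire-like vessel geometry with
controllable fraction, length density and radius, and cells as uniformly
random disks with optional non-overlap, clumping and diameter spread. It
does not emulate intensity noise, uneven illumination, segmentation error,
anisotropic or elongated cells, 3D structure collapsed by z-projection, or
biologically directed (non-random) cell motion. Passing tests therefore
validate the statistical machinery and its calibration under the stated
placement models, not the segmentation of real micrographs, whose
thresholds remain user-supplied.

## Numerical choices and edge cases

* Binomial and hypergeometric pmfs are evaluated via log-gamma; tails by
  log-sum-exp.
* σ of the hypergeometric with N = 1 is defined as 0.
* Degenerate two-sample inputs (all values tied) report p = 1 with a
  warning; zero-length or zero-cell images are excluded from the affected
  generic metric with a warning; a pruning target above the initial
  network measure returns the skeleton unchanged with a flag.
* Connected components use 8-connectivity, so diagonally touching cells
  merge — matching the quantification failure mode being modeled.
* The test suite seeds every stochastic check from one study seed chosen
  up front; tolerance bands are 3–4 Monte-Carlo standard errors.

## Known limitations

2D only; disk-shaped cells only; no automatic threshold selection; the
hypergeometric model's η must be tabulated per image size and diameter,
which is why the binomial model is the testing default; rank-sum p-values
use the normal approximation, adequate for the permutation calibration but
not for exact small-sample inference on its own.
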