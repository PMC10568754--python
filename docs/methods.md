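# Methods

This note records the models, conventions, and numerical choices behind
`segscore`, including the places where the underlying procedure is genuinely
open and a decision had to be made.

## Region model and geometry conventions

A label image is a 2D non-negative integer array; 0 is background and each
positive value is one region of interest (ROI). Regions are defined by
**label identity, not connectivity**: a fragmented label is one region,
because in an instance map the label is authoritative. Regions with fewer
than 3 pixels (`min_area = 3`) are discarded uniformly at the ROI and
feature levels; such fragments are segmentation debris, and including them
at one level but not another would make levels incomparable.

Coordinates are 0-based `(row, col)` with pixel centers at integer
positions. Fixed conventions, chosen so every number is bit-reproducible:

* **Centroid** — unweighted mean of pixel-center coordinates.
* **Feret diameters** — measured on the convex hull of the four corner
  points of every region pixel (pixels as unit squares). The minor feret is
  the rotating-calipers minimum width of that hull. Measuring on corners
  rather than centers guarantees a strictly positive minor feret even for
  1-pixel-thick regions (a 1×10 line has minor feret 1.0, a single pixel
  1.0); this matters because half the minor feret is the ROI matching
  radius and must never vanish.
* **Perimeter** — count of exposed unit pixel edges (4-connectivity). This
  integer definition is exactly invariant under 90° rotation.
* **Convex area / solidity** — area of the corner-point hull;
  `solidity = area / convex_area ∈ (0, 1]`, exactly 1 for solid rectangles.
* **Eccentricity** — from the eigenvalues `λ1 ≥ λ2` of the pixel-coordinate
  covariance, `√(1 − λ2/λ1)`; 0 for single pixels and isotropic blobs.

## ROI matching and the pseudo confusion matrix

A predicted region is a *candidate match* for a ground-truth region when
the Euclidean distance between their centroids is **strictly less** than
half the ground-truth region's minor feret diameter. Ground-truth regions
are swept in ascending label order; per region, all still-unclaimed
candidates are collected: exactly one ⇒ TP; two or more ⇒ TP and
`over_segmented += 1`; none ⇒ FN. Candidates are then deleted from the
predicted pool, and everything left after the sweep is FP. Background is a
single negative object, so there is no TN — a pseudo confusion matrix.

Decisions where the procedure is underdetermined:

* **Sweep order.** The deletion rule makes results order-dependent;
  ascending label order is fixed and documented.
* **TP status of over-segmented regions.** A region matched by multiple
  predictions is counted TP (with the multiplicity logged in the match
  table); counting it FN would break `tp + fn = #GT`.
* **Under-segmentation** is evaluated against the *original* pre-deletion
  sets: every predicted region whose centroid satisfies the criterion for
  `k ≥ 2` ground-truth regions adds `k` to the tally. This makes the count
  independent of sweep order.

A geometric caveat worth knowing: for **centrally symmetric** disjoint
regions (disks, ellipses), a prediction formed by merging two ground-truth
regions can never satisfy the criterion for both — the triangle inequality
would require the two ground-truth centroids to be closer than half the sum
of their minor ferets, which disjointness forbids. Under-segmentation is
therefore only *detectable* by the centroid rule for asymmetric shapes
whose centroid sits well off-center (the test suite uses flat triangle
pairs sharing a base, where the centroid lies at h/3 from the base but the
match radius is h/2). This is a property of the centroid rule itself, not
of this implementation.

## Pixel level

Binarization maps any nonzero label to foreground. All counts are exact
integers. MCC is computed with an exact-integer shortcut: when
`(TP·TN − FP·FN)²` equals the product of the four marginals the result is
returned as exactly ±1.0, so perfect (anti-)agreement is never blurred by
floating-point square roots. Every zero-denominator ratio is NaN
(undefined), never 0 — downstream PCA handles missing values explicitly
and silently zeroing would fabricate signal.

## Feature level

For each feature, ground-truth and predicted per-region samples are pooled
to choose **shared** bin edges (per-sample binning would make bin-wise
distances ill-defined): Freedman–Diaconis width `h = 2·IQR·n^(−1/3)`, bin
count `ceil(range/h)`, minimum 1. Degenerate fallbacks: zero IQR with
nonzero range ⇒ Sturges count `ceil(log2 n)+1`; all-equal pooled values ⇒
one unit-width bin `[v−0.5, v+0.5]`; both samples empty ⇒ undefined.
Histograms are normalized to probability vectors, so intersection is 1.0
for identical distributions regardless of region counts.

Numerical conventions in the distance registry:

* Histogram intersection is computed as `1 − L1/2` (identical to
  `Σ min(p,q)` for probability vectors) and the Bhattacharyya coefficient
  as `1 − ½Σ(√p−√q)²`, so self-comparison scores are exactly 1.0/0.0
  rather than 1 ± 1 ulp.
* An epsilon (1e-10) replaces zero bins **only inside** log/ratio formulas
  (KL, PSI, percentage errors); absolute metrics see raw vectors.
* The Jensen–Shannon distance uses natural logarithms (disjoint supports
  score √ln 2 ≈ 0.8326); KS, match distance, Cramér–von Mises and
  Wasserstein are CDF-based on the shared edges, Wasserstein weighting CDF
  differences by bin widths (so it equals the match distance on unit bins).
* Sum/CDF-based metrics are invariant to padding both histograms with
  empty bins; the per-bin *mean/median* error statistics in the registry
  (MAE, SMAPE, ...) are bin-count dependent by definition and are not.

The registry holds 38 metrics; with 9 ROI and 22 pixel metrics the suite
totals 69 distinct names (prefixed `roi_`/`pixel_`, feature metrics named
once each). Histogram comparisons are only meaningful when each image
contributes tens of regions; with a handful of regions the histograms are
dominated by binning noise, and the identity results below do not certify
behavior in that regime.

## PCA metric selection

Rows are image pairs (optionally across models), columns metrics. Cleaning
is explicit: constant columns dropped with a warning, incomplete rows
dropped complete-case with the count reported. Columns are mean-centered
but **not variance-scaled by default**: the selection statistic
`Σ_retained |loading| × variance%` is designed to surface the metrics
carrying the most variance, and rescaling every column to unit variance
erases exactly that signal (with standardized iid columns PCA provably
cannot prefer any column). `standardize=True` exists for tables mixing
incommensurate scales. Components are retained up to 90% cumulative
explained variance (threshold configurable); importance aggregates
retained components by *sum*, and the full component × metric grid is
returned so callers can apply max instead. Ties rank alphabetically, making
selection deterministic; eigenvector sign is irrelevant since absolute
loadings are used.

## Synthetic scenes and corruptions

`generate_scene` rejection-samples non-overlapping axis-rotated ellipses
(default: 15 regions, semi-axes 4–8 px, centroid separation > 18 px on a
192×192 frame — a sparse field of nucleus-sized objects) with a budget of
500 attempts per region, raising a `PackingError` naming the constraint on
failure. Semi-axes are drawn independently from the radius range, capping
the aspect ratio at 2; this guarantees that bisecting a region across its
centroid leaves both half-centroids within the match radius (half-ellipse
centroid offset ≈ 0.424·a < b whenever a/b < 2.36), so `split` provably
produces `over_segmented = 1`. The intensity channel is Gaussian
(foreground mean 200, background 40, sd 8, clipped at 0) — a high-contrast
fluorescence-like image. The generator emulates object layout and contrast
only; it has no texture, no intensity gradients within objects, no touching
cells and no annotation noise, so perfect scores on synthetic identity
pairs certify the *metric implementations*, not segmenter performance on
real tissue.

Corruptions and their designed consequences: `drop k` ⇒ recall exactly
`(n−k)/n`, FDR 0; `add m` (blobs placed outside every existing region's
match radius) ⇒ FDR exactly `m/(n+m)`, recall 1; `split` ⇒ over = 1;
`merge` relabels the nearest pair (see the centroid-rule caveat above);
`erode`/`dilate` shrink/grow each region with a 4-connected structuring
element (dilations that would collide with a neighbor are skipped with a
warning); `shift` translates regions, clipping at borders, with collision
pixels ceded to the stationary region. All randomness flows through one
`numpy.random.default_rng` seed carried in the spec.

## Problem sizes used in verification

Self-evaluation exactness runs 50 default scenes; oracle equivalence uses
500 random 8×8 mask pairs and 200 random 10-bin histogram pairs; the
corruption grid uses scenes of 8–15 regions; the PCA recovery experiment
uses 100 replicates of two 50-sample populations over 8 metrics with a
3-sd effect in exactly one; the erosion ladder applies magnitudes 0–4 to
20 dense scenes (60 regions, semi-axes 5–10 px, 288×288) — dense enough
that area histograms are populated and their degradation is monotone
rather than binning-noise-dominated. These sizes are the package's chosen
verification conditions and are fixed in `scripts/acceptance.py` and the
test suite.

## Known limitations

* The centroid/feret matching rule cannot flag under-segmentation of
  symmetric shapes (see above) and can in principle match a prediction
  whose overlap with the ground-truth region is poor, since no overlap is
  checked; it is the documented procedure, not an optimal assignment
  (no IoU matching, no Hungarian algorithm, by design).
* Only 2D single-class label images are supported; multi-class data should
  be evaluated one class map at a time.
* The feature catalog is the 9-feature geometry/intensity subset, not a
  full cytometric extractor; texture features are out of scope.
* The exact historical membership of the 38-metric distribution registry
  is partly reconstructed; the 16 canonical distances are standard, the
  remaining error statistics are documented in `feature_eval.py` and the
  registry is extensible.
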