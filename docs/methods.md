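# Methods

This note documents the statistical models implemented in `spatcell`, their
assumptions, the parameters that matter, and the design choices made where
the methodology was genuinely open.

## Data model

An ROI is a labelled planar point pattern: cell centroids in continuous µm
coordinates inside a rectangular window, each carrying an opaque categorical
cell-type label. Coordinates follow the imaging convention — origin top-left,
y increasing downward, half-open window [0, W) × [0, H); masks are 0-based
integer label images with pixel (r, c) centred at ((c+0.5)s, (r+0.5)s) for
pixel size s. The window should be supplied explicitly (e.g. 1000 × 1000 µm
for a 1 mm² acquisition); when absent it is inferred as the bounding box
rounded up to whole µm, which slightly biases densities and is therefore
only a fallback. All statistics treat each ROI as one independent pattern;
condition-level estimates aggregate ROIs explicitly (below) rather than
pooling raw points.

## Quadrat correlation matrix (QCM)

The window is tiled from the origin into squares of edge `quadrat_size`
(default 100 µm; edge quadrats may be partial and are kept, since observed
and null share the geometry). For each unordered type pair, the observed
Pearson correlation of the quadrat count vectors is compared with a null
built by randomly permuting all cell-type labels over the fixed positions
(`n_shuffles`, default 1000). Only labels move, so each type's total count
and the point set's spatial structure are preserved — correlation induced
purely by shared tissue architecture is absorbed into the null. Two-sided
empirical p-values use add-one smoothing, p = (1 + #{|null| ≥ |obs|}) /
(n_shuffles + 1), so p = 0 never occurs; BH correction runs across pairs.
A pair passes the screen when its coefficient is positive and q < 0.05 —
positivity because the screen gates co-location analysis; negative
associations are reported but never gate. Raw counts (not densities) are
correlated: quadrats are equal-area apart from edge remnants and the null
uses identical geometry, so any bias cancels. Screening is per ROI; at
condition level a pair proceeds to PCF analysis if it passes in at least one
ROI of that condition (a deliberately permissive gate for a screening step).

## Cross-pair correlation function

With anchors a of type A, g(r) = [Σ_a n_a(r)/W_a(r)] / (N_A N_B/|Ω|), where
n_a(r) counts B cells at distance [r, r + dr) (half-open bins; self-pairs
excluded when A = B) and W_a(r) is the exact area of the annulus intersected
with the window. The edge correction is analytic: the disc∩rectangle area
decomposes into four quadrant problems with a closed form (each quadrant is
either a full quarter disc, a chord segment, or the full corner rectangle),
valid whenever the centre is inside the window — always true for anchors.
This keeps E[g] = 1 under CSR including near boundaries. Defaults follow the
headline statistic of the analysis protocol: inner radius 20 µm with annulus
width dr = 10 µm (about one cell diameter), and the full curve on r ∈
[0, 300] µm in 5 µm steps. Annuli that fall entirely outside a small window
have W_a = 0 and yield NaN (undefined), never zero.

Confidence intervals follow the anchor-resampling bootstrap: the N_A
per-anchor contributions n_a/W_a are resampled with replacement `n_boot`
times (default 1000, implemented as multinomial weights) and the 2.5/97.5
percentiles of the replicate g values form the 95% CI. One anchor leaves the
CI undefined (flagged, not faked). Condition-level curves pool counts: the
per-anchor contributions of all ROIs are concatenated, each normalised by
its own ROI's B intensity, so the pooled curve is the count-weighted
combination rather than an average of per-ROI ratios, and the bootstrap
resamples anchors across the whole condition.

The topographical correlation map is the matching local indicator of
spatial association: per anchor, Γ_a = observed/expected − 1 with expected =
N_B W_a/|Ω| for the disc of the threshold radius (default 100 µm). Γ is
bounded below by −1 (no B within the threshold) and positive where B is
locally enriched; Σ_a (1 + Γ_a) reweights the anchors' contributions to the
cross-K numerator at the threshold. For visualisation Γ is smoothed onto a
raster by a Gaussian-kernel weighted average with bandwidth threshold/2.

## Neighbourhood correlation function (NCF)

Every cross-type triplet (one cell of each of C1, C2, C3) defines a
neighbourhood — the minimum enclosing circle of the three centroids. The
3-point MEC is computed in closed form from the pairwise distances: if the
largest squared side is at least the sum of the other two (right/obtuse or
degenerate triangles) the MEC is the longest side's diameter circle,
otherwise the circumcircle; no general-purpose MEC algorithm is needed for
fixed-size triples, and the case analysis is exact and fully vectorised.

MEC radii are binned at 5 µm up to 150 µm. The CSR reference p3(r) — the
probability that three uniform points in the same window give an MEC radius
in bin r — is Monte-Carlo estimated from M triples (default 10⁷; 10⁵ is
adequate for exploration and is what the test suite uses), with an overflow
bucket beyond 150 µm so the total mass is exactly 1; estimates are cached
per (window, bins, M, seed). Then NCF(r) = hist(r)/(n · p3(r)) with n the
number of triplets used. When N₁N₂N₃ exceeds `subsample_cap` (default
5×10⁶) a seeded uniform subsample of that size replaces full enumeration
and n rescales accordingly — an unbiased estimator of the same quantity.
Bins where the reference has no mass give NaN, not 0.

Uncertainty comes from a label-shuffle bootstrap: positions stay fixed, the
labels of the participating cells are permuted (`shuffle_universe` chooses
between the three participating types only — the default, preserving the
three counts and the joint spatial support — or all cells), and the MEC
histogram is recomputed per replicate (default 1000). The envelope is the
5th/95th percentile per bin, the summary the median. Percentiles are order
statistics (`lower` for the 5th, `higher` for the 95th): histogram counts
are integers, and interpolating between order statistics would narrow the
envelope spuriously for discrete counts. Note the observed pattern is
exchangeable with its own label shuffles under CSR, so the band's per-bin
coverage is by construction close to its nominal 90% — the envelope
calibrates inference, it does not inflate it.

Condition-level NCFs concatenate the observed radii of all ROIs (sum the
histograms), sum the ROI bootstrap histograms per replicate index, and use
the triplet-count-weighted p3, so the pooled curve is
total_hist(r)/Σ_i n_i p3_i(r). Two identical ROIs therefore pool to the
single-ROI curve exactly.

## Contact networks (ACN / CCN)

Two segmented cells are in contact when some pixel of one lies within
Chebyshev distance 1 of a pixel of the other (8-connectivity across a
shared boundary; a 1-pixel background gap breaks contact). A config switch
(`contact_rule: chebyshev1 | edge_only`) restricts to 4-connectivity. Every
mask label is a node of the adjacency graph, isolated cells included.

For each ordered type pair, O_AB counts A cells touching at least one B.
The null permutes all cell-type labels over the fixed graph (default 1000
permutations); z_AB = (O_AB − μ)/σ from the permutation mean and SD, with
two-sided p = 2·Φ̄(|z|) and BH FDR across pairs. σ = 0 is flagged degenerate
(p = 1), never divided through. O_AB is anchored on A and deliberately
asymmetric; both orientations are reported. The z on counts equals the z on
proportions O_AB/N_A because N_A is fixed under label permutation — the
count form is canonical and the equivalence is unit-tested.

Condition-level aggregation weights ROIs by their anchor counts: weighted
mean z with w_i = N_A,i, and a weighted Stouffer combination
Z = Σ w_i Φ⁻¹(1 − p_i)/√(Σ w_i²) of one-sided p_i = Φ̄(z_i). One-sided at
condition level because the network filter requires positive z and a
Stouffer combination of two-sided p-values would discard direction; ROI
level stays two-sided. The final network keeps pairs with g(20) > 1,
z > 0 and condition-level q < 0.05; node size encodes cells/mm², edge
weight the contact count, and greedy-modularity communities are reported as
a visualisation aid, not asserted science.

## Abundance screen

Densities are counts per mm² of window area, zero-filled for absent types.
Within a condition, every pair of types is correlated across ROIs (Pearson r,
two-sided t-based p with df = n − 2, BH across the condition's pairs);
conditions with fewer than `min_rois` (default 3) ROIs, or zero-variance
density vectors, are flagged not-evaluated. Densities rather than counts
are correlated; with equal-sized windows the two are identical.

## Synthetic data

The generators emulate the study conditions each statistic needs, not real
tissue morphology:

* **CSR** — independent homogeneous Poisson per type: the null for every
  statistic (QCM significance ≈ α, g ≈ 1, NCF ≈ 1, CCN z ≈ 0).
* **Paired attraction** — anchors in the window eroded by offset + 10 µm,
  each with exactly one partner at the exact offset distance, uniform angle.
  Optional exact `n_pairs` and a hard-core `min_separation` between anchors
  (sequential dart throwing): with min_separation greater than offset plus
  the annulus outer radius, each anchor's annulus holds exactly its own
  partner and g(r) has a closed form — the package's analytic benchmark
  (50 pairs at 25 µm in 1 mm² give g(20) = 10⁶/(50·π·500) ≈ 12.73). Exact
  distances (not noisy) are deliberate: they yield the closed-form target.
* **Triplet clusters** — parent points in an eroded window, one cell of each
  of three types uniform in a disc of `cluster_radius` around each parent;
  all planted MEC radii are ≤ cluster_radius by geometry, giving the NCF its
  recovery target.
* **Thomas process** — Poisson parents with Gaussian offspring shared
  between types, for softer co-clustering alternatives.
* **Mask synthesis** — each cell rasterised as a disc; contested pixels go
  to the nearest centroid (ties to the lower cell id) and every cell keeps
  at least its centroid pixel. Erosion margins keep planted structure away
  from boundaries so analytic targets are edge-correction-agnostic.

All generators are deterministic given the seed. What passing tests on this
test bed do **not** show: robustness to segmentation errors, irregular
(non-rectangular) tissue windows, intensity inhomogeneity within an ROI, or
mis-annotation of cell types — real-data effects outside the generators'
scope.

## Numerical choices and problem sizes

* Distance bins and quadrats are half-open, [r, r + dr), so boundary points
  are counted exactly once.
* p-values from permutation tests use add-one smoothing; BH q-values come
  from the standard step-up (statsmodels) with NaN (undefined tests)
  excluded from the correction.
* Sub-seeds for every (module, condition, ROI, pair) are derived from the
  master seed by a stable hash, so stage results are reproducible
  independently of execution order and the whole pipeline is byte-identical
  under rerun.
* The test suite and the acceptance script run scaled-down problem sizes
  chosen to estimate each quantity with adequate precision on one core:
  calibration rates use 100–200 simulated ROIs/graphs with 199 permutations
  each; NCF null calibration pools 50 sparse ROIs (500 × 500 µm, ~20 cells
  per type) at M = 10⁵ and 200 bootstrap replicates; the demonstration
  pipeline uses three 400 × 400 µm ROIs. Production analyses should use the
  defaults (M = 10⁷, 1000 replicates/permutations).

## Known limitations

* Edge correction assumes rectangular windows; masked/irregular tissue
  boundaries are not supported.
* The CCN normal approximation for permutation p-values can be coarse for
  very rare types (few permuted configurations); degenerate cases are
  flagged rather than resolved.
* The NCF is implemented for exactly three types; higher-order
  neighbourhoods are out of scope.
* Contact analysis is 2-D and unweighted; shared-boundary length is not
  used.
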