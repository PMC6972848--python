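# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `parklens`.

## Photograph classification

Photographs are represented only by their keyword sets (≤ 10 labels, as
a machine-vision API would return). The binary keyword matrix has the
sorted union of all keywords as its vocabulary; duplicates within a
photo count once. Jaccard distances are computed exactly via a float64
matrix product (intersection counts are integer-valued sums of 0/1
products, so no precision is lost relative to set arithmetic).

Ward clustering is applied directly to the Jaccard dissimilarity matrix
through the Lance–Williams update (scipy's `linkage(…, "ward")` on the
condensed matrix). This is "Ward on dissimilarities": Jaccard distances
are not Euclidean, so the variance interpretation is heuristic, but the
merge criterion is well defined and the resulting tree has monotone
heights. Cutting is done with `cut_tree`, which always yields exactly k
clusters; category ids follow dendrogram leaf order so that adjacent
ids are adjacent clusters (this ordering also makes the distance-based
kappa weights meaningful).

The evaluation graph uses one seeded random sample (default 10% with a
floor of 200 photos) re-used across all k; eval(k) is the pair-weighted
mean between-cluster distance minus the mean within-cluster distance.
On data with c well-separated groups the curve rises steeply to k = c
and flattens after, which is what the L-method exploits. Note that
eval(k) peaks at the true group count and can decrease beyond it:
splitting a tight cluster moves near-zero distances into the
between-cluster pool.

The L-method fits two least-squares lines over every admissible
breakpoint (each segment ≥ 2 points) within a window of the first 20
graph points; the knee minimizes the size-weighted RMSE. If the knee is
not in the middle third of the window, the window grows by 10 points
and the search repeats, stopping when the knee is roughly centred or
the points are exhausted. On a continuous piecewise-linear curve the
junction point lies on both lines, tying two breakpoints at zero RMSE;
the tie is resolved to the junction (the larger candidate). A perfectly
collinear graph has no knee: the smallest candidate is returned with a
warning rather than an error, leaving the decision to the caller.

## Accuracy assessment

A stratified random sample (default per-stratum size capped by the
stratum) is shuffled and compared against manual labels. Weighted kappa
uses disagreement weights w_ij = |i−j|/(C−1) (linear, the default;
quadratic and 0/1 also available) over the category ordering; the
weighting scheme and ordering are configuration because agreement
studies rarely pin them down. Mutual-misclassification candidates are
pairs whose symmetrized off-diagonal rate
(n_ij + n_ji)/(row_i + row_j) exceeds a threshold; merging such a pair
can only move off-diagonal mass onto the diagonal, so aggregation never
lowers overall accuracy.

In the pipeline's synthetic setting there is no human observer. The
stand-in observer labels each photo with the cluster category that is
the majority vote for the photo's *true* generator category — i.e. an
observer who understands the discovered categories perfectly. The
resulting accuracy therefore measures cluster purity and is
optimistically high compared with a human study; it is not comparable
to agreement rates on real imagery.

## User axes

Residential status: profile country if present, else the modal country
of geotagged public photos (subsampled to a 50-photo cap with a seed;
ties broken lexicographically for determinism); neither → unresolved,
excluded downstream.

Compositions are closed after replacing zeros by the
percentage-scale +1 rule: counts → percentages (0–100) → add 1 to every
component → re-close. This keeps every part strictly positive with a
bounded distortion (≤ 1 part in 103 per component at C = 3).

The ilr transform uses pivot coordinates,
z_j = √((C−j)/(C−j+1)) · ln(x_j / gm(x_{j+1..C})). Any orthonormal ilr
basis yields the same fitted subspace, which is why loadings are
reported back in clr space (loadings_clr = V · loadings_ilr, with V the
contrast matrix; clr loadings of each component sum to zero by
construction). Robust PCA takes location/scatter from a
minimum-covariance-determinant estimate with support fraction 0.75 and
falls back to classical moments with a warning when the estimator
cannot run. Component signs are fixed so each component's
largest-magnitude clr loading is positive; the recovered axes are
therefore reproducible but their orientation relative to any external
axis is arbitrary.

## Regression models

Counts: NB2 with log link and log-offset; (β, θ) jointly estimated by
maximum likelihood (statsmodels, BFGS from a Poisson warm start,
gradient tolerance 1e−8, Nelder–Mead fallback). Passing a fixed θ fits
a GLM with known dispersion; θ → ∞ recovers Poisson. AIC is
2(p + 1) − 2ℓ with p coefficients plus the estimated dispersion. All
regressors, including the binary tourist indicator, are standardized to
mean 0 and sample SD 1, so coefficients are per-SD effects; this keeps
the design consistent with scaling every regressor and is documented
rather than hidden.

Composition: Dirichlet regression in the common parameterisation,
log α_ic = x_iᵀ β_c, fitted by quasi-Newton (BFGS, analytic gradient
via digamma, tolerance 1e−8), standard errors from the inverse observed
information (numerical Hessian). Inputs must be strictly interior to
the simplex; `dirichlet_compress` applies the standard shrink
y* = (y(n−1) + 1/C)/n before fitting. With two components the
likelihood coincides with a Beta regression, which the tests exploit as
a reduction check. The park composition is built over the aggregated
categories; a configurable category subset mirrors analyses that drop a
catch-all category before closure.

Stepwise selection drops the least significant candidate while its
p-value exceeds 0.05, otherwise the candidate whose removal lowers AIC
most, stopping when neither applies. Pure backward-AIC
(`p_threshold=None`) is also available and then the AIC trace is
non-increasing by construction; the combined rule is the default
because AIC alone retains a null regressor with probability
P(χ²₁ > 2) ≈ 0.16, which is rarely what a p-value-guided analysis
intends. VIF_j = 1/(1−R²_j) from regressing each regressor on the rest
with intercept; perfect collinearity reports ∞ with a warning.

## Frequency comparison

One photo is drawn per user per repetition (default 50 repetitions) and
category fractions are averaged per user group, which weights every
user equally regardless of how many photos they took. The estimator's
expectation equals the mean over users of their within-user category
proportions. Tests per category use the pooled two-proportion z
statistic (z² equals the Pearson χ² of the 2×2 table); the effect size
is the χ² → r → d conversion d = 2r/√(1−r²), r = √(χ²/N), and r is
reported alongside d. P-values are raw by default (no multiplicity
correction), matching common practice in this kind of descriptive
comparison. The sensitivity analysis recomputes the mean-frequency
table under independent sub-seeds for each repetition count and reports
the SD across recomputations, which decreases with repetitions in
expectation.

## Spatial aggregation

Point-in-polygon uses shapely with `intersects`, so boundary points
count as inside; a photo covered by overlapping polygons is assigned to
the smallest-area polygon (a convention — official park layers rarely
document their overlap semantics). Coordinates are WGS84 lon/lat and
the test is planar; at city scale the geodesic error is negligible, and
this is a documented limitation rather than a correction. Park area is
an equirectangular approximation (deg² × 111.32² × cos φ); parks under
0.1 km² are flagged. Per park, users are counted uniquely, skew is
tourists − locals (positive = tourist-dominated, recorded in the output
metadata), and mean axis scores appear only for parks with at least
three unique users.

## Synthetic-data generator

The generator emulates the study conditions every stage is validated
against:

* **Users.** Default 800 users, 59% tourists (matching the roughly
  3:2 tourist:local split of the emulated study population). Half list
  a profile country. Each user has two latent preference axes per
  channel (public, favourited) — a 'Landscapes–People'-like axis and a
  'Wildlife–City'-like axis — normal with SDs 1.3 and 1.0 and a
  cross-channel correlation of 0.35 per axis (the weak cross-channel
  agreement reported for such data is ~0.33–0.36). Unequal SDs give the
  two principal components distinct eigenvalues; with equal SDs the
  PCA solution is rotation-degenerate and no method could attribute
  components to axes.
* **Keywords.** Ten categories, 30 category-specific keywords each plus
  a 40-keyword shared vocabulary; each photo draws 5–10 distinct
  keywords, each draw taking the shared pool with probability 0.2.
  This produces the within-category keyword overlap that makes
  clustering recoverable while leaving realistic between-category
  confusion.
* **Channel compositions.** A user's public (and favourited) category
  distribution is softmax(1.5 · (a₁v₁ + a₂v₂)) with fixed orthogonal
  zero-sum contrast directions v₁, v₂; photo categories are multinomial
  draws from it. Public upload counts are Poisson (default mean 30,
  min 1), favourites Poisson (mean 20).
* **Park photos.** Counts are NB2 with log-offset on uploads,
  β = (−1.8, −0.4 tourist, 0.25, 0.4, 0.1, 0.2) over
  (intercept, tourist, public axes, favourited axes) and θ = 2 — about
  0.17 park photos per upload at the baseline, i.e. a city-scale rate
  at which a heavy tail of users passes the ≥5-photo eligibility rule.
  The per-user park composition is Dirichlet with
  log α = xᵀB (tourists shifted toward 'city' categories). Tourists
  concentrate their park visits on low-index parks and locals on
  high-index parks (geometric weights), giving each park a
  residential-status skew; park geometry is a grid of disjoint
  rectangles in a synthetic WGS84 box.
* **Geotags.** Locals' public photos are geotagged in the home country
  with probability 0.9, tourists' with probability 0.2 (otherwise in
  the tourist's own country), which makes the modal-country heuristic
  informative but imperfect.

What the generator does **not** emulate: label-confidence scores,
temporal dynamics, spatially heterogeneous park shapes, user-specific
vocabulary idiosyncrasies, and the long-tailed activity distributions
of real platforms. Passing recovery tests therefore demonstrates that
the machinery is correct and well calibrated under its stated model,
not that any particular real-world dataset would yield the same
accuracy.

## Problem sizes and determinism

Validation runs use deliberately moderate sizes — 2,000 photos for
cluster recovery, 2,000 users for axis recovery, n = 3,000 × 50
replicates for count-model bias, 20 seeded end-to-end runs for the
sign-recovery rate — chosen so the whole validation suite completes in
minutes on one CPU while keeping Monte-Carlo error well below the
assertion margins. All randomness flows through seeded
`numpy.random.Generator` instances; pipeline outputs contain no
timestamps or timing, so identical configurations produce
byte-identical files.

## Known limitations

* Ward on non-Euclidean dissimilarities is a heuristic (documented
  above); no embedding-based or probabilistic keyword weighting is
  provided.
* The quadratic memory/time cost of the distance matrix caps practical
  clustering around ~10⁴ photos; the pipeline clusters a seeded
  subsample above `max_cluster_photos` and extends assignments by mean
  Jaccard similarity to the sampled cluster members.
* Status inference assumes the platform's profile country is truthful
  and that public geotags reflect residence.
* The Dirichlet model needs several users per parameter; the pipeline
  skips the fit (and says so in its output) when the eligible-user
  count is below three per parameter.
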