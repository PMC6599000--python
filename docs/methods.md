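# Methods

This note records the models, conventions and open design choices behind
`isoassign`, in the order the pipeline runs them.

## Delta notation and calibration

Isotope abundances are expressed as δ = 1000·(R_sample/R_std − 1) in per
mil, with R the heavy/light ratio and R_std the international standard
(VPDB for C, AIR for N, VSMOW for H and O). Raw instrument deltas are
normalized per isotope by the unique affine map through two keratin
reference materials analysed alongside the samples: BWBIII (δ¹³C −20.18,
δ¹⁵N +14.31) and PRCgel (−13.64, +5.07) for C/N; CBS caribou hoof
(δ²H −197, δ¹⁸O +2.50) and KHS kudu horn (−54.1, +21.46) for H/O.

For hydrogen the two-point keratin map *is* the comparative-equilibration
correction: co-equilibrated keratins absorb the exchangeable-hydrogen
effect, so no explicit exchange-fraction model is kept. C/N normalization
is likewise two-point; a lab that prefers a single-point offset can pass
a slope-1 line. One line per isotope per batch; within-run drift is out
of scope. Anchors map to their accepted values to machine precision — a
fitted line applied at an anchor reading must return the accepted value
exactly, which is the package's own built-in correctness check.

## Cohort screening and age contrast

Adults are deduplicated to one record per individual (earliest capture —
the rule is arbitrary but must be deterministic; recapture records carry
no extra cross-sectional information). An individual sampled as a cub and
later as an adult legitimately appears once in each age group.
Subpopulations with fewer than `min_n = 20` adults are dropped entirely
(too small for the discriminant and kriging steps downstream).

The age contrast controls for subpopulation with the additive two-factor
model and Type II sums of squares: the hypothesis cross-product H for age
is the increase in residual cross-product when age leaves the model, E
the full-model residual cross-product. Pillai's trace V = tr(H(H+E)⁻¹)
is converted to the standard approximate F with s = min(p, q), q = 1 for
the age term; with p = 1 this reduces exactly to the univariate Type II
F, which is how the implementation is cross-checked against an
independent OLS/ANOVA route. No interaction term is fitted: the question
is a mean shift between age classes given subpopulation, and an
interaction would change the estimand. The multivariate test uses
complete cases on all requested isotopes; univariate ANOVAs use
per-isotope completeness, so their error degrees of freedom legitimately
differ from the MANOVA's.

## Grouping subpopulations

Each isotope is z-scaled across all individual records first (making per
mil scales commensurate — δ²H spans ~100 per mil, δ¹³C ~5), then the
per-subpopulation median of scaled values is taken. Scaling before the
median preserves the median's robustness to within-subpopulation
outliers; the opposite order is available by scaling medians externally,
but is not the default. Rows are clustered agglomeratively on Euclidean
distance; the linkage (Ward, average, complete) with the highest
cophenetic correlation wins, ties resolved in that fixed order. The
group count maximises mean silhouette width over k, with silhouette of a
singleton cluster defined as 0 (a common convention; it guarantees the
all-singletons cut can never beat genuine structure) and ties broken
toward smaller k.

## Quadratic discriminant analysis

Per class: mean, unbiased covariance, prior proportional to class size
(mirroring the default of the reference discriminant implementation;
uniform priors are a flag). No covariance regularisation by default —
the estimator stays the plain Gaussian QDA; an optional
shrinkage-to-diagonal λ exists for near-singular classes. LOOCV refits
the model from scratch on every fold; the implementation is verified to
equal an explicit refit loop exactly, and its accuracy approaches the
analytic Bayes rate Φ(2) on the two-Gaussian N(0,1)/N(4,1) design.

One caveat documented by the tests: under the null (labels carry no
information), LOOCV with size-proportional priors is pessimistically
biased below chance at small n, because removing the held-out record
tips the prior toward the other class. The null-calibration check
therefore runs with uniform priors, where mean accuracy is 50% as
expected.

## Isoscapes

Per isotope, on training records only:

- **Outlier fence**: records outside [Q1 − 3·IQR, Q3 + 3·IQR] are
  removed and logged (k = 3 is a conservative reading of histogram-based
  outlier removal; configurable). Zero IQR disables the fence with a
  warning.
- **Split**: 70/30 per-subpopulation simple random split, at least one
  record on each side of every stratum.
- **Detrend**: OLS plane value ~ 1 + lon + lat (order configurable
  {0, 1, 2}); kriging operates on residuals and the trend is added back
  to predictions.
- **Semivariogram**: Matheron estimator on great-circle-distance bins
  (15 lags to one third of the maximum pairwise distance), fit by
  weighted least squares with weights N(h)/h² over nugget, partial sill,
  range (and Matérn shape ν ∈ [0.2, 5] for the K-Bessel model; ν = 0.5
  is exactly the exponential model). All distances are haversine km —
  the analysis is projection-free, and grids live in geographic degrees
  (default 0.5–1.5° cells at desk scale).
- **Ordinary kriging**: per cell, solve [Γ 1; 1ᵀ 0][w; m] = [γ₀; 1];
  prediction wᵀz, variance wᵀγ₀ + m. The matrix diagonal is 0 while the
  nugget is retained in off-diagonal and right-hand-side semivariances:
  the nugget then acts as a measurement-error filter (smoothing
  kriging), and with nugget = 0 the predictor interpolates the data
  exactly. This convention matters: placing the nugget on the diagonal
  makes the system the unregularised signal-covariance form, and with
  smooth fitted shapes (ν near 5) the weights oscillate violently —
  observed as residual predictions an order of magnitude outside the
  data range. Duplicate locations are jittered by 1e-4° (or rejected,
  by configuration); a nearest-neighbour cap (default 100) bounds the
  system size, and when all observations fit under the cap one
  factorisation serves every cell.
- **Uncertainty (EBK-style)**: the proprietary restricted-likelihood
  empirical Bayes kriging is approximated by an explicit bootstrap:
  n_sims subsets of subset_size records drawn without replacement, each
  detrended, fitted and kriged; the surface is the across-simulation
  mean and the standard error combines mean kriging variance with
  between-simulation prediction variance. Desk-scale defaults are
  100 simulations of 100 records (25 in the demo pipeline); the
  500/500 configuration used on full-size data sets is available
  through configuration.

Aligned stacks crop to the common extent, resample bilinearly to the
coarsest grid, and propagate any layer's nodata mask to all layers.

## Spatial clusters

Unmasked stack cells are z-scaled per layer (again so δ²H cannot
dominate) and partitioned around medoids. PAM is the canonical
deterministic BUILD (greedy cost-minimising seeding) plus
steepest-descent SWAP; clara runs PAM on 5 independent subsamples of
size 40 + 2k (the classical defaults) and keeps the draw whose medoids
give the lowest total dissimilarity over all points, reducing to exact
PAM whenever a draw covers the data. k ranges over [2, 10]; the average
silhouette width over the full cell set selects k, the total-cost curve
is returned for elbow inspection, and a best silhouette below 0.3
triggers a weak-structure warning. Labels are renumbered by descending
cluster size so repeated runs are comparable.

A known property worth stating plainly: BUILD+SWAP converges to a
swap-neighbourhood local optimum, which on a few percent of small
unstructured instances is not the global medoid optimum; the reference
R implementation returns the identical medoid set on such instances.
The tests therefore assert that PAM never beats the exhaustive optimum
and matches it on the overwhelming majority of random instances.

## Multivariate assignment

Each spatial cluster is summarised by the mean and unbiased covariance
of the raw (unscaled) isotope vectors of training individuals captured
inside it — individuals, not raster cells, because they carry the
within-region biological variance the assignment must model (the
raster-cell alternative sits behind a flag). A new individual is
assigned to the cluster maximising the Gaussian log-density, with equal
priors across clusters (forensic neutrality; area-proportional priors
would presume abundance information). Ties go to the lowest cluster id;
the posterior ratio of best to second-best is reported and an optional
odds threshold can leave weak cases unassigned. Clusters with fewer
than p + 2 training members raise an error, or are merged into the
cluster with the nearest medoid when the merge fallback is enabled.
Accuracy on the held-out 30% uses the raster label at the capture
location as truth.

## Synthetic data

The generator emulates the features the analysis depends on:

- **Polygons**: Voronoi cells of seeded random centres tiling the
  study bbox (default five subpopulations over the −100…−62°E,
  58…76°N window), or equal longitudinal bands.
- **Surfaces**: per-isotope linear trends (δ¹³C and δ²H rising
  eastward, δ¹⁵N westward, δ¹⁸O weak) plus a Gaussian random field with
  exponential covariance C(h) = sill·exp(−h/range), drawn by Cholesky
  factorisation of the cell-centre covariance (grids capped at ~3000
  cells — simplicity over spectral methods at desk scale).
- **Records**: uniform locations within each polygon; adult value =
  bilinear field value + N(0, σ) with σ the per-isotope measurement
  error (0.1 per mil C/N, 2 per mil ²H, 0.4 per mil ¹⁸O); cubs add the
  offsets (+0.9 δ¹⁵N, −1.3 δ¹³C, −20 δ²H, 0 δ¹⁸O) — plausible
  magnitudes for the nursing signature, configurable, and not estimates
  from any data set. Defaults of 100 adults and 16 cubs per
  subpopulation are roughly half the per-subpopulation scale of a
  full-size field study.
- **Plateau scenario**: the end-to-end benchmark plants three
  longitudinal regions whose mean vectors step by `separation` (default
  3) within-region SDs between neighbours, with distinct spatial
  patterns per isotope (δ¹³C monotone east, δ¹⁵N central low, δ²H
  eastern high) so the region signatures are non-collinear in isotope
  space — mirroring the qualitative situation where different elements
  trace different gradients. Under this scenario the pipeline recovers
  k = 3 and ≥ 85% held-out assignment accuracy, and accuracy rises
  monotonically with separation.

What the generator does **not** emulate: sea-ice or prey dynamics,
inter-annual drift, non-Gaussian biological variation, spatially varying
measurement error, and movement of individuals between regions.
Passing tests therefore demonstrate correctness and statistical
calibration of the machinery, not field-data performance; real tissue
data carry temporal and behavioural variance these conditions exclude.

## Numerical conventions

Quartiles by linear interpolation; unbiased (ddof = 1) variances
throughout; covariance factorisations by Cholesky with failures surfaced
as explicit errors naming the class or cluster; kriging systems by LU
with a 1e-10·sill diagonal guard; softmax posteriors shifted by the row
maximum; variogram optimisation by bounded trust-region least squares
started from the first-lag/plateau heuristic. Determinism: every
stochastic step takes a seed, and identical configurations produce
byte-identical CSV, ASCII-grid and manifest outputs.

## Problem sizes

Demo and test runs use grids of a few hundred cells, 180–580 records,
10–25 bootstrap simulations of 60–100 records, and Monte-Carlo suites of
100–500 replicates — sizes chosen so the whole pipeline and its
statistical checks run comfortably on a laptop while leaving every
asymptotic property measurable. The full-scale settings (0.1–0.5°
grids, 500 simulations of 500 records) are plain configuration changes.
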