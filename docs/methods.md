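# Methods

## The maximum-entropy model

The core estimator is a presence/background Gibbs model over
environmental space.  Given presence covariate rows x₁…x_m, background
rows with base-measure weights w(x) ≥ 0, and a feature expansion f(x),
the model is

    q_λ(x) = w(x) · exp(λ·f(x)) / Z(λ),
    Z(λ)   = Σ_background w(x) · exp(λ·f(x)),

and fitting minimizes the convex objective

    −(1/m) Σ_i λ·f(x_i) + log Z(λ) + Σ_j ρ_j |λ_j|,
    ρ_j = β · s_j / √m,

with s_j the sd of feature j over the background and β a single
regularization multiplier (default 3, a deliberately smooth setting
appropriate for small samples and broad extents).  Features are the
standardized value z and its square z² per continuous covariate —
quadratic response curves and nothing richer; threshold and hinge
features are intentionally absent — and one-hot indicators per declared
categorical level (an unseen level encodes as the all-zero reference;
aspect uses N/E/S/W with "flat" as reference).

The L1 term is handled exactly by splitting λ = u − v with u, v ≥ 0 and
running L-BFGS-B on the smooth objective in (u, v); at the optimum the
usual soft-thresholding stationarity conditions hold, and the solution is
compared against an independent cyclic-coordinate-descent optimizer in
the tests (agreement to 1e-3 per coefficient).  Convergence tolerance is
1e-10 on the relative objective, 5,000 iterations maximum.  Constant
covariates are dropped with a log message.  Background weights enter the
partition function as base-measure weights, so the fit is invariant under
positive rescaling of the weights, and all-ones weights reproduce the
unweighted fit bit for bit.

Predictions: the raw relative density exp(λ·f(x) − log Z) (weighted mean
1 over the training background) is converted to a per-point scale and
transformed; the default cloglog output is 1 − exp(−e^{H−log n}·raw)
with H the entropy of the fitted background density and n the
(positive-weight) background count, so a featureless model predicts
1 − 1/e everywhere.  Logistic and raw outputs are available.  When
projecting beyond the training range, covariates are clamped to the
training minimum/maximum — the standard transfer behavior; response
curves therefore flatten outside the training envelope.

Replicated fitting draws independent random splits of the presences
(70% train / 30% evaluation by default, 10 replicates), shares the
background across replicates, and averages predictions arithmetically.
Splitting the background as well would change little (it only enters
through means); sharing it keeps the feature standardization constant
across replicates.

Variable contributions use permutation importance: the drop in
presence/background AUC when one variable's values (both expanded
features jointly) are permuted across the pooled evaluation rows, mean of
10 permutations, floored at zero and normalized to sum to 100%.  This is
one of several contribution heuristics in circulation; it is simple,
model-agnostic, and winner-takes-most when a single covariate separates
perfectly — worth remembering when reading contribution tables.

## Background weighting for non-equilibrium invaders

An invading population has not reached every suitable site, so the
invaded-range background contains "false absences" that bias the fitted
niche narrow.  Each invaded background point is weighted by

    w(p) = 1 / (1 + (p / (1 − p))²),    w(1) := 0,

where p is the suitability projected at that point by the model
calibrated in the native range.  w decreases strictly from w(0) = 1
through w(½) = ½; points the native model considers suitable contribute
little to the background sum.  No rescaling to mean 1 is applied — the
dual is invariant under positive scaling of the weights, which a test
asserts.  Presences are never weighted.

## Evaluation

AUC is the Mann–Whitney statistic (ties count one half), computed from
mid-ranks, which equals exact pair counting at every sample size.

The continuous Boyce index slides windows across the range of the
landscape/background scores at 101 equally spaced centers; per window,
P = share of presence scores inside and E = share of landscape scores
inside; windows with E = 0 are dropped, and CBI is the Spearman
correlation between window center and P/E.  The default window width is
2% of the score range.  The more common 10% width makes neighboring
windows share 90% of their data, leaving roughly ten effectively
independent windows — a random model then shows |CBI| ≈ 0.3 routinely,
which defeats the index's "0 = random" reading.  At 2% a random model
stays below |CBI| = 0.3 in ≈99% of simulations at n = 1,000.  Both the
width and the number of centers are recorded in every report and
settable in `StudyConfig`.

## Variable screening

Candidate variables are clustered by the transitive closure of pairwise
|r| > 0.7; the best-scoring member of each cluster is kept (score =
training gain of a univariate MaxEnt fit by default); then the
worst-scoring variable with VIF > 10 is dropped iteratively until all
survivors pass.  Exact score ties keep the variable earlier in canonical
column order, making the procedure deterministic.  Expert judgment is
supported only as explicit `force_keep` / `force_drop` lists.

## The virtual-species generator

The generator manufactures landscapes with the statistical structure the
analysis assumes, not any real geography:

* **Climate.**  White noise convolved with a Gaussian kernel
  (autocorrelation range in km), then empirically whitened and mixed
  through a PSD square root of a target correlation matrix, so realized
  pairwise correlations equal the target exactly.  Layers are
  standardized over cells.
* **Habitat.**  Quantile slices of a second smoothed field give clustered
  integer classes; the host raster thresholds another smoothed field at
  the (1 − prevalence) quantile; DEM and stand basal area are smooth
  fields in plausible ranges (0–1,500 m; 5–40 m²/ha).  Habitat structure
  uses its own (typically finer) clustering range than climate.
* **Truth.**  Suitability is s(x) = expit(a0 + Σ a1_j z_j + a2_j z_j²)
  with a2_j ≤ 0 (unimodal, representable by the model's quadratic
  features).  Standardization constants can be frozen so one niche
  definition applies across regions whose climate envelopes differ.
  Occupancy weight is s × host (if host-dependent) × (normalized basal
  area)^affinity — the affinity exponent makes *presence* partly
  habitat-driven while *impact severity* remains a function of climate
  suitability alone, via three ordered cutpoints on s plus a ±0.05
  uniform jitter (severity 1–4; levels 3–4 count as "high").
* **Sampling.**  Equilibrium mode draws cells without replacement with
  probability ∝ occupancy weight (at most one record per cell, mirroring
  the de-clustering applied to field data).  Invasion-front mode occupies
  introduction cells in year 1 and, each later year, draws up to a fixed
  number of new cells among those within the dispersal radius of the
  occupied set, again ∝ weight; the occupied set never shrinks and each
  newly colonized cell yields one dated record.

### Reference study conditions

The packaged experiments freeze one set of conditions:

* Niche: a0 = 2, a2 = (−4, −1.5) on the two informative layers of four,
  optimum at z = 0.  In the native region the informative layers are
  generated with inflated variance (×2.5, ×1.5) — the native range is
  climatically broader, exposes both niche flanks, and suitable habitat
  is a rare tail of the environment.  These curvatures were chosen so the
  *Bayes-optimal* presence/background AUC of the generator itself (a
  property computable from the truth alone) falls in the 0.88–0.95 band
  where well-fitting regional SDMs operate; a flatter niche caps every
  model, perfect ones included, near AUC 0.8.
* Truncated invasion: the invaded region's dominant layer is offset by
  +3 sd, so its envelope covers one niche flank, and occurrences come
  from a 5-year dispersal-limited spread (radius 10 km) from a single
  introduction at the region's best cell — both niche truncation and
  within-region false absences, the structure background weighting is
  designed to absorb.  Native sample 83 occurrences; invaded ~1,000;
  10,000 background points per region.
* Regional experiment: 160×160 cells of 0.5 km, climate autocorrelation
  12 km versus habitat clustering 1.5 km (climate varies regionally,
  forest structure locally — without this separation the climate layer
  separates presences from background even inside 10 km buffers and the
  Reduced models degenerate to 100% climate), host prevalence 0.3,
  habitat affinity 3, 6 invasion years at 150 new cells per year; the
  distribution model uses the final year's records as presences and
  distances to the prior year's records, the severity model the
  high-severity subsets of each.
* Grid sizes (120–200 cells per side) and single fits inside the
  multi-seed loops keep a full 10-seed comparison in the tens of seconds
  on one CPU; the replicated-split machinery is exercised separately.

What passing these experiments shows — and what it does not: the
generator reproduces the *statistical* structure (autocorrelation,
collinearity, truncation, dispersal limitation, severity linkage), not
real marginal climate distributions, real geography, sampling bias, or
observation error.  Directional results on these landscapes demonstrate
that the machinery behaves as designed, not that any particular real
invasion obeys the same magnitudes.

## Pipeline conventions and open choices

* Planar km coordinates on a regular grid, Euclidean distances, cell
  centers carry coordinates; row 0 is the top row.  Distances are
  computed in km and reported in metres in covariate outputs.
* Patch metrics per 1 km² block anchored at the raster origin
  (4-connectivity by default; partial edge blocks use available cells):
  fragmentation = patches/classes, heterogeneity = patches × classes.
* Focal statistics use a circular window of cells whose centers fall
  within the radius; masked cells leave both numerator and denominator
  (shrinking window at borders, no padding).
* Aspect = down-slope facing quadrant from central differences, flat
  below gradient 1e-6; entered in models as one-hot over N/E/S/W with
  flat as the all-zero reference.
* Regional models: calibrated on the current year's occurrences only;
  the severity models use high-severity (levels 3–4) presences, with the
  threshold configurable.  Reduced variants drop the distance and
  host-cover covariates and use the buffered, host-masked background.
* Area summaries count unmasked cells at or above a suitability
  threshold (default 0.5 on the cloglog scale — the transform's midpoint
  convention; the threshold is reported with every summary) × cell area,
  in hectares.  Next-year projection freezes coefficients and updates
  only the distance layers, masking output by the host distribution.
* Response-curve support width (used in the transfer comparison) is the
  width of the variable interval where the replicate-mean curve reaches
  half its maximum, swept over each model's own training range — beyond
  it clamping flattens the curve, so a model trained on a narrow envelope
  cannot gain width it never observed.
* All randomness flows from per-run seeds through named `numpy`
  Generators; no stage touches global random state.  Identical
  configuration and seed reproduce every output byte for byte, which the
  determinism test asserts on output digests.

## Known limitations

* The generator's severity link (cutpoints on suitability) is an
  assumption enabling oracle tests, not an empirical claim about any
  insect.
* Permutation contributions are unstable when covariates are strongly
  collinear; the screening module exists precisely to limit that regime.
* No geodesic distances, no multi-resolution rasters, no sampling-bias
  model (target-group background and bias files are out of scope).
* GeoTIFF I/O is not provided; the on-disk raster format is the ESRI
  ASCII grid, which round-trips values at float32 precision.
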