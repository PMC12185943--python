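# Methods

This note documents the models, the defaults and the design choices behind
`ecosdm`, and what the synthetic validation does and does not establish.

## Study design

Each species is modeled with a presence–background design: its filtered
occurrence records against a species-specific set of background points, in
three variable arms (climate-only, soil-only, climate + soil), with four
model families fit over repeated stratified train/test splits.  Species are
assigned to ecoregions at thresholds τ ∈ {0.6, 0.7, 0.8, 0.9, 1.0} — a
species belongs to an ecoregion at τ iff at least a fraction τ of its
on-map records fall inside it — and results are aggregated by ecoregion and
τ.  The comparator is inclusive (≥) rather than strict: a strict reading of
"more than τ" would make the 100% class unsatisfiable, while the inclusive
rule keeps it meaningful (species with every record in one ecoregion).

## Occurrence preparation

* **Cleaning** drops records with missing/non-finite coordinates, records
  off the raster extent or on nodata cells, and exact duplicate coordinates
  within a species; each drop carries a reason code.  This replaces the full
  test battery of dedicated coordinate-cleaning packages with validity,
  extent and duplicate checks — adequate for gridded synthetic data and a
  documented simplification for real data.
* **Geographic filtering** keeps the first record per occupied grid cell
  (idempotent, commutes with cleaning).
* **Minimum-record gate**: species with ≤ `min_records` presences are
  excluded before modeling.  Continental studies typically gate at >100
  records; the synthetic default is 50 so small fixtures remain viable.
* **Environmental filtering** (optional, off by default in the synthetic
  study) bins each variable's observed range into `n_bins = 8` equal-width
  intervals and keeps one record per occupied bin combination, chosen
  uniformly at random.  Bin count and variable set are configurable because
  neither is canonical; filtering uses the full candidate catalog by
  default rather than the post-selection subset.
* **Background weighting**: a product-Gaussian KDE of the presence
  coordinates is evaluated at every unmasked cell center; cells are sampled
  without replacement with probability ∝ density (one point per cell, at
  cell center, mirroring the presence convention).  The per-axis bandwidth
  is the normal-reference rule 1.06·min(sd, IQR/1.34)·n^(−1/5), with a
  global scale factor; degenerate spreads require an explicit bandwidth.
  The default request of 10,000 points caps at the number of
  positive-density cells with a warning.  Background is drawn once per
  species, not per replicate.

## Covariate selection

Per species, on its presence + background rows:

1. **VIF pre-screening** (optional entry point; threshold 10): iteratively
   drop the variable with the largest 1/(1 − R²) until all fall below the
   threshold.  When used on rasters, VIF is computed on whole-domain cell
   values rather than presence-only values.
2. **Collinearity filter** (r_cut = 0.7): among any pair with |Pearson r| >
   r_cut, processed in decreasing |r|, remove the member with the lower
   univariate explained deviance (weighted logistic fit of the response on
   that variable alone).
3. **Three embedded rankings**:
   * *Elastic net* (mixing 0.5): logistic elastic-net fits over a geometric
     30-point penalty path from λ_max; variables rank by order of entry
     (first nonzero coefficient), ties within a step by coefficient
     magnitude, never-entered variables last.  Entry order is a pure
     ranking device, so no cross-validated penalty choice is needed.
   * *Shrinkage-spline GAM*: a weighted additive logistic model with cubic
     B-spline smooths (basis dimension 4), centered for identifiability and
     fit by penalized IRLS with penalty α·(curvature + 0.1·I) per smooth.
     The ridge component shrinks the penalty null space, so a smooth can be
     removed entirely — the behaviour of selection-capable shrinkage
     smoothers.  Variables rank by the weighted variance of their fitted
     component on the linear-predictor scale (a deviance-explained share);
     smooths shrunk to zero rank last.
   * *Guided regularized random forest* (γ = 0.5, 500 trees): a
     preliminary forest's importances set per-variable penalty factors
     λ_j = (1 − γ) + γ·imp_j/max(imp); the ranking is a second forest's
     importance scaled by λ_j.  This realizes the guided-regularization
     idea — variables the guide considers unimportant are handicapped —
     at the ranking stage, since per-feature split-gain penalties are not
     expressible inside standard tree learners.
4. **Aggregation**: unweighted mean of per-method ranks (a method that
   fails to converge is dropped with a warning), ties broken toward higher
   univariate deviance; the top 5 climate and top 5 soil survivors are
   chosen.  The chosen set can never contain a pair above r_cut, and this
   is asserted in tests.

## Model families

All families consume the same weighted design matrix; case weights equalize
total presence and background mass (effective prevalence 0.5) because
backgrounds outnumber presences by orders of magnitude.

* **GLM** — weighted logistic regression on standardized linear + quadratic
  terms (near-unpenalized, C = 10⁴).
* **GAM** — the shrinkage-spline additive logistic model above (α = 1.0);
  prediction inputs are clipped to the training range because B-spline
  bases do not extrapolate.
* **RF** — 500-tree classification forest, mtry = ⌈√p⌉, balanced class
  weights; the suitability score is the class-1 vote fraction.  Tests use
  smaller forests (50–200 trees) purely to keep the suite fast; forest
  size does not change any qualitative conclusion.
* **MaxEnt-style** — L1-penalized logistic regression (C = 1) on
  standardized linear + quadratic + hinge features (10 quantile knots per
  variable, forward and reverse), with background case weights inflated
  ×100 to approximate the infinitely-weighted presence–background scheme.
  This is the standard GLM realization of maximum entropy, not a port of
  the original Java software.

**Replicates**: "n replicates" means n independent stratified random 80/20
splits (presences and backgrounds stratified separately), not disjoint
k-fold CV — repeated splitting is the convention of ensemble SDM platforms,
and both readings are available through `test_fraction`/`n_replicates`.
**Ensembles** default to the unweighted cellwise mean over all live
family × replicate members; TSS-weighted averaging and a TSS inclusion
cutoff are options because no single committee rule is canonical.  The
ensemble is always bracketed cellwise by the member min/max.

## Evaluation and importance

* **AUC** uses the Mann–Whitney rank form with midranks for ties.
* **TSS** maximizes sensitivity + specificity − 1 over the distinct
  observed scores plus the endpoints {0, 1} (exact and scale-free, rather
  than a fixed grid); classification is score ≥ threshold ⇒ presence, and
  threshold ties break toward the smaller value.
* **Permutation importance** shuffles one column at a time (default 5
  permutations), re-predicts, and takes clip(1 − Pearson r, 0, 1) between
  reference and permuted predictions, averaged over permutations; constant
  prediction vectors score 0.  Pearson correlation on the raw predictions
  is the default (Spearman available); the clip keeps anti-correlated
  permutations on the [0, 1] scale.  Importance is computed on the full
  presence + background matrix, not test rows only.
* **Relative contributions** average importance over families × replicates
  per variable and normalize to percentages summing to 100 per species
  (all-zero vectors stay zero, flagged); ecoregion tables are unweighted
  means over the species assigned at a given τ, with per-category mean
  rows.  Normalize-then-average is the default (averaging raw importances
  is available via the intermediate tables).

## Sensitivity analysis

The unit of replication is the species: per (species, τ) rows carry the
species' replicate-mean ensemble AUC/TSS (or its contribution shares) and
its assigned ecoregion at that τ.  A two-way ANOVA with interaction uses
type II sums of squares (robust to the unbalanced species counts per
ecoregion); if any factor cell has fewer than two observations the
interaction is dropped with a warning.  Tukey HSD runs on each factor's
marginal means, with bands at 0.05/0.01/0.001/0.0001.  Tukey adjusted
p-values are never below the raw pairwise p-values, and the ANOVA's type-I
error is calibrated (checked at 0.05 ± 0.02 over 200 null simulations).

## Synthetic landscape and virtual species

* **Environmental layers** are Gaussian random fields: white noise
  convolved with a Gaussian kernel (σ = `autocorr_range` cells,
  restandardized), mixed through the Cholesky factor of a target
  cross-correlation matrix (default: exchangeable 0.3 correlation between
  the climate and soil blocks, so soil is informative about climate-driven
  niches without being redundant).  Non-PSD targets are rejected naming the
  offending eigenvalue.
* **Ecoregions** are grown competitively from well-separated seed cells
  (farthest-point sampling): each region claims the unassigned frontier
  cell with the lowest priority (distance from seed + smoothed noise) until
  it reaches its area quota.  Growth from a single seed makes every region
  one connected blob by construction, and quotas reproduce the default
  49/11/12/28% area shares to within a few cells.  Region-growing was
  chosen over quantile-slicing a smoothed latent field because slices of a
  random field routinely fragment thin area classes, violating the
  contiguity contract.
* **Region–environment coupling**: real ecoregions differ in their
  environments, so the driver layers are shifted per region by ±`strength`
  (default 2 SD units) with the sign pattern of a hypercube corner per
  region.  Without this, a narrow niche cannot confine a species to one
  region and the assignment thresholds never bind.
* **Virtual species** have product-Gaussian suitability
  ∏ exp(−(x_v − μ_v)²/2σ_v²) over their active variables, rescaled by the
  realized grid maximum (so every landscape contains a perfectly suitable
  cell; this couples suitability to the realization and is intentional).
  Specialists use σ = 0.4 centered on a home region's mean environment;
  generalists σ = 1.2.  These defaults make specialists reach the 100%
  assignment class in roughly half of landscape realizations and
  generalists the 60% class in most — a flora with both classes populated,
  matching the sharp attrition of the 100% class seen in real floras.
* **Sampling** draws presence cells without replacement ∝ suitability ×
  optional bias surface (an exponential corner gradient emulating uneven
  collection effort), points at cell centers.

What the generator does **not** emulate: climate physics and realistic
variable semantics (layers are exchangeable z-scored fields), dispersal
limitation, biotic interactions, coastline/mask geometry, taxonomic error,
and temporal sampling structure.  Passing tests therefore establish that
the *pipeline* recovers planted structure under its own assumptions — not
that any particular real flora satisfies those assumptions.

## Problem sizes and numerical choices

The validation suite runs specialist/generalist floras on 32×32 grids with
~120–150 presences, ~1000 background points, 2 replicates and reduced
forests, over 20-seed panels; the acceptance script uses 5-seed panels.
These sizes were chosen as the smallest at which the planted effects are
comfortably detectable.  Degenerate inputs are defined behaviour: empty
occurrence tables pass through cleaning, constant variables collapse to one
bin, species failing any stage are skipped with a logged reason and never
abort a run.  All stochastic steps take explicit seeds; pipeline stage
seeds derive from the master seed keyed on (stage, species), so adding a
species never perturbs existing results and a rerun is byte-identical.

## Raster formats

Rasters are read and written as single-band ESRI ASCII grids (`.asc`,
plain text, nodata tag) with a JSON sidecar for the variable catalog —
a deliberately simple, diff-able interchange format; multi-band GeoTIFF
stacks can be converted with any standard GIS tool.

## Known limitations

* MaxEnt is the penalized-logistic equivalent, not the reference Java
  implementation; regularization paths differ in detail.
* The guided-RRF ranking approximates guided regularization at the
  importance level rather than inside tree induction.
* No spatial cross-validation: replicate splits are random, so reported
  AUC/TSS are optimistic under strong spatial autocorrelation (a known
  property of the design, not corrected here).
* The ANOVA treats species as independent replicates; phylogenetic and
  spatial non-independence are out of scope.
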