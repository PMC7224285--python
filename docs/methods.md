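# Methods

## The problem

Inferential variable selection in epidemiological datasets with p close to n
and strong multicollinearity is unstable: different automated selection
methods, each defensible, select different covariate subsets from the same
data. `selstab` operationalises *triangulation* across methods: run many
selectors under one common protocol, quantify each covariate's bootstrap
selection stability per method, and aggregate stability across methods to
identify covariates that are robust to both data perturbation and analytic
choice.

The motivating data shape is a survey-style study: one continuous outcome
(revenue per acre, in GBP), ~400 subjects, ~340 continuous and binary
covariates with block-wise correlation, a handful of true effects, and a
best attainable cross-validated R² around 0.65.

## Common protocol

For every method:

1. **Tuning.** Hyperparameters are chosen by repeated k-fold cross-validation
   (library default 10 folds × 10 repeats) minimising the mean absolute
   error (MAE). All candidates share the same seeded fold partitions; ties
   resolve to the sparser-inducing value (larger λ, smaller `nprune`), then
   first-listed.
2. **Final model.** Fit on the full data at the tuned values; the selected
   support is the set of covariates retained (nonzero coefficients; for
   ridge, coefficients above a relative magnitude threshold of 1e-3; for
   MARS, parents of retained hinge terms).
3. **Internal vs CV fit.** MAE and R² on the full training data ("internal")
   versus under repeated k-fold CV with hyperparameters frozen. The CV MAE is
   the mean of per-fold MAEs; the CV R² is computed on the pooled held-out
   residuals (more stable than per-fold averaging at k=10; the aggregation
   choice was open).
4. **Selection stability.** B bootstrap resamples of rows (with replacement);
   the method is refit on each (hyperparameters frozen at the full-data
   tuned values; BSLR and RBVS, which have no tuned hyperparameters, re-run
   their full searches); stability of covariate j = percentage of resamples
   selecting j. Coefficient values on selected resamples are summarised by
   2.5/50/97.5 percentiles.
5. **Triangulation.** Per covariate, the max and median stability across the
   eight sparse methods (BSLR and ridge are excluded by default: they retain
   nearly everything, so their stability vectors are uninformative). Stable
   subsets: `any90` = stability > 90% in ≥ 1 method; `median50` / `median90`
   = median stability > 50% / > 90%. Each subset is refit by OLS and
   evaluated with repeated k-fold CV. Method agreement is the Spearman rank
   correlation of stability vectors (average ranks for ties; a constant
   vector has undefined correlations, reported as NaN, never 0).

All losses are on the `1/(2n)·RSS + penalty` scale, so one λ scale is
coherent across the penalized family (`λ_raw-SSE = 2n·λ_here`). The
intercept is never penalized.

## The ten selectors

- **BSLR** — backward stepwise linear regression minimising the Gaussian
  AIC (`2k − 2 ln L̂`, k = slopes + intercept + error variance), starting
  from the full OLS model, removing the covariate whose removal most
  decreases AIC; ties resolve to the lowest column index. Implemented with
  inverse-Gram downdating (O(p²) per step). Requires n > p + 1; on bootstrap
  resamples (≈0.63n distinct rows) aliased columns are dropped via
  rank-revealing pivoted QR before the search, mirroring R's `lm`.
- **MARS** — greedy forward addition of mirrored hinge pairs `(x−t)+`,
  `(t−x)+` (knots at ≤15 quantile-spaced observed values per covariate;
  products with existing terms up to the tuned degree, restricted to the 4
  most recent parent terms), followed by backward deletion by smallest RSS
  increase down to `nprune` terms. Candidate scoring orthogonalises the
  precomputed candidate columns against the growing basis incrementally
  (rank-one updates), so a forward pass is a few dense matrix products.
  Tuned over `nprune` ∈ 2..30 and degree ∈ {1, 2}; one forward pass per
  fold per degree serves every `nprune` via the nested deletion sequence.
- **Lasso / ridge / elastic net** — cyclic coordinate descent on the
  precomputed Gram system with soft-thresholding (ridge: linear shrink),
  an active-set sweep strategy, and warm-started descending-λ paths.
  λ grid: 50 log-spaced points from λ_max down to 1e-3·λ_max (ridge grid
  shifted up, as it never zeroes); α ∈ {0.1,…,1.0}.
- **Adaptive elastic net** — stage 1 is the tuned elastic net; stage 2
  re-solves the elastic-net loss with L1 weights `w_j = |β1_j|^(−γ)`,
  excluding stage-1 zeros (infinite weight); γ ∈ {0.5, 1, 2}.
- **SCAD / MCP** — coordinate descent with the canonical SCAD and firm
  (MCP) thresholding operators. The operators assume unit-scale columns, so
  these two solvers standardise columns to unit second moment internally and
  penalise on that scale (as `ncvreg` does); coefficients are mapped back.
  Warm-started descending-λ paths mitigate nonconvexity; the tuning grid
  uses 30 λ points down to 1e-2·λ_max (the dense unpenalized tail is slow
  and never optimal) with γ ∈ {2.5, 3.7, 5} (SCAD) / {1.5, 3, 5} (MCP).
- **SparseStep** — penalty `λ·β²/(β²+γ²)`, solved by iterative
  majorization (each step a weighted ridge solve) with γ annealed from a
  large start down to the target by factor 3 with two majorization steps per
  level, converging fully at the target γ. Small target γ (default grid
  {1e-4, 1e-3, 1e-2}) makes the penalty an approximate L0 count and the fit
  genuinely sparse — the behaviour of the method's reference implementation.
  Large γ would turn the method into an adaptive ridge that selects
  everything, which is not the design intent; this is why the γ grid sits
  well below the coefficient scale. Final fits additionally restart the
  majorization from hard-thresholded least-squares patterns and keep the
  lowest objective (the loss is nonconvex; continuation alone can land in a
  neighbouring basin ~1% above the optimum). Coefficients below 1e-6 are
  zeroed to define the support. λ acts as a per-covariate price, so its
  tuning grid spans the single-coordinate RSS gains.
- **RBVS** — iterative ranking-based selection: per iteration, 100
  subsamples of 200 rows without replacement; covariates ranked by lasso
  path entry order (residual-update coordinate descent, path to 10% of
  λ_max or 35 entrants — only leading ranks matter; ties by coefficient
  magnitude, then marginal correlation); for each k ≤ 10 the most frequent
  top-k set and its frequency f_k are recorded (f_0 = 1); the accepted size
  maximises f_k/f_{k+1}; accepted covariates are removed and the procedure
  iterates (≤5 times) until the maximiser is k = 0. Final coefficients are
  an OLS refit of the accepted union, and that OLS is what the CV evaluates.

## Synthetic data generator

Real survey datasets of this shape are rarely deposited, so the generator
emulates the structure: covariates drawn as equicorrelated Gaussians within
blocks (`x = √ρ·f + √(1−ρ)·ε`) and independent across blocks; a chosen
fraction dichotomised at the median; continuous covariates centred and
scaled by **two** standard deviations (making a one-unit change a 2-SD
change, comparable to a binary contrast — binaries are centred only);
selected covariates expanded as centred polynomials to power four, each
power standardized and treated as its own covariate; outcome
`y = β0 + X_support·β + N(0, σ)` built on the standardized scale.

The default study-emulating configuration: n=408, 337 base covariates in 29
correlated blocks of 5–20 (ρ = 0.6) plus independent remainder, 20% binary,
six polynomial parents (18 extra columns), two dominant effects (+200, +60
outcome units per 2 SD), four moderate ones (+22, −16, +13, +10), intercept
200, noise SD 75. With those values the OLS fit on the true support attains
a cross-validated R² ≈ 0.63, inside the plausible band for the motivating
study. Signal covariates sit in distinct blocks and are kept continuous so
the coefficient scale is interpretable; the outcome is left unstandardized
because the natural error metric (MAE) lives in outcome units.

What the generator does **not** emulate: non-Gaussian covariate marginals,
heteroscedastic or skewed outcome noise, block structures estimated from a
real questionnaire, missingness (complete data is a precondition), or true
non-linear outcome relationships (the polynomial columns exist, but the
default truth is linear in the standardized columns). Passing tests
therefore demonstrate correct behaviour under a Gaussian, block-correlated,
sparse-linear world — not performance guarantees on any particular survey
dataset. One consequence worth knowing: on a *fixed* realized dataset, a
truly null covariate with a lucky sample correlation is stably selected
under bootstrap (bootstrap resamples inherit the realized correlation).
High stability flags candidates for follow-up; it cannot certify causality.

## Numerical choices

- Coordinate descent: fixed ascending update order, tol 1e-7 on the maximum
  coefficient change, 10 000 sweep cap for final fits; tuning paths use
  tol 1e-4 (they only rank hyperparameters). Non-convergence raises an
  error carrying the last iterate.
- SCAD/MCP single-λ fits run an internal 25-point descending-λ warm-start
  path; the reported fit is that warm-started local minimum.
- Degenerate inputs: zero-variance continuous covariates are dropped with a
  warning at standardization; MARS knots avoid column extremes; empty
  stage-1 adaptive-enet fits return intercept-only with a warning; empty
  stable subsets are skipped with a warning rather than refit.
- Bootstrap resample failures are logged and excluded from the stability
  denominator; more than 10% failures aborts the method.
- Ties: stepwise AIC and MARS pruning resolve to the lowest column/term
  index; tuning ties to the sparser candidate, then first-listed.
- All RNG flows from three named seeds (synthesis, folds, bootstrap);
  per-resample generators are spawned from a SeedSequence, so results do not
  depend on execution order.

## Standard experiment settings

The study-scale experiment (the `selstab.experiment` module and
`scripts/acceptance.py`) runs all ten methods on the default synthetic
dataset with 10-fold × 2-repeat CV for tuning and reporting and B = 100
bootstrap resamples per method — about ten minutes on one CPU. The library
defaults remain 10 × 10 and B = 500 for standalone analyses.

## Known limitations

- MARS interaction search is restricted (recent-parent heuristic, thinned
  knots); degree > 2 is untested and not tuned by default.
- SCAD/MCP coordinate descent is a local method; different λ-path
  granularities can land in different local minima on strongly correlated
  designs.
- RBVS under block correlation can accept an entire correlated block along
  with the true member (the top-k sets of correlated covariates are
  themselves stable); this mirrors the method's known behaviour, not a bug.
- The pipeline is single-process; for B = 500 on study-scale data expect
  roughly an hour end to end.
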