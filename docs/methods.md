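# Methods

`gscover` analyses factorial nutrient-addition experiments in grassland
plant communities in which species genome size (GS, the 1C DNA amount in
pg) is hypothesized to mediate cover responses to nitrogen (N) and
phosphorus (P). This note describes the statistical machinery, the
synthetic experiment generator used to validate it, and the numerical
choices made where the design was genuinely open.

## Genome-size resolution

Each species needs one 1C-value per site. Records come from two source
classes: curated database entries (possibly one per cytotype) and
site-specific flow-cytometry measurements. Resolution applies, in order:
(1) a measured record for the exact (species, site) pair; (2) never
transfer measured values across sites; (3) otherwise the species' minimum
database value — the conservative choice when cytotypes of different
ploidy are listed, because it shrinks rather than inflates any GS effect;
(4) species with no record are reported as unresolved, never silently
dropped. Duplicate measured values for one (species, site) are an error.

Distribution summaries report mean, median, histogram mode, range, and
the max/min fold range. The mode uses bins of configurable width
(default 0.1 pg) centred on multiples of the width, so candidate modes
are round values (0.1 pg, 0.2 pg, …); the bin width is a free parameter
because no canonical value exists for this statistic.

## Community metrics

* **Mean recent cover**: per plot and species, the arithmetic mean
  percent cover over the most recent (up to) three treatment years;
  a species missing from some window years contributes zero for those
  years (absence = zero cover).
* **Δcover**: mean recent cover minus the pretreatment-year cover, in
  percentage points. Recruits enter with pretreatment 0; species lost
  from the recent window enter with recent mean 0. Per plot, Δcover sums
  to the change in total cover.
* **cwGS**: the cover-weighted geometric mean of species 1C-values,
  `exp(Σ w_i ln GS_i)`, with weights the cover shares among species that
  have a resolved GS (the remainder is reported as a per-plot coverage
  diagnostic). Weighting log GS and back-transforming keeps cwGS strictly
  positive — 1C-values below 1 pg make ln GS negative, and a mean taken
  on the ln scale could be ≤ 0, leaving the response ratios below
  undefined. An intercept-only weighted-least-squares fit of ln GS equals
  the weighted mean, so this is also the WLS estimate (unit-tested).
* **ΔcwGS**: natural-log response ratios of cwGS. The *control contrast*
  is ln(plot cwGS / mean cwGS of the site's control plots), computed for
  every plot including controls; the averaging pool can be narrowed to
  the plot's block by configuration. The *temporal contrast* is
  ln(plot cwGS / same plot's pretreatment cwGS).

## Climate axes

Sites carry 19 BioClim-style variables, 11 temperature and 8
precipitation. Variables are z-scored across sites (sample SD). Within
each group a correlation-matrix PCA (eigendecomposition; component signs
fixed by making the largest-magnitude loading positive) selects the
variable with the largest |loading| on PC1 and on PC2 — four axes in
total. An a-priori override replaces the data-driven picks; the pipeline
default override is the canonical quartet: mean annual temperature
(bio1), annual precipitation (bio12), temperature seasonality (bio4),
precipitation seasonality (bio15). The override exists because loading
ranks and prior knowledge can disagree, and the tie-break between them is
a scientific judgement, not a computable rule.

## Phylogenetic comparative methods

Trees are rooted with strictly positive branch lengths (Newick I/O and
pruning via dendropy; pruning collapses degree-2 nodes and sums branch
lengths, preserving patristic distances). The Brownian covariance C has
C[i,j] = depth of the most recent common ancestor, C[i,i] = root-to-tip
distance. Pagel's transform scales off-diagonals: C_λ = λC + (1−λ)diag C.

* **Pagel's λ** maximizes the Gaussian likelihood with mean μ1 and
  covariance σ²C_λ, with μ and σ² profiled analytically and λ searched on
  [0, 1] by bounded Brent iteration (tolerance 1e-6), with both endpoints
  checked so the reported optimum never falls below the boundary
  likelihoods. The p-value is a likelihood-ratio test against λ = 0 on
  χ²(1).
* **Blomberg's K** is the observed MSE₀/MSE ratio (variance about the
  phylogenetic mean over the C-whitened residual variance) divided by its
  Brownian expectation `(tr C − n/(1ᵀC⁻¹1))/(n−1)`; E[K] = 1 under
  Brownian evolution. The p-value is a one-sided tip-label permutation
  test (default 1000 permutations, +1 correction, mandatory seed); the
  count and sidedness are package defaults, declared rather than
  canonical.
* **PGLS** regresses a tip trait on a group factor with residual
  covariance σ²C_λ, λ fixed at 1 by default (ML estimation optional),
  and reports the F-test of the factor against the intercept-only model.

All estimators use dense matrix algebra; the trees here have at most a
few hundred tips and dense factorizations keep every statistic checkable
against brute-force likelihood oracles (the unit tests compare the
profiled likelihood to direct numerical maximization of the multivariate
normal density).

## Mixed-model inference

All models are Gaussian LMMs `y = Xβ + Σ_k Z_k u_k + ε` with
`u_k ~ N(0, σ_k² G_k)` and iid residuals, estimated by REML (ML
optional). Variance ratios are profiled via the Woodbury identity —
after one pass of cross-products the per-iteration cost depends only on
the number of random levels — and optimized deterministically
(bounded Brent for one component; L-BFGS-B on log-ratios from a fixed
start, with a Nelder-Mead fallback, for several). Singular fits
(a component at the boundary) are flagged with a warning, never hidden.
Fits are bit-reproducible given fixed inputs.

Fixed-effect tests are marginal (Type-III-style) Wald F-tests with
Satterthwaite-style denominator degrees of freedom: the derivative of
the coefficient covariance with respect to the variance parameters is
taken by central finite differences, and the variance-parameter
covariance is twice the inverse finite-difference Hessian of the REML
deviance. Multi-df hypotheses are eigen-split into independent 1-df
contrasts whose dfs are pooled in the usual way. Marginal R² is the
fixed-effect linear-predictor variance over the total (fixed + random +
residual) variance — the standard formulation for mixed models, adopted
because no formula-level specification exists for this quantity.

* **Plot-level models** regress a ΔcwGS response ratio on the nutrient
  factors with random intercepts for site and block-within-site
  (intercepts only — no random slopes). The treatment model feeds Tukey
  HSD contrasts over the four factorial cells (studentized-range
  p-values at per-contrast Satterthwaite df; compact letters by
  insertion–absorption). The climate model adds the four z-scored
  climate axes and all nutrient × climate two- and three-way
  interactions — 19 single-df fixed-effect rows.
* **The species-level phylogenetic mixed model** regresses Δcover on
  `N * P * log(GS)` (all two- and three-way products) with a species
  random effect whose covariance is σ_p²A, A the phylogenetic
  correlation matrix (C pruned to the observed species and scaled to
  unit diagonal). By default the model also includes an iid species
  intercept — phylogenetic and non-phylogenetic species variation are
  distinct sources and conflating them biases σ_p² — and random
  intercepts for block-in-site and plot. The design terms matter:
  cover changes of species sharing a plot (and plots sharing a block)
  shift together, and treating those shifts as independent noise
  distorts the precision of treatment contrasts; with them the null
  rejection rate of the GS × N test sits at its nominal 5%
  (see the validation experiments). This model is a deliberate
  frequentist re-cast of a Bayesian phylogenetic regression: REML
  variance components, GLS coefficients, and Wald t intervals with
  Satterthwaite df replace MCMC. With weak priors the point estimates
  are expected to be close, but equivalence with a posterior is not
  claimed, and every fit carries that note.

Post hoc plot-level models (plot age, pretreatment soil N and P) are
ordinary term lists over the same engine; no dedicated code path exists.

## The synthetic experiment generator

The generator emulates a coordinated nutrient-addition network: by
default 27 sites, 3 blocks per site (2–6 supported), each block holding
the four factorial cells (control, N, P, N+P) on randomly assigned
plots; one pretreatment year plus 3 treatment years; a 200-species pool
on a Yule phylogeny (birth rate 1) carrying ln GS as Brownian motion
(rate 0.2 on a λ = 0.9 transformed tree, root ln 1.5 pg) — giving a
right-skewed 1C distribution spanning roughly 0.2–20 pg with strong
phylogenetic signal, as real grassland floras show. Functional groups
occupy contiguous clades of the tree (35% grass, 30% perennial forb,
15% annual forb, 8% legume, 7% geophyte, 5% woody; a quarter of grasses
C4), so group GS differences emerge from the phylogenetic signal rather
than an added offset.

Species baseline covers are Gamma(2) with mean 8% (a typical per-species
cover where plot totals exceed 100% for overlapping canopies; the
overall scale is a configuration knob, since the distribution of total
cover is not canonical). The expected cover change of species *i* on
plot *p* is

    [β + β_MAP·z(MAP) + β_Tseas·z(TSeas)] · ln GS_i · N_p  (+ P terms)

plus site, block, and species random intercepts (SD 0.5, 0.3, 0.5) and
per-year observation noise (SD 1.5), with covers truncated at zero —
cover change is generated on the percentage-point scale so the estimand
matches the species-level model's. Defaults: β = 1 percentage point per
ln pg, β_MAP = −0.5 and β_Tseas = −0.3 per SD of the site climate
variable, P-effects zero. Climate draws 19 variables from two correlated
blocks (within-group correlation ≈ 0.7, between ≈ 0.2) on plausible
natural scales. All four generators draw from per-module RNG streams
derived from one master seed; identical seeds give bit-identical tables.

What the generator does *not* emulate: within-plot spatial structure,
colonization/extinction dynamics beyond cover change, non-Gaussian cover
noise (beyond zero-truncation), fencing or potassium treatments, and
real raster climate. Passing validation therefore demonstrates that the
estimators recover the truth under this generative model, not that the
field data satisfy its assumptions.

## Validation experiment sizes

The replicated experiments (`gscover.validation`, also run by
`scripts/acceptance.py`) use fixed problem sizes chosen to keep a full
sweep desk-scale:

* λ recovery: 100 trees × 200 tips per true λ ∈ {0, 1};
* K calibration: 200 Brownian simulations × 200 tips;
* GS × N slope recovery and interval coverage: 200 replicates at
  10 sites × 2 blocks, 80-species pool;
* type-I error: 500 null replicates at 8 sites × 2 blocks, 60-species
  pool;
* directional pattern: 100 replicates at the full 27 sites with 6 blocks
  per site — the top of the design's replication range, chosen because
  sign determination of the N × precipitation interaction needs the full
  between-site climate gradient and maximal within-site replication.

## Numerical choices and degenerate inputs

Zero-SD climate columns, constant traits, empty control sets, plots with
no GS-bearing cover, rank-deficient designs, duplicate measured GS
values, and species absent from the tree all raise typed errors naming
the offender; nothing is silently dropped except plots lacking
treatment-epoch data, which are excluded with a logged warning.
λ tolerance is 1e-6; REML convergence tolerances are 1e-12 (relative
criterion) with variance ratios bounded to e^±14; Satterthwaite df fall
back to the residual df when the finite-difference information matrix is
not usable (e.g., hard boundary fits), and are capped at the residual df.
PCA signs are fixed deterministically; Tukey letters are assigned in
ascending order of group means.

## Known limitations

Wald intervals and Satterthwaite df are approximations; with few sites
the plot-level models' climate main effects have low denominator df.
The zero-truncation of covers makes the Gaussian model mildly
misspecified at low baseline cover. K's permutation p-value resolution
is bounded by the permutation count. The PGLS implementation handles a
single categorical predictor (the use here), not general designs.
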