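# Methods

This note records the models behind `nichedyn`, the defaults that matter,
the numerical choices that were genuinely open, and what the synthetic
validation does and does not establish.

## Niche comparison in ordination space

Each species × realm comparison gets its own climate space: a PCA of the
correlation matrix of all cells of both regions (presences and background
together), keeping two axes. Working per comparison rather than in one
global space follows the standard niche-overlap framework; with the default
two synthetic climate variables the ordination is a rotation and the
retained variance is 100%, so the analytic truth is exact. A
`variance_check` flags comparisons whose two axes capture ≤ 75% of the
variance when more variables are supplied; such comparisons are logged, not
dropped.

Occurrence density is a separable Gaussian kernel density on an R×R grid
(R = 100) spanning the pooled scores of both regions plus one bandwidth per
side, so both regions share bin edges and all mass is representable.

**Bandwidth (default 0.5 × Silverman).** The per-axis normal-reference rule
`h = σ n^(−1/6)` assumes an untruncated Gaussian cloud. Realized occupancy
in this problem is truncated — by region envelopes and by colonization
masks — and the reference rule then oversmooths, pushing the estimated
occupied set several bandwidths past a hard edge. The package therefore
uses half the reference bandwidth by default (`bandwidth_factor`
parameter). Validation against the analytic oracle (10 seeds × 4 scenario
types at 1000 presences per range) keeps all expansion/unfilling errors
within ±0.09; the reference bandwidth leaves the half-mass truncation
scenario ~0.17 too low. Bandwidths are floored at half a grid-cell width,
below which the kernel underflows between cell centers.

**Availability correction (default on).** Occupancy is occurrence density
divided by background density, separating where the species sits in climate
space from what was available. The corrected density is clipped to cells
whose background *cell-count histogram* is positive: outside the
background's own support, dividing the occurrence-kernel tail by the
background-kernel tail would manufacture occupancy from availability
artefacts. A floor of 1e-12 on the divisor avoids 0/0 at support
boundaries. The uncorrected variant is switchable.

**Occupied set (default mass quantile q = 0.05).** Binarizing occupancy at
strict density positivity is ill-posed for a float64 Gaussian kernel: the
tail stays positive for ~38 bandwidths beyond the last presence (until
`exp` underflows), so the "occupied" set would depend on floating-point
underflow and swallow the grid. The package instead takes the occupied set
as the cells holding the top 1 − q of occupancy mass, with q = 0.05 —
small enough to keep 95% of the niche, large enough to shed the kernel
fringe. The same function defines the occupied sets of the analytic
oracle, so estimator and truth share one support definition; q = 0 recovers
strict positivity, which is the right semantics for hand-built toy grids
and is used in the brute-force equivalence tests.

**Analog climates.** The indices are computed only where both backgrounds
offer the climate. The mask is the intersection of the two backgrounds'
supports on the grid, taken from the background cell-count histograms
(count > 0 at quantile 0) rather than the smoothed densities, whose kernel
bleed would extend the available envelope by several bandwidths. A
nonzero analog quantile shrinks the mask monotonically.

**Indices.** With binary occupancies `o_nat`, `o_ali` and the analog mask
`m`: `E = Σ_{m ∧ o_ali ∧ ¬o_nat} z_ali / Σ_{m ∧ o_ali} z_ali`, `S = 1 − E`,
and `U` symmetrically with the roles of native and alien swapped. `E + S
= 1` holds exactly by construction. Comparisons with no occupancy mass
inside analog climates are undefined and dropped with a logged reason,
mirroring the minimum-presence filter (≥ 5 presences per range for niche
analysis, ≥ 20 native presences for suitability models). Overlapping
native/alien cells are assigned to the alien range before analysis.

**Novelty.** Every alien-background cell is scored against the native
background: `NT1 = Σ_i min(x_i − min_i, max_i − x_i, 0)/(max_i − min_i)`
(≤ 0, 0 iff inside all univariate ranges) and, only where `NT1 = 0`,
`NT2 = D²(x)/max_ref D²` (Mahalanobis against the native mean and
covariance, self-normalized by the native maximum). A cell is novel iff
`NT1 < 0` or `NT2 > 1`; a comparison is flagged when novel cells exceed 5%.

## The synthetic world

Two rectangular regions carry linear climate gradients with Gaussian noise
(SD 0.1 climate units); their extents are offset so envelopes overlap but
are unequal (native variable-1 span [0, 10], alien [4, 14]; analog
climates [4, 10]). The virtual species occupies climate space with
probability ∝ exp(−½ (c − μ)' Σ⁻¹ (c − μ)), μ = (6, 5), Σ = 0.8² I, placed
so the niche sits inside the analog window with room for both mechanisms
of change. Presences are cells drawn *without replacement* with those
weights (one presence per cell, like rasterized range maps), via the
Gumbel-top-k equivalence. Unfilling is induced geometrically (a mask on
the alien cells), expansion by shifting the alien optimum by δ — the two
mechanisms the indices are meant to separate.

The analytic oracle integrates the truncated occupancy Gaussians over a
≥ 400×400 climate-space grid, using the same index formulas and the same
mass-quantile support rule. Refining the grid 400 → 800 changes values by
< 1e-3 except when a mask edge passes through the density mode, where mass
discretization converges at first order (< 0.01); the worked-example
half-mass mask sits exactly on the mode, giving a truth of 0.496 rather
than 0.500 at the default 500×500 resolution.

What the generator does *not* emulate: spatial autocorrelation and
dispersal kinetics (masks are static), climate collinearity structure
beyond two variables (k > 2 is supported but the default keeps truth
exact), observation error in presences, and realm-level heterogeneity of
climate availability. Passing tests therefore show the estimators are
correct and well-calibrated under known geometry — not that real range
maps meet these assumptions.

**Driver tables.** 337 species-by-realm rows; raw covariates have
realistic skew (log-normal sizes/counts/rates, Bernoulli insularity,
bounded community similarity; a 0.4 latent correlation between range size
and richness). Link-scale effects apply to the transformed + standardized
covariates — the same preparation the inference stage performs, so
recovery is attenuation-free. Expansion: Bernoulli(logit⁻¹(−0.9 + Xβ_e +
realm intercept)), realm SD 0.3, supported effects −0.8 (range size),
−0.6 (community similarity, human disturbance), +0.8 (introduction
effort). Unfilling: the √-scale response is Beta(μφ, (1−μ)φ) with
logit⁻¹(1.0 + Xβ_u + realm + order intercepts), SDs 0.3, φ = 12, effects
+0.6 (disturbance), +0.5 (range loss), −0.8 (effort), −0.5 (residence
time); the stored unfilling value is the square of the draw.

## Mixed models

Binomial-logit and beta-logit (mean-precision, log-precision link)
regressions with independent random intercepts are fitted by maximum
likelihood with a Laplace approximation: penalized Fisher scoring jointly
maximizes over fixed effects and random intercepts at given variance
parameters (profiling the fixed effects at the joint mode, as lme4's
default does), the marginal likelihood is the joint maximum plus the
Gaussian normalization minus half the log-determinant of the
random-effects Hessian, and the log-SDs are optimized by Nelder-Mead. The
beta precision φ is profiled at the joint mode by interleaved Newton
steps. As all SDs → 0 the approximation collapses exactly to the
fixed-effects likelihood (verified to 1e-6), and fits agree with
`lme4::glmer` / `glmmTMB` reference estimates to ~0.01 on coefficients on
a frozen fixture. Fixed-effect SEs come from the inverse of the full
penalized information; trigamma is evaluated by a recurrence + asymptotic
series (scipy's zeta-based polygamma dominated the fit time).

A fit is *singular* when any random-intercept SD estimates below 1e-4 on
the link scale; the fallback plan drops singular terms, then tries a
single species intercept, then none. Gaussian responses go through
statsmodels MixedLM (ML) behind the same interface.

**All-subsets inference.** All 2^p additive fixed-effect subsets keep the
global random structure. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting
fixed effects, random-effect variances, and φ. An
observations-per-variable guard warns below 10 per covariate. Ranking,
then removal of models whose fixed-effect set strictly contains that of a
no-worse simpler model, then the ΔAICc < 4 cut define the confidence set;
full averaging substitutes zero for absent coefficients, unconditional
SEs follow `Σ w_i √(SE_i² + (β_i − β̄)²)`, intervals use the normal 1.96
quantile (the t-quantile alternative was considered and rejected for
consistency with the weights' large-sample justification), and importance
is the summed weight of models containing the term.

*Screening profile.* Variance parameters move little between fixed-effect
subsets, so the 2048 screening fits hold them at the global model's
estimates (fixed effects, random modes, and φ still fully optimized);
every confidence-set member is then refitted with a tight variance-
parameter optimization before weights and averages are computed. On test
tables this changes averaged estimates by ≲ 0.01 and cuts the dredge from
minutes to seconds.

*Open boundary handling.* The beta likelihood is undefined at 0/1;
responses touching the boundary are shrunk by `(y(n−1) + 0.5)/n`
(Smithson-Verkuilen), applied only when boundary values occur.

*Expansion binarization.* The data-driven threshold is exact 1-D 2-means
(all splits of the sorted values enumerated), returning the centroid of
the denser cluster; ties resolve to the near-zero cluster, and the binary
response is value > threshold.

## Suitability ensembles and transfer

Native models: boosted classification trees on the leading axes (up to 4,
capped at the number of climate variables) of a PCA of the pooled
two-region background. 200 trees, depth 2, learning rate 0.1, bag
fraction 0.5 — only the tree count is externally constrained; the rest
are the package's shallow-boosting defaults, exposed as parameters. Five
1:1 pseudo-absence sets within the native background, three stratified
70/30 calibration/evaluation splits each; replicates with holdout AUC
> 0.7 enter the averaged projection. Projections are clamped: cells whose
scores leave the per-axis training range are removed from every
evaluation set.

Evaluation against alien presences: rank-based AUC (ties ½), TSS
maximized over observed thresholds (smallest maximizer reported, with a
1e-12 tolerance absorbing float ties), Sensitivity/Specificity in percent
at the max-TSS threshold (a fixed 0.5 alternative is available — the
threshold convention behind published sensitivity medians is not
standardized), and the Continuous Boyce Index with 101 moving windows of
width range/10 (windows without background skipped; fewer than two valid
windows → missing). Individual CBI replicates are noisy because the
windows overlap heavily; null behaviour is therefore assessed on
Monte-Carlo means. Pseudo-absences follow a tiered fallback: 1:1 from
unoccupied alien-background cells; else 5% of all alien-background cells;
else 1:1 from unoccupied cells of all regions (a 5% target that exceeds
the available unoccupied cells also falls through to the last tier).

Transferability models: AUC, TSS and CBI are mapped to [0, 1] (the two
correlations via (x+1)/2), arcsine-√ transformed, and fitted with Gaussian
mixed models with realm and native-sample-size-quintile intercepts;
Sensitivity and Specificity are binarized at their first quartile and
fitted with binomial mixed models, the Sensitivity model dropping random
effects when singular.

**Directional scenarios.** The validation suite contrasts matched
replicates: conserved niche, optimum shift (δ = 2 climate units ≈ 2.5
niche SDs), and *patchy colonization* — a climate-matched core plus a
small marginal satellite patch. The patchy geometry matters: a mask
through the niche optimum removes occupancy evenly across suitability
classes and leaves the rank-based Boyce index unchanged, while a pure
fringe mask lowers sensitivity. Matched-core-plus-satellite reproduces
both published signatures at once (sensitivity up through well-matched
presences, CBI down through unoccupied high-suitability classes and
marginal-climate occupancy).

## Problem sizes

Niche-metric recovery runs at 1000 presences per range on 40 000-cell
regions (tolerance ±0.10 against the oracle). Driver-effect recovery runs
100 replicates for the binomial expansion response — where coefficient SEs
(~0.15 at n = 337) make power the live question — and 20 replicates for
the beta unfilling response, whose coefficient z-statistics of 12–20 make
recovery effectively certain; the success criterion is ≥ 90% per effect in
both. The directional transfer suite uses 20 matched triplets at 300
presences per range. The pipeline demonstration scripts default to the
same sizes, scaled down where a stage is illustrative.

## Known limitations

- Index estimates carry O(h) support bias at hard truncation edges; the
  half-bandwidth default keeps it within ±0.1 at n = 1000 but small
  samples near the 5-presence minimum are qualitative only.
- The Laplace approximation profiles fixed effects at the joint mode;
  against adaptive-quadrature references this attenuates binomial
  coefficients by ~1–2% at ~30 observations per group.
- The beta precision is profiled rather than treated as an outer
  parameter; its estimate differs from glmmTMB's by ~2% on test fixtures.
- CBI has high replicate-level variance under the conventional
  overlapping-window scheme; directional conclusions use medians over
  replicated scenarios.
- Cell identity is opaque: no spatial autocorrelation, dispersal, or
  geometry enters the analysis except through the sampling masks.
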