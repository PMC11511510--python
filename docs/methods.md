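# Methods

`metsel` implements the statistical evaluation of a replicated field trial of
many genotypes (accessions) grown in a randomized complete block design that
is repeated over years — the layout used to screen quinoa germplasm for
adaptation to temperate, long-day environments.  This note records the models,
the numerical choices, and what the synthetic-data generator does and does not
emulate.

## Models

### Single-trait evaluation (fixed genotype effects)

For one trait, the plot observation of genotype *i* in year *j* and block *k*
is modeled as

    y_ijk = mu + g_i + a_j + (ga)_ij + b_k + e_ijk

with fixed genotype (g), year (a) and genotype-by-year (ga) effects, a random
block effect b_k ~ N(0, sigma2_b), and residuals that may be heteroscedastic
by year and correlated across years within a genotype x block cell.  The cell
is the repeated unit of a re-randomized two-year trial, and year-specific
residual variance is the norm when growing conditions differ (here, a much
wetter second season).  The engine tries the correlated heteroscedastic
structure first and falls back to heteroscedastic-only and then iid when a
richer structure is not estimable or does not converge; the chosen structure
is logged and reported.

This fit supplies the Wald-F analysis of variance per fixed term (residual,
i.e. containment, denominator degrees of freedom — at 288 plots and balanced
data the Kenward–Roger/Satterthwaite refinement changes nothing material and
is out of scope), a conditional pseudo-R² (squared Pearson correlation of
observations with fitted values that include the predicted random effects),
and the adjusted genotype x year cell means that feed standardization.  Under
balance those cell means equal arithmetic means for any variance components;
this is asserted in the tests.

### Variance components and heritability (all effects random)

Variance components come from the all-random model

    y_ijkl = mu + g_i + a_j + (ga)_ij + b_k + (ba)_kj + c_l + e_ijkl

with independent random genotype, year, genotype x year, block, block x year
and column effects and iid residuals.  Columns are modeled as nested in
year x block (four per block): the trial sows each block in four columns, so
a flat column numbering across the whole trial would conflate physically
distinct positions.  Broad-sense heritability on an entry-mean basis is

    h2 = sigma2_g / (sigma2_g + sigma2_gxy / J + sigma2_e / (J K))

for J years and K blocks per year (divisors 2 and 6 at the default design).
Year, block, block x year and column components shift all entry means equally
and cancel from the entry-mean variance.  The divisors are parameters, not
constants, so other designs reuse the formula; no standard errors for h² are
produced.

### REML engine

Both models are special cases of y ~ N(X beta, V) with
V = sum_f sigma2_f Z_f Z_f' + R.  The restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ] + const,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1

is maximized over log variances (and atanh of the residual cross-year
correlation) with L-BFGS-B and the analytic gradient
dl_R/d theta = -1/2 [tr(P dV/d theta) - y'P (dV/d theta) P y], followed by a
few Newton steps with a finite-difference Hessian of that gradient: the
profile is extremely flat along components with few degrees of freedom (the
year term has one), and the polish sharpens those last digits so that on
balanced data the estimates agree with closed-form expected-mean-squares
(Henderson method 3) estimators to better than 1e-6 relative error — the
engine's primary oracle, computed independently in the test suite.

Zero boundaries are routine, not exceptional (the published component table
has an exactly-zero year variance for five of twelve traits).  A component
whose estimate collapses below 1e-7 of the response variance is removed, the
remaining components are refit, and the component is reported as exactly zero
with a boundary flag.  Dense Cholesky factorizations are used throughout;
at n = 288 observations a full fit costs well under a second.

Fixed effects use reference coding (first genotype, first year, in order of
first appearance in the data).  All reported quantities — cell means,
contrasts, ANOVA — are coding-invariant.

## Contrast families and multiplicity

Two families per trait:

* **Grand-mean differences (GMD).**  Within each year, each genotype's cell
  mean minus the average of all genotype cell means.  Estimates sum to zero
  by construction, and under balance the t statistics are equicorrelated with
  rho = -1/(m-1) (asserted as an internal check).
* **Year contrasts.**  Each genotype's second-year mean minus its first-year
  mean.  A genotype whose adjusted p-value is not below 0.05 is flagged
  *stable*.

Family-wise adjustment is single-step max-|t|: adjusted p_i is the
probability that the maximum absolute statistic of the family exceeds |t_i|
under the joint multivariate t with the estimated correlation of the
statistics.  This probability is computed by seeded Monte Carlo (default
100,000 draws; the contrast correlation matrix may be singular, which the
eigenvalue-based sampler handles directly).  Adjusted p-values are clipped
from below at the raw p-value, a single-hypothesis family returns the raw
two-sided t p-value exactly, and Sidak/Bonferroni are available as
closed-form conservative fallbacks.  For the equicorrelated case the test
suite checks the sampler against an independent quadrature oracle over the
shared latent factor.  Significance stars follow the 0.05 / 0.01 / 0.001
ladder.

Pearson correlations are computed separately per year, by default on
per-accession means (several traits are scored once per plot, making
plot-level correlation needlessly noisy; the aggregation level is an
option).  Confidence intervals use the Fisher z transform.

## Selection index

The index of genotype i in year j is I_ij = sum_m h2_m z_ijm over the six
index traits (thousand-kernel weight, seed yield, days to flowering, plant
height, downy mildew susceptibility, saponin content).  z_ijm standardizes
the adjusted cell means within year across genotypes (n-1 SD) and flips the
sign of lower-is-better traits, so larger I is always better.  One two-year
h² per trait weights both years identically.  Ranks are per year, ties broken
by genotype label order.

The index is then treated as an additional trait: plot-level index values are
built by applying the same per-year center/scale (an affine map) to plot
values, which makes the plot-level index's cell means equal the index
computed from adjusted means, and the full single-trait machinery — model
fit, GMD contrasts, year contrasts — applies to it unchanged.  Stability of a
genotype means a non-significant year contrast of its index.

The final selection is a scored shortlist rather than a formula fixed by
theory, so the rule is explicit and auditable: a trait counts for a genotype
when its GMD is significant and favorable in at least one year and never
significantly unfavorable in either year (cross-year consistency); genotypes
are ranked by number of counted traits, then by total significant favorable
(trait, year) pairs, then stability, then mean index rank, then label order.
Each selected genotype carries a rationale string naming its counted traits.

## Synthetic trials

No plot-level data from the motivating study are public, so the generator is
first-class: it draws every effect of the all-random model independently from
Normal(0, sigma2) — except genotype effects, which are drawn jointly across
traits from a genetic correlation matrix — and supports year-heteroscedastic
residuals correlated across years within genotype x block, missing-value
injection, planted genotype shifts for recovery studies, and per-trait
rounding grids and clamp bounds applied after effect summation.

Defaults reproduce the published study conditions: 48 genotypes x 2 years x
3 blocks, four columns per block, 13 traits with the published genotype /
year / genotype-by-year / residual variances and trait means.  Three
components the study does not tabulate are set once as a small positional
nuisance (block, block x year and column variances each 10% of the trait's
residual variance).  Days to maturity, which appears in the published
correlation analysis but not the component table, is included with mean 112
days, sigma2_g = 15, sigma2_gxy = 6, sigma2_e = 2 and genetic correlation 0.8
with days to flowering.  The default genetic correlation matrix is built from
loadings on two latent factors (earliness, yield potential), which guarantees
positive semidefiniteness while reproducing the published sign pattern
(earliness traits mutually positive and tied to height and saponin; yield
positively tied to kernel weight and panicle density, negatively to mildew
and lodging).  Column assignment is re-randomized per year x block, unlike
the physical trial, which grouped entries by maturity; randomization keeps
column effects estimable apart from genotype in simulation.

What the generator does not emulate: spatial row-column autocorrelation,
non-Gaussian trait distributions (scores are clamped Gaussians, not ordinal
processes), multi-location structure, and maturity-clustered column
assignment.  Passing tests therefore demonstrate correctness of the
estimation and selection machinery under the stated Gaussian mixed model, not
robustness to field-spatial artifacts or heavy-tailed traits.

## Numerical and design choices

* All simulation randomness derives from one master seed via deterministic
  substreams (layout, genotype effects, one per trait, missing-data mask);
  identical seeds give bit-identical datasets.  Monte-Carlo p-values take an
  explicit seed.
* Optimizer bounds confine log variances to [1e-8, 1e6] x the response
  variance; the residual correlation is optimized on the atanh scale within
  [-5, 5] (|rho| <= 0.9999).
* A tight `ftol` can abort the L-BFGS-B line search at the optimum with an
  "abnormal" status; the fit is accepted as converged when the projected
  gradient is below 1e-3, and the Newton polish then reduces it further.
* Degenerate inputs raise explicit errors: all-zero variance components in
  the heritability formula, zero within-year SD in standardization, zero
  variance in correlation pairs, single-year data in models with a
  genotype x year term, duplicate plot rows on ingest.
* Percent traits are stored on the 0–100 scale, score traits on their
  published 1–9 / 1–5 scales, saponin as afrosimetric foam-column height in
  mm, yield in t/ha.
* The published h² column is used for index weights when reproducing the
  published weight total (0.86 + 0.85 + 0.78 + 0.70 + 0.46 + 0.51 = 4.16);
  pipeline runs on data estimate h² from the data.  Two published h² values
  (thousand-kernel weight, panicle shape) disagree at 2 dp with the value the
  formula gives from the published components — consistent with the
  published h² having been computed from unrounded components — and the test
  suite documents both exceptions rather than asserting them.

## Problem sizes used in validation

Validation simulations run at the study's own design size (48 x 2 x 3, 288
plots): 200 replicate trials for variance-component and heritability
recovery, 1000 null trials for family-wise error calibration of the
grand-mean procedure, and 50 planted-signal trials for selection recovery;
oracle-equivalence fixtures use 4–8 genotypes where closed-form estimators
are available.  These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances while keeping the whole suite desk-scale.

## Known limitations

* Containment df everywhere; no Kenward–Roger/Satterthwaite small-sample df.
* No spatial covariance models, no multi-trait REML, no Bayesian fitting.
* The heritability-weighted index is a phenotypic index; no economic-weight
  (Smith–Hazel) or desired-gains construction.
* Stability is the year-contrast notion only — no Eberhart–Russell or other
  multi-environment stability statistics.
* h² is reported without uncertainty.
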