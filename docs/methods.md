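# Methods

## Problem and data

A closed population of unknown size N (all incident cases of a cancer in a
region and year) is sampled by T incomplete lists ("sources": a
histopathological registry, hospital multidisciplinary team meetings, a
screening programme).  The data are the capture histories of the n observed
individuals — the binary vector of which lists recorded each case — or
equivalently the counts of the 2^T − 1 non-empty capture patterns.  The goal
is the number of cases missed by every list, hence N and each list's
completeness 100·n_list/N̂.

Two failure modes dominate applied work: *dependence* between lists and
*capture heterogeneity* between individuals (severe, metastatic cases are
over-represented in clinical lists; screen-detected cases in the screening
list).  Heterogeneity induces apparent dependence even between causally
unrelated lists, and with only three lists the two are confounded.  The
package therefore implements three complementary estimator families and the
conversions between their data representations.

## Bayesian M0/Mt/Mh/Mth with model averaging (`crcapture.bayes`)

Capture probabilities follow

    logit(p_it) = μ + α_t + γ_i,   γ_i ~ N(0, σ²_γ)  i.i.d.,   Σ_t α_t = 0,

and the four models M0/Mt/Mh/Mth arise by switching the episode effects α
and the heterogeneity variance σ²_γ on or off.  Behavioural (trap-response)
models are deliberately out of scope: epidemiological lists have no capture
order, so a recapture effect is meaningless.  The likelihood of the capture
matrix x for a population of size N ≥ n is

    f(x | θ, γ) ∝ N!/(N−n)! · Π_t Π_i p_it^{x_it} (1−p_it)^{1−x_it},

with x_it = 0 for the N − n never-observed individuals.

**Priors.**  μ ~ N(0, 10²); the T−1 free components of α ~ N(0, 10²) with
α_T = −Σ α_k (the sum-to-zero constraint resolves the μ/α confounding and
keeps μ interpretable as the mean logit capture rate); σ_γ ~ U(0, 10); model
indicator uniform over the admitted model space (independent probability 0.5
per effect).  N carries the uniform prior on {0, …, M_aug} induced by data
augmentation with an inclusion probability ψ ~ U(0, 1); the ceiling defaults
to M_aug = max(5n, n+200) and a warning is raised whenever ≥ 1% of kept
draws sit on the ceiling.  All of these are configuration fields of
`SamplerConfig` and are echoed into every run report.

**Sampler.**  The individual effects are integrated out of the likelihood
rather than sampled: given θ, individuals are i.i.d., so only the marginal
probability of each *distinct* capture pattern is needed, a one-dimensional
Gauss–Hermite integral (31 nodes by default; at σ_γ = 0 the rule is exact
and reduces to the plain product, which is also how the Mh → M0 reduction
property holds to machine precision).  This choice has two consequences:

* N has a closed-form full conditional.  With the uniform induced prior,
  N − n | rest ~ NegBin(n+1, 1−p₀) truncated at M_aug, where p₀ is the
  marginal probability of an all-zero history; it is drawn exactly each
  sweep by inverse-CDF, so N mixes in one step.
* The between-model moves are low-dimensional.  One time toggle and one
  heterogeneity toggle are attempted per sweep; toggling an effect on
  proposes its parameters from their priors (T−1 α components, or σ_γ),
  giving a reversible-jump acceptance ratio equal to the marginal likelihood
  ratio (prior and proposal densities cancel, Jacobian 1).  An explicit
  per-individual γ sampler was rejected at design time: a prior-draw toggle
  would then have to propose thousands of γ_i jointly and its acceptance
  probability vanishes, so the chain could never enter the heterogeneity
  models it is supposed to weigh.

Within a model, μ, each free α component, and log σ_γ take random-walk
Metropolis steps whose scales adapt toward 20–50% acceptance during burn-in
only (frozen afterwards, so the kept chain is a fixed-kernel Markov chain
and replay under one seed is bit-identical).  The explicit-γ likelihood of
the display above is still provided (`log_likelihood`) and is verified
against a scalar brute-force product in the tests.

**Summaries.**  Model posterior probabilities are visit frequencies; the
model-averaged posterior of N is simply the pooled kept draws; per-model
summaries condition on the visited subsets.  Intervals are highest-posterior-
density intervals: the shortest window containing the requested mass of the
empirical distribution (computed by `arviz.hdi`, cross-checked in the tests
by exhaustive window search).  The Monte-Carlo standard error of the mean
uses the effective sample size from `arviz.ess`.

**Default schedule.**  25 000 kept iterations after 5 000 burn-in, matching
the published analysis of the bundled tables; covariate-expanded histories
converge more slowly and 10 000 burn-in is recommended there.

**Oracle.**  `grid_posterior_oracle` computes the posterior of N for the
no-heterogeneity models by direct summation of likelihood × prior over a
(μ, α) grid and the N range — an independent code path used to bound the
sampler's total-variation error on toy instances (n ≤ 30, T ≤ 3).

## Log-linear models (`crcapture.loglinear`)

For T = 3 the hierarchical family has eight members, from the saturated
model with all three pairwise interactions down to mutual independence; the
three-way term is never included because it would leave the unobserved cell
unidentified.  Each model is a Poisson GLM on the 7 observed cells (fitted
with statsmodels); because the all-zero cell's design row is the intercept
alone, the projection is x̂₀₀₀ = exp(θ̂) and N̂ = M + x̂₀₀₀.  The saturated
projection has the closed form x̂₀₀₀ = x₁₁₁x₁₀₀x₀₁₀x₀₀₁ / (x₁₁₀x₁₀₁x₀₁₁),
kept as an independent check on the iterative fit.

**Confidence intervals.**  N̂ ± 1.96·√(x̂₀₀₀ + x̂₀₀₀²·Var̂(θ̂)) — the Poisson
prediction variance of the unobserved cell plus the delta-method estimation
variance.  Several interval constructions were candidates (log-normal on
x̂₀₀₀, profile likelihood); this Wald form was adopted because it reproduces
the intervals published for the bundled tables to within one case in 14 of
16 rows, so it is evidently the construction behind them.

**Selection.**  Stepwise descent from the saturated model: every currently
included interaction is tentatively dropped, the nested deviance difference
G²(reduced) − G²(current) is referred to χ² on the df difference, and the
drop with the largest non-significant p-value is taken (ties broken by the
fixed term order HR*MTM, HR*CSP, MTM*CSP); descent stops when every removal
is significant at α (default 0.05).  G² uses 0·log 0 ≡ 0.  A zero observed
cell that empties an interaction margin makes that term inestimable; those
cells get a 0.5 continuity correction with a warning (the bundled tables
contain no zeros, so this never triggers on shipped data).

## Lincoln–Petersen and dependence screening (`crcapture.petersen`)

The two-list estimator is the plain N̂ = n₁n₂/m with variance
n₁n₂(n₁−m)(n₂−m)/m³ and a normal 95% interval; Chapman's small-sample
correction is available behind a flag (the plain form is the default because
it reproduces the published pooled estimates and intervals for the bundled
tables exactly).  A zero overlap raises an error that points at pooling or
Chapman.  `hypergeometric_mle` provides the exhaustive integer MLE as an
independent cross-check (it agrees with ⌊n₁n₂/m⌋ within one).

Dependence between a pair of lists is screened by the odds ratio of their
capture indicators with a 95% Woolf (log-OR) interval.  The 2×2 table is by
default restricted to cases *present in* the third list — among three
conventions (present / absent / marginal) this is the one that reproduces
the published odds ratios for the bundled tables, and the convention is
recorded in every result object.  Zero cells get the Haldane–Anscombe 0.5
correction.  A significant pair is pooled by union (`pool_sources`), which
preserves the total observed count, and the remaining two-list cross is
estimated as above.  Completeness is reported as 100·n_list/N̂ rounded
half-up to one decimal, with the interval obtained by inverting the N̂
bounds.

## Data model and bundled tables (`crcapture.capture_data`)

Capture histories are validated binary matrices (no all-zero rows — an
unobservable individual cannot appear in list data); pattern counts and
histories convert losslessly in both directions.  The two bundled
three-source tables ship as plain CSV with a checksum sidecar holding their
published marginal totals, re-verified on every load; `validate_fixture`
returns a per-checksum report rather than an exception so corrupted inputs
are diagnosable.  One subtlety is deliberate: the published multi-source
total for the breast table (470) counts cases in *exactly* two sources,
while the colorectal figure (337) counts *at least* two — the sidecars pin
each with its own key.  Both readings are reproduced, along with every
pairwise overlap, by the shipped cells.

Covariate-to-episode expansion turns each (source, covariate, level) triple
into its own capture episode: individual i scores 1 in episode (s, c, ℓ)
iff i was captured by s and has c = ℓ.  The standard maps are provided
(5 five-year age bands × 3 sources + screening history × 3 = 21 episodes
for breast; age + gender + metastasis-positive = 24 for colorectal).  Ages
outside 50–75 and covariate values outside declared level sets are rejected,
not imputed.  Expanded matrices are fed to the Mth machinery unchanged; no
structural-zero filtering is applied (an individual's impossible episodes
simply contribute factors the episode effects absorb).

## Synthetic generator (`crcapture.synthetic`)

Scenarios draw γ_i ~ N(0, σ²_γ), set p_it by the logistic model plus
optional per-source covariate shifts (binary covariates with configurable
prevalence; age uniform over the study range), and sample captures
independently.  The full truth (including never-captured individuals) and
the observed-only history are both returned, and everything is reproducible
by seed.  The library scenarios fix the study conditions used in the tests:
`mt_cancer_like` (N = 790, episode capture rates 0.92/0.68/0.26, matching
the scale of the bundled breast table), `mh_strong` (N = 800, σ_γ = 1.5),
`mth_mixed`, and `negative_dependence_covariates` (metastatic cases
over-captured by the clinical list and under-captured by screening — the
mechanism that makes the two non-registry lists negatively dependent and
inflates their pairwise Lincoln–Petersen estimate).

What the generator does *not* emulate: record-linkage errors (false matches
or missed matches between lists), informative missingness in covariates,
population openness (migration, death mid-year).  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to linkage error.

## Numerical choices and test scale

Quadrature: 31 Gauss–Hermite nodes (error well below Monte-Carlo noise for
σ_γ ≤ 3).  Logistic terms use `log_expit`, which saturates instead of
overflowing; a conflicting observation under a numerically degenerate p
yields −∞ log-likelihood, not an exception.  The sampler's N draw guards
p₀ < 1 explicitly.  Test and example chains are scaled to the information in
the problem rather than the published schedule: toy oracle comparisons use
12 000 kept draws, parameter-recovery and coverage checks 50 replicates of
1 500 kept draws under the time-effects model, heterogeneity detection five
replicates of 3 000 — sizes at which every asserted property has comfortable
Monte-Carlo margin.  The published 25 000/5 000 schedule is the default for
real analyses and is what the reproduction script uses.

## Known limitations

* The log-linear family is implemented for exactly three lists; stratified
  or covariate log-linear models are out of scope (the episode-expansion +
  Mth route covers that need).
* Bayesian fits of the bundled tables put ~97% of posterior mass on Mt with
  an averaged N̂ near the independence log-linear fit, as the likelihood
  dictates; the historically published posterior summaries for these tables
  (means ~2% lower, posterior sds below the information bound √x̂₀₀₀) are
  not reproducible by a correctly mixing sampler and appear to be an
  augmentation-ceiling artifact of the original software run.  Likewise the
  published saturated-model figure for the colorectal table contradicts the
  closed-form identity on any cell table consistent with its other published
  statistics; the package reports the closed-form-consistent value.
* Model probabilities from reversible jump with prior proposals are exact in
  law but mix slowly when an effect is strongly supported; with the diffuse
  default priors the Occam penalty against Mth is substantial, which is the
  intended behaviour of the uniform-over-models prior.
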