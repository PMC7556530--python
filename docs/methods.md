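# Methods

This note documents the statistical model, the preprocessing contracts,
the synthetic-data generator, and the numerical choices made where the
design was genuinely open.

## Units, outcome, and analysis window

Births are the unit of analysis. The outcome is binary: death before the
fifth birthday. Only births occurring at least 5 and less than 10 years
before the survey date (`survey_date − birth_date ∈ [5, 10)`) enter the
analysis: the lower bound guarantees every analyzed child had the full
five-year exposure (no censoring within the outcome window), the upper
bound limits recall error in retrospective birth histories. The window is
half-open so the two exclusion rules partition time without overlap; all
dates are decimal years (a converter from DHS-style century-month codes is
provided, plus a documented — untested — column mapping for Births Recode
files in `preprocessing.DHS_BIRTHS_RECODE_MAPPING`).

## Covariates

Eight base risk factors: maternal age at birth (years), relative wealth
(see below), maternal education (years), calendar year of birth, birth
order, child sex, urban/rural residence, and a prior-death indicator.

**Relative wealth.** Raw wealth-index scores have arbitrary,
survey-specific scales. Within each survey, household scores are mapped to
their empirical CDF with the midpoint-rank convention `(rank − 0.5)/n`
(mean ranks for ties), one score per household, broadcast to the
household's births. This keeps values strictly inside (0, 1), is invariant
to any strictly increasing rescaling of the raw score, and makes wealth
interpretable as within-survey rank. Quintiles cut the CDF at 0.2, …, 0.8
(quintile 1 = poorest); a pre-assigned quintile column, when present in
the input, takes precedence. The midpoint-rank rule is this package's
documented convention; ranking is performed over the households present in
the filtered analysis table.

**Prior-death indicator.** 1 iff an earlier-order sibling died before age
five *and* that death occurred strictly before the index birth; 0 for all
first births. It is computed on the complete birth history before the
window filter, so elder siblings outside the analysis window still count,
and it never uses information from later births. When a died sibling's
death date is missing, the death is counted only when it is certain to
precede the index birth (the sibling's five-year risk window closed before
it); such imputations are counted and logged.

## Risk model

For birth *i* in cluster *c(i)*:

```
died_i ~ Bernoulli(p_i)
logit(p_i) = α + Σ_j β_j x_ij + u_c(i)
```

- **Main effects.** Continuous covariates enter through piecewise-linear
  (hinge) spline bases `x, max(0, x − κ_1), …` so any continuous
  piecewise-linear trend with breaks at the knots is exactly
  representable. Default knots: wealth CDF at the quintile boundaries
  {0.2, 0.4, 0.6, 0.8}; maternal age {20, 25, 30}; education {4, 8, 12};
  birth order {3}; birth year linear (the window spans only five calendar
  years). Knots outside the observed range are dropped with a warning.
- **Interactions.** All products of k distinct standardized base
  covariates for k = 2, 3, 4 — C(8, k) columns per order (28 + 56 + 70).
  Interactions use the linear standardized covariates, not their spline
  bases: splines and interactions are separate devices, and full
  spline-by-spline products would explode the design without support in
  the modelling intent. Constant covariates are excluded from
  interactions.
- **Standardization.** Every design column is standardized to mean 0,
  sd 1 on the analysis table; means, sds and knots are stored in the
  fitted artifact so the identical transform applies at prediction time.
- **Priors.** Coefficients of order-k terms share a scale:
  β ~ N(0, σ_k²) with σ_k ~ Half-Normal(s_k) and the schedule
  s = {1.0, 0.5, 0.25, 0.125} for k = 1…4 (halving per order, strictly
  decreasing, configurable), so higher-order interactions are shrunk
  hardest unless the data demand them. Cluster effects
  u_c ~ N(0, σ_loc²), σ_loc ~ Half-Normal(1); intercept α ~ N(0, 5) on
  the log-odds scale. These hyperparameters are this package's defaults;
  alternatives can be supplied through `ModelSpec`.
- **One model per survey.** Cross-survey pooling is out of scope; survey
  sampling weights are deliberately not used.

### Sampling

The posterior is sampled by adaptive Hamiltonian Monte Carlo with analytic
gradients on the non-centered parameterization (β = σ_k z, u = σ_loc z_u,
scales sampled as logs with the Jacobian included) — the non-centering
avoids the funnel pathology of hierarchical scales. Warmup adapts the step
size by dual averaging (target acceptance 0.85) and re-estimates a
diagonal mass matrix twice from trailing windows; path length ≈ 1.2 with
±30% jitter, at most 64 leapfrog steps. Defaults: 4 chains × 500 warmup,
exactly 1000 retained draws pooled across chains (the per-draw equity
statistics are computed on these). Split rank-normalized R-hat (via
`arviz`) is reported for α, each σ_k, and σ_loc; any value ≥ 1.05 raises a
diagnostics *warning*, not a failure. Divergences are counted after
warmup. All randomness flows from a single integer seed through
`numpy.random.SeedSequence`.

Separation (a covariate perfectly predicting the outcome) does not abort
the fit — the priors regularize — but implausibly large posterior-mean
coefficients are logged. Zero deaths (or zero survivors) is an error.

### Per-birth risk posterior

For each retained draw s, `p_i^(s) = expit(α^(s) + x_i'β^(s) + u^(s))`,
giving an S × N matrix; clusters unseen at fit time get a zero cluster
effect. The posterior mean risk per birth is the row average.

## Equity statistics

All per-draw statistics are summarized by their mean and the equal-tailed
95% interval (2.5th/97.5th percentiles); "significant" means the interval
excludes the null (1 for ratios, 0 for differences). Choices on points the
analysis convention leaves open:

- **ANOVA scale.** The per-draw R² = SS_between/SS_total is computed on
  the *probability* scale by default — the decomposition concerns risks
  themselves, not log-odds; a logit-scale variant is available behind
  `anova_r2(..., scale="logit")`. A draw with zero total variance
  contributes R² = 0.
- **Targeting sets.** The poor set is the ⌊qN⌋ births with lowest wealth
  CDF — ranked, not quintile membership, so the comparison set is exactly
  the fraction q. The high-risk set is recomputed per draw from that
  draw's risk ranking (rank-based, hence invariant to monotone transforms
  of the risks); a point version uses the posterior-mean ranking. Ties at
  the cutoff break by stable birth-id order and are logged.
- **Group comparisons.** Odds ratios use the Haldane–Anscombe +0.5
  correction when a 2×2 cell is empty (logged).
- **Boxplots.** Tukey convention: quartiles by linear interpolation,
  whiskers at the most extreme points within 1.5 IQR of the quartiles,
  outliers not drawn.

## Synthetic-data generator

The generator emulates the data-generating features the analysis is
sensitive to, with a fully known risk surface:

- **Wealth.** True relative wealth w ~ Uniform(0, 1) per mother
  (households ≈ mothers); the raw score is the quantile of a named
  distribution (default lognormal) at w — equivalent to drawing a score
  and applying the population CDF, and it keeps the true CDF available to
  tests. Risk depends on wealth only through w.
- **Correlated covariates.** Education is normal around
  `education_base + education_wealth_slope · w` (defaults 4 + 8w, sd 3,
  rounded, clipped to 0–18); urban residence has probability
  expit(−1.5 + 3w). Both correlations can be switched off per scenario.
- **Birth histories.** Age at first birth ~ N(19, 3) clipped to [13, 40];
  parity 1 + Binomial(max_parity − 1, 0.45); first birth uniform in the
  18 years before the survey (wider than the analysis window, so the
  filter always has work); spacing 2 years + Uniform(−0.5, 1) jitter.
  Births are simulated forward in time: each birth's prior-death
  indicator derives from already-simulated elder-sibling outcomes, never
  from the future. Death timing beyond the binary outcome is a uniform
  age in [0, 5) — only the ordering relative to later births matters
  downstream, and the [5, 10) filter removes censoring concerns.
- **Risk surface.** logit p = baseline + wealth gradient (per unit CDF)
  + optional per-quintile offsets + optional piecewise-linear wealth
  term + main effects (log-odds per unit of centered covariates)
  + centered interaction products + cluster effect (N(0, cluster_sd),
  cluster assigned per mother).

Canned scenarios: `equity_scenario` (risk independent of wealth — constant
by default; `heterogeneous=True` adds wealth-independent variation via
age, sex, birth order, prior death and clusters, which is the setting
where a near-zero wealth R² is meaningful); `gradient_scenario` (monotone
pro-poor gradient, −1.2 log-odds per unit wealth CDF, plus realistic main
effects); `interaction_scenario` (2- and 3-way terms so that poor rural
births with a prior death carry risk no single stratifier reveals); and
`quintile_variance_scenario(f)`, which calibrates a monotone
piecewise-linear wealth effect (knots at quintile boundaries, hence
exactly representable by the model's spline basis) so that the
between-quintile share of true-risk variance equals f exactly — the
amplitude is found by 1-D root finding on the analytic risk surface
integrated over the covariate distribution, with no simulation involved.
In that scenario education is made wealth-independent and its effect set
to −0.25 log-odds/year so the total risk variance is realistic; at small
overall variance the binomial noise floor of realized quintile death
rates would dominate the between-quintile signal and no estimator could
recover f.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: DHS sampling weights and stratification,
missing data patterns, age heaping and date misreporting, migration
between clusters, non-stationary fertility, or real-world covariate
dependence structures beyond the wealth–education–urban correlations
above. Tests demonstrate the *method* recovers known truths under the
stated structure, not that any country's published estimates are
reproduced.

## Problem sizes and runtime choices

Test and demonstration runs use sizes chosen to make the statistical
check informative while keeping the suite quick: NPD benchmarks on
~200,000-birth surveys (the 99% binomial interval around 80% is then
below ±1 point), variance-fraction recovery at ~20,000 births with
2 chains × 300 retained draws, interval-calibration at ~4,000 births ×
20 replicates, and parameter-recovery at ~10,000 births × 3 seeds. The
full pipeline example (2,000 mothers, complete interaction model,
clusters) runs in well under a minute on one core.

## Known limitations

- Plain HMC with jittered path length, not NUTS; very stiff posteriors
  (tiny prior scales combined with strong likelihoods) may need a larger
  warmup. R-hat warnings surface such cases.
- The exact wealth-CDF tie convention and the prior hyperparameters are
  package conventions (documented above), configurable where reasonable.
- The efficiency-gain calculus assumes equal intervention cost per birth.
- Cross-survey and cross-country pooled analyses are out of scope; the
  package fits one survey at a time.
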