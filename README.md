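# riskequity

Measuring inequality in under-5 mortality **within** and **between**
socioeconomic groups, and evaluating risk-based versus poverty-based
targeting of child-health interventions.

National averages of under-5 mortality — and even averages disaggregated by
wealth quintile — can hide "left behind" populations, because births in the
same socioeconomic group face very different mortality risks: risk depends
on many factors (maternal age and education, relative wealth, rural
residence, birth order, a prior sibling death, local geography) and their
interactions. This package estimates the full per-birth risk distribution
from survey full-birth-history microdata and asks two policy questions:
how much of the variability in risk do wealth quintiles actually explain,
and how many more deaths would an intervention reach if it targeted the
highest-*risk* births instead of the *poorest* births?

## What it computes

**Risk model.** For birth *i* in sampling cluster *c(i)*,

```
died_i ~ Bernoulli(p_i),    logit(p_i) = α + Σ_b x_i'β_b + u_c(i)
```

with main effects entered through piecewise-linear splines for continuous
covariates, all 2-, 3- and 4-way interaction products of the eight base
covariates, order-dependent shrinkage priors
β_k ~ N(0, σ_k²), σ_k ~ Half-Normal(s_k) with s_k strictly decreasing in the
interaction order k, and a cluster random effect
u_c ~ N(0, σ_loc²). The posterior is sampled with an adaptive Hamiltonian
Monte Carlo sampler (analytic gradients, non-centered parameterization);
the product is an S × N matrix of per-birth risk draws.

**Equity statistics**, each computed per posterior draw and summarized by
its mean and equal-tailed 95% interval:

- **NPD** — the non-poor-deaths fraction: the share of observed deaths
  among births outside the poorest wealth quintile. Exactly 80% under
  perfect equity; below 80% when mortality is concentrated among the poor.
- **Bayesian ANOVA R²** — the between-group share of the variance of
  per-birth risk across wealth quintiles (or any grouping).
- **Efficiency gain** — `(HRDeaths − PoorDeaths) / PoorDeaths × 100`,
  where HRDeaths is observed mortality among the 20% highest-risk births
  and PoorDeaths is observed mortality among the 20% poorest.
- **Group comparisons** — odds ratios (binary factors) and mean
  differences (continuous factors) between the top-20%-risk births and the
  rest.

Wealth enters as the within-survey empirical CDF of the raw wealth-index
score (midpoint ranks), so "wealth" always means *relative* wealth on
(0, 1) and is comparable across surveys.

Because real full-birth-history microdata are access-restricted, the
package ships a first-class synthetic-survey generator
(`riskequity.synthetic`) with a known ground-truth risk surface: mothers
carry household wealth scores of arbitrary distribution, births are
simulated forward in time so the prior-death indicator is endogenous, and
the wealth→risk gradient is configurable — including a zero-gradient
perfect-equity benchmark and a scenario family whose between-quintile
variance fraction is calibrated exactly.

## Worked example

```python
from riskequity.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(
    output_dir="demo_run", scenario="gradient", n_mothers=2000, seed=7,
    model_overrides={"chains": 2, "warmup": 300, "draws_total": 600},
))
print(report.to_frame().round(3).to_string())
```

which simulates a 2,000-mother survey with a pro-poor mortality gradient,
fits the full interaction model, and prints:

```
                                                     mean  lower   upper
statistic
npd                                                 0.667    NaN     NaN
anova_r2[wealth_quintile]                           0.284  0.137   0.469
mortality_poor                                      0.168    NaN     NaN
mortality_highrisk                                  0.196  0.171   0.220
efficiency_gain_pct                                16.882  1.613  30.645
comparison[urban:odds_ratio]                        0.251  0.072   0.511
comparison[sex:odds_ratio]                          1.656  0.694   3.371
comparison[prior_death:odds_ratio]                  8.157  2.646  22.188
comparison[wealth_cdf:mean_difference]             -0.299 -0.377  -0.208
comparison[maternal_education:mean_difference]     -3.437 -4.583  -2.245
comparison[maternal_age_at_birth:mean_difference]  -0.476 -1.826   0.971
comparison[birth_order:mean_difference]             0.131 -0.282   0.555
```

Reading the output: only 67% of deaths occur outside the poorest quintile
(below the 80% equity benchmark), yet wealth quintiles explain just 28%
(14–47%) of the variance in risk — most inequality is *within* quintiles.
Targeting the model's top-20%-risk births captures 17% more deaths than
targeting the poorest 20%, and those high-risk births are rural
(urban OR 0.25), poorer (−30 wealth percentiles), and far more likely to
have a mother who already lost a child (OR 8.2).

The same stages are available as a CLI
(`riskequity simulate | preprocess | fit | analyze | all`) and as
scikit-learn-style estimators (`SurveyPreprocessor`, `BayesianRiskModel`)
for use in pipelines.

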