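"""Synthetic DHS-like survey birth histories with a known risk surface.

Real full-birth-history microdata (DHS Births Recode files) are access
restricted, so every downstream stage of the package is exercised on
simulated surveys whose ground truth is known exactly.  The generator
emulates the structural features that matter for the analysis:

* per-survey wealth-index scores with an arbitrary marginal distribution,
  where only the *relative* wealth (the population CDF value) enters risk;
* geographic sampling clusters with a shared log-odds offset;
* mother-level birth sequences simulated forward in time, so the
  prior-death indicator is endogenous — it depends on earlier simulated
  outcomes and never on later ones;
* covariate-dependent logistic mortality risk with configurable main
  effects, interaction terms, and a wealth gradient, including a
  zero-gradient "perfect equity" benchmark.

True relative wealth is drawn as ``w ~ Uniform(0, 1)`` and the raw score is
the named distribution's quantile at ``w``; this is equivalent to drawing a
raw score and applying the population CDF, and keeps the true wealth-CDF
value available for oracle tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "ScenarioConfig",
    "SurveyDataset",
    "TrueRisk",
    "generate_survey",
    "equity_scenario",
    "gradient_scenario",
    "interaction_scenario",
    "quintile_variance_scenario",
    "linear_predictor",
]

# Centering constants for covariates entering the true linear predictor.
# Effects in ScenarioConfig.effect_sizes are log-odds per unit of the
# centered covariate, so baseline_logit is the risk of a "reference birth"
# (25-year-old mother, 6 years of education, second birth, rural, female,
# median wealth, born mid-window, no prior death).
COVARIATE_CENTERS = {
    "maternal_age": 25.0,
    "maternal_education": 6.0,
    "birth_order": 2.0,
    "birth_year_offset": 7.5,  # years before survey; centered at window midpoint
    "wealth": 0.5,
}

_BINARY_COVARIATES = ("sex_male", "urban", "prior_death")
_CONTINUOUS_COVARIATES = ("maternal_age", "maternal_education", "birth_order", "birth_year", "wealth")
_KNOWN_COVARIATES = set(_BINARY_COVARIATES) | set(_CONTINUOUS_COVARIATES)


@dataclass
class ScenarioConfig:
    """Parameters of one simulated survey and its true risk surface.

    ``wealth_gradient`` is the log-odds change per unit of the true wealth
    CDF (a value of -1.0 means the richest birth has one log-odds unit lower
    risk than the poorest, all else equal).  ``quintile_logit_offsets`` and
    ``wealth_spline`` add, respectively, a step function over true wealth
    quintiles and a continuous piecewise-linear function of wealth CDF to
    the linear predictor; both default to absent.
    """

    n_mothers: int = 5000
    max_parity: int = 6
    n_clusters: int = 100
    cluster_sd: float = 0.0
    baseline_logit: float = logit(0.1)
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple, float] = field(default_factory=dict)
    wealth_gradient: float = 0.0
    quintile_logit_offsets: Sequence[float] | None = None
    wealth_spline: tuple[Sequence[float], Sequence[float]] | None = None  # (knots, values at 0,knots..,1)
    wealth_score_distribution: tuple[str, Mapping[str, float]] = ("lognorm", {"s": 1.0})
    education_base: float = 4.0
    education_wealth_slope: float = 8.0
    survey_year: float = 2015.0
    survey_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        if self.max_parity < 1:
            raise ValueError("max_parity must be >= 1")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")
        finite_params = [self.baseline_logit, self.wealth_gradient, *self.effect_sizes.values(), *self.interaction_effects.values()]
        if not np.all(np.isfinite(finite_params)):
            raise ValueError("scenario effects must be finite")
        for name in self.effect_sizes:
            key = "wealth" if name == "wealth" else name
            if key not in _KNOWN_COVARIATES:
                raise ValueError(f"unknown covariate in effect_sizes: {name!r}")
        for tup in self.interaction_effects:
            for name in tup:
                if name not in _KNOWN_COVARIATES:
                    raise ValueError(f"unknown covariate in interaction_effects: {name!r}")
        if self.quintile_logit_offsets is not None and len(self.quintile_logit_offsets) != 5:
            raise ValueError("quintile_logit_offsets must have length 5")
        if self.wealth_spline is not None:
            knots, values = self.wealth_spline
            if len(values) != len(knots) + 2:
                raise ValueError("wealth_spline values must cover 0, each knot, and 1")
            if not np.all(np.diff(knots) > 0):
                raise ValueError("wealth_spline knots must be strictly increasing")

    def to_json(self, path):
        d = asdict(self)
        d["interaction_effects"] = {"|".join(k): v for k, v in self.interaction_effects.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["interaction_effects"] = {tuple(k.split("|")): v for k, v in d.get("interaction_effects", {}).items()}
        if d.get("wealth_spline") is not None:
            d["wealth_spline"] = tuple(d["wealth_spline"])
        if d.get("wealth_score_distribution") is not None:
            d["wealth_score_distribution"] = tuple(d["wealth_score_distribution"])
        return cls(**d)


@dataclass
class SurveyDataset:
    """Birth records from one simulated survey."""

    births: pd.DataFrame
    survey_id: str
    survey_year: float


@dataclass
class TrueRisk:
    """Ground-truth risk for each simulated birth (parallel to the records)."""

    table: pd.DataFrame  # birth_id, true_wealth_cdf, linear_predictor, p_true

    @property
    def p_true(self) -> np.ndarray:
        return self.table["p_true"].to_numpy()


def _centered_values(config: ScenarioConfig, cov: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    c = COVARIATE_CENTERS
    return {
        "maternal_age": cov["maternal_age"] - c["maternal_age"],
        "maternal_education": cov["maternal_education"] - c["maternal_education"],
        "birth_order": cov["birth_order"] - c["birth_order"],
        "birth_year": cov["birth_year"] - (config.survey_year - c["birth_year_offset"]),
        "wealth": cov["wealth"] - c["wealth"],
        "sex_male": cov["sex_male"],
        "urban": cov["urban"],
        "prior_death": cov["prior_death"],
    }


def _wealth_spline_value(spline, w):
    knots, values = spline
    xs = np.concatenate(([0.0], np.asarray(knots, float), [1.0]))
    return np.interp(w, xs, np.asarray(values, float))


def linear_predictor(config: ScenarioConfig, cov: dict[str, np.ndarray], cluster_effect=0.0) -> np.ndarray:
    """True log-odds of under-5 death for births with the given covariates.

    ``cov`` maps covariate names (``maternal_age``, ``maternal_education``,
    ``birth_order``, ``birth_year``, ``wealth`` (CDF scale), ``sex_male``,
    ``urban``, ``prior_death``) to arrays.  Exposed so tests can integrate
    the analytic risk surface without simulating outcomes.
    """
    z = _centered_values(config, cov)
    eta = np.full_like(np.asarray(cov["wealth"], float), config.baseline_logit)
    eta = eta + config.wealth_gradient * z["wealth"]
    if config.quintile_logit_offsets is not None:
        q = np.minimum((np.asarray(cov["wealth"]) * 5).astype(int), 4)
        eta = eta + np.asarray(config.quintile_logit_offsets, float)[q]
    if config.wealth_spline is not None:
        eta = eta + _wealth_spline_value(config.wealth_spline, cov["wealth"])
    for name, beta in config.effect_sizes.items():
        eta = eta + beta * z[name]
    for tup, beta in config.interaction_effects.items():
        term = np.ones_like(eta)
        for name in tup:
            term = term * z[name]
        eta = eta + beta * term
    eta = eta + cluster_effect
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor; check scenario effects")
    return eta


def _wealth_quantile(distribution, w):
    name, params = distribution
    dist = getattr(stats, name)
    return dist.ppf(w, **params)


def generate_survey(config: ScenarioConfig) -> tuple[SurveyDataset, TrueRisk]:
    """Simulate one survey's birth records plus their ground-truth risks.

    Mothers are simulated sequentially birth by birth: each birth's
    prior-death indicator is computed from the death dates of its
    already-simulated elder siblings, so no information flows backwards in
    time.  Birth dates span roughly the 18 years before the survey — wider
    than the [5, 10) analysis window — so the window filter has work to do.
    """
    rng = np.random.default_rng(config.seed)
    M = config.n_mothers
    P = config.max_parity
    sy = config.survey_year

    cluster_of_mother = rng.integers(0, config.n_clusters, size=M)
    cluster_effects = (
        rng.normal(0.0, config.cluster_sd, size=config.n_clusters)
        if config.cluster_sd > 0
        else np.zeros(config.n_clusters)
    )

    w = rng.uniform(size=M)  # true wealth CDF, one per mother/household
    score = _wealth_quantile(config.wealth_score_distribution, w)
    education = np.clip(np.round(rng.normal(config.education_base + config.education_wealth_slope * w, 3.0)), 0, 18)
    urban = (rng.uniform(size=M) < expit(-1.5 + 3.0 * w)).astype(int)
    age_first_birth = np.clip(rng.normal(19.0, 3.0, size=M), 13.0, 40.0)
    parity = 1 + rng.binomial(P - 1, 0.45, size=M)
    first_birth_date = rng.uniform(sy - 18.0, sy - 1.0, size=M)

    # mother x order grids of pre-drawn randomness; sequential structure is
    # preserved by iterating over birth order below
    gaps = 2.0 + rng.uniform(-0.5, 1.0, size=(M, P))
    u_sex = rng.uniform(size=(M, P))
    u_outcome = rng.uniform(size=(M, P))
    u_death_age = rng.uniform(size=(M, P))

    bdates = first_birth_date[:, None] + np.concatenate(
        [np.zeros((M, 1)), np.cumsum(gaps[:, 1:], axis=1)], axis=1
    )
    orders = np.arange(1, P + 1)
    valid = (orders[None, :] <= parity[:, None]) & (bdates < sy)
    # a mother's sequence stops at her first invalid slot
    valid = np.logical_and.accumulate(valid, axis=1)

    died = np.zeros((M, P), dtype=int)
    prior_death = np.zeros((M, P), dtype=int)
    eta_grid = np.zeros((M, P))
    death_date = np.full((M, P), math.nan)
    earliest_death = np.full(M, np.inf)
    cl_eff = cluster_effects[cluster_of_mother]

    for j in range(P):
        mask = valid[:, j]
        if not mask.any():
            break
        prior_death[mask, j] = (earliest_death[mask] < bdates[mask, j]).astype(int)
        cov = {
            "maternal_age": age_first_birth[mask] + (bdates[mask, j] - first_birth_date[mask]),
            "maternal_education": education[mask],
            "birth_order": np.full(mask.sum(), float(j + 1)),
            "birth_year": bdates[mask, j],
            "wealth": w[mask],
            "sex_male": (u_sex[mask, j] < 0.5).astype(float),
            "urban": urban[mask].astype(float),
            "prior_death": prior_death[mask, j].astype(float),
        }
        eta = linear_predictor(config, cov, cl_eff[mask])
        eta_grid[mask, j] = eta
        p = expit(eta)
        d = (u_outcome[mask, j] < p).astype(int)
        died[mask, j] = d
        dd = bdates[mask, j] + 5.0 * u_death_age[mask, j]
        dd = np.where(d == 1, dd, np.inf)
        death_date[mask, j] = np.where(np.isinf(dd), math.nan, dd)
        em = earliest_death[mask]
        earliest_death[mask] = np.minimum(em, dd)

    keep = valid.ravel()
    mother_grid = np.repeat(np.arange(M), P)[keep]
    order_grid = np.tile(orders, M)[keep]
    bd = bdates.ravel()[keep]
    n = keep.sum()
    births = pd.DataFrame(
        {
            "birth_id": np.arange(n),
            "survey_id": config.survey_id,
            "cluster_id": cluster_of_mother[mother_grid],
            "mother_id": mother_grid,
            "birth_order": order_grid,
            "birth_date": bd,
            "survey_date": sy,
            "sex": np.where(u_sex.ravel()[keep] < 0.5, "male", "female"),
            "maternal_age_at_birth": age_first_birth[mother_grid] + (bd - first_birth_date[mother_grid]),
            "maternal_education": education[mother_grid],
            "wealth_score": score[mother_grid],
            "urban": np.where(urban[mother_grid] == 1, "urban", "rural"),
            "died_u5": died.ravel()[keep],
            "death_date": death_date.ravel()[keep],
        }
    )
    truth = pd.DataFrame(
        {
            "birth_id": np.arange(n),
            "true_wealth_cdf": w[mother_grid],
            "linear_predictor": eta_grid.ravel()[keep],
            "p_true": expit(eta_grid.ravel()[keep]),
        }
    )
    return SurveyDataset(births, config.survey_id, sy), TrueRisk(truth)


# ---------------------------------------------------------------------------
# Canned scenarios


def equity_scenario(
    n_mothers: int = 5000,
    seed: int = 0,
    baseline_risk: float = 0.1,
    heterogeneous: bool = False,
) -> ScenarioConfig:
    """Perfect-equity benchmark: death risk independent of wealth.

    By default every birth shares the identical death probability
    ``baseline_risk``, so the expected non-poor-deaths fraction is exactly
    80%.  With ``heterogeneous=True``, risk still does not depend on
    wealth (directly or through wealth-correlated covariates) but varies
    through maternal age, child sex, birth order, prior sibling death and
    sampling cluster — the setting in which "how much risk variance do
    wealth quintiles explain?" has a meaningful near-zero answer.
    """
    effects = {}
    cluster_sd = 0.0
    if heterogeneous:
        effects = {
            "maternal_age": -0.03,
            "sex_male": 0.15,
            "birth_order": 0.1,
            "prior_death": 0.6,
        }
        cluster_sd = 0.25
    return ScenarioConfig(
        n_mothers=n_mothers,
        cluster_sd=cluster_sd,
        baseline_logit=float(logit(baseline_risk)),
        wealth_gradient=0.0,
        effect_sizes=effects,
        survey_id="equity",
        seed=seed,
    )


def gradient_scenario(n_mothers: int = 5000, seed: int = 0) -> ScenarioConfig:
    """Monotone pro-poor mortality gradient plus realistic main effects."""
    return ScenarioConfig(
        n_mothers=n_mothers,
        cluster_sd=0.3,
        baseline_logit=float(logit(0.1)),
        wealth_gradient=-1.2,
        effect_sizes={
            "maternal_education": -0.04,
            "maternal_age": -0.02,
            "birth_order": 0.05,
            "urban": -0.25,
            "prior_death": 0.7,
        },
        survey_id="gradient",
        seed=seed,
    )


def interaction_scenario(n_mothers: int = 5000, seed: int = 0) -> ScenarioConfig:
    """Main effects plus 2- and 3-way interactions.

    Poor rural births whose mother already lost a child carry risk well
    above what the main effects alone imply, so no single stratifier can
    identify the highest-risk group.
    """
    return ScenarioConfig(
        n_mothers=n_mothers,
        cluster_sd=0.3,
        baseline_logit=float(logit(0.1)),
        wealth_gradient=-1.0,
        effect_sizes={
            "maternal_education": -0.04,
            "urban": -0.3,
            "prior_death": 0.6,
        },
        interaction_effects={
            ("wealth", "prior_death"): -1.2,
            ("urban", "prior_death"): -0.5,
            ("wealth", "urban", "prior_death"): 1.0,
        },
        survey_id="interaction",
        seed=seed,
    )


def _quintile_variance_fraction(amplitude: float, edu_beta: float, baseline_logit: float, edu_base: float = 8.0, edu_slope: float = 0.0) -> float:
    """Between-quintile share of true-risk variance for the calibration scenario.

    Risk depends on wealth through a fixed decreasing piecewise-linear shape
    scaled by ``amplitude`` (knots at quintile boundaries) and on education.
    Integrates the analytic risk surface on a fine wealth grid crossed with
    the education distribution.
    """
    # fixed shape: piecewise-linear, value 1 at w=0 declining to 0 at w=1,
    # steeper among the poor (knots at quintile boundaries)
    shape = ([0.2, 0.4, 0.6, 0.8], [1.0, 0.55, 0.3, 0.15, 0.05, 0.0])
    wgrid = (np.arange(2000) + 0.5) / 2000
    g = amplitude * _wealth_spline_value(shape, wgrid)
    edu = np.arange(0, 19, dtype=float)
    # marginal education distribution induced by the generator (normal around
    # 4 + 8w, sd 3, rounded and clipped), approximated on the same grid
    pe = np.zeros((wgrid.size, edu.size))
    for j, e in enumerate(edu):
        lo = -np.inf if e == 0 else e - 0.5
        hi = np.inf if e == 18 else e + 0.5
        mu = edu_base + edu_slope * wgrid
        pe[:, j] = stats.norm.cdf(hi, mu, 3.0) - stats.norm.cdf(lo, mu, 3.0)
    pe /= pe.sum(axis=1, keepdims=True)
    eta = baseline_logit + g[:, None] + edu_beta * (edu[None, :] - COVARIATE_CENTERS["maternal_education"])
    p = expit(eta)
    weights = pe / pe.sum()
    mean = float((p * weights).sum())
    total_var = float(((p - mean) ** 2 * weights).sum())
    q = np.minimum((wgrid * 5).astype(int), 4)
    between = 0.0
    for k in range(5):
        mask = q == k
        wk = weights[mask].sum()
        mk = float((p[mask] * weights[mask]).sum() / wk)
        between += wk * (mk - mean) ** 2
    return between / total_var


def quintile_variance_scenario(
    f: float, n_mothers: int = 5000, seed: int = 0, edu_beta: float = -0.25
) -> ScenarioConfig:
    """Scenario whose between-quintile share of true-risk variance equals ``f``.

    The wealth effect is a monotone decreasing piecewise-linear function
    with knots at the quintile boundaries (so the risk model's spline basis
    can represent it exactly); maternal education — made wealth-independent
    in this scenario — supplies the remaining, within-quintile variance.
    The wealth amplitude is calibrated by 1-D root finding on the analytic
    risk surface, with no simulation involved.
    """
    if not 0 < f < 0.85:
        raise ValueError("f must be in (0, 0.85) for this scenario family")
    base = float(logit(0.1))
    amp = optimize.brentq(
        lambda a: _quintile_variance_fraction(a, edu_beta, base, edu_base=8.0, edu_slope=0.0) - f,
        1e-8,
        8.0,
        xtol=1e-10,
    )
    shape_values = np.array([1.0, 0.55, 0.3, 0.15, 0.05, 0.0]) * amp
    return ScenarioConfig(
        n_mothers=n_mothers,
        cluster_sd=0.0,
        baseline_logit=base,
        wealth_spline=([0.2, 0.4, 0.6, 0.8], shape_values.tolist()),
        effect_sizes={"maternal_education": edu_beta},
        education_base=8.0,
        education_wealth_slope=0.0,
        survey_id=f"quintile_var_{f:g}",
        seed=seed,
    )
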