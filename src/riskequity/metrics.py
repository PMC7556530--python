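"""Equity statistics computed from per-birth posterior risk draws.

All per-draw statistics follow the same recipe: compute the quantity once
per retained MCMC draw of the risk vector, then summarize the resulting
distribution by its mean and equal-tailed 95% interval (2.5 and 97.5
percentiles).  The statistics:

* **NPD** — the non-poor-deaths fraction, the share of observed under-5
  deaths occurring to births outside the poorest wealth quintile.  Under
  perfect equity it is exactly 80%; a pro-poor mortality gradient pushes
  it below 80%.
* **Bayesian ANOVA R²** — per draw, the between-group share of the
  variance of per-birth risk across a grouping (e.g. wealth quintile), on
  the probability scale.
* **Targeting efficiency gain** — observed mortality among the 20%
  highest-risk births versus the 20% poorest:
  ``(HRDeaths − PoorDeaths) / PoorDeaths × 100``.
* **Group comparisons** — top-20%-risk versus the rest: odds ratios for
  binary risk factors, mean differences for continuous ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riskequity.model import RiskPosterior

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "TargetingResult",
    "GroupComparison",
    "EquityReport",
    "npd_fraction",
    "anova_r2",
    "boxplot_summary",
    "targeting",
    "compare_groups",
    "equity_report",
]

CATEGORICAL_COMPARISON = ("urban", "sex", "prior_death")
CONTINUOUS_COMPARISON = ("wealth_cdf", "maternal_education", "maternal_age_at_birth", "birth_order")


def _risk_draws(risk) -> np.ndarray:
    if isinstance(risk, RiskPosterior):
        return risk.draws
    return np.atleast_2d(np.asarray(risk, dtype=float))


def _interval(values: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def npd_fraction(table: pd.DataFrame) -> float:
    """Share of under-5 deaths among births outside the poorest quintile.

    Returns NaN (flagged missing) when the table records no deaths.
    """
    deaths = table["died_u5"].to_numpy() == 1
    if deaths.sum() == 0:
        logger.warning("npd_fraction undefined: no deaths in table")
        return float("nan")
    nonpoor = table["wealth_quintile"].to_numpy() >= 2
    return float((deaths & nonpoor).sum() / deaths.sum())


@dataclass
class AnovaResult:
    """Posterior of the one-way ANOVA R² of risk across a grouping."""

    grouping: str
    r2_draws: np.ndarray
    mean: float
    interval: tuple[float, float]
    group_means: pd.Series

    def __post_init__(self):
        if np.any((self.r2_draws < 0) | (self.r2_draws > 1)):
            raise ValueError("per-draw R^2 must lie in [0, 1]")


def anova_r2(risk, groups, name: str = "group", scale: str = "probability") -> AnovaResult:
    """Per-draw between/total variance ratio of risk across ``groups``.

    For each draw s with risk vector p(s): R²(s) = SS_between / SS_total,
    with SS_total the total sum of squares of p(s) and SS_between the sum
    of squares of group means around the grand mean.  The decomposition is
    done on the probability scale by default (``scale="logit"`` decomposes
    log-odds instead; group mean risks are always reported on the
    probability scale).  A draw with zero total variance contributes
    R² = 0; a single group yields R² ≡ 0 with a warning.
    """
    if scale not in ("probability", "logit"):
        raise ValueError("scale must be 'probability' or 'logit'")
    P = _risk_draws(risk)
    codes, cats = pd.factorize(np.asarray(groups))
    if P.shape[1] != codes.size:
        raise ValueError("group labels do not align with risk draws")
    G = len(cats)
    if G < 2:
        logger.warning("anova_r2: single group; R^2 is identically 0")
        zeros = np.zeros(P.shape[0])
        gm = pd.Series(P.mean(axis=0).mean(), index=list(cats), name="mean_risk")
        return AnovaResult(name, zeros, 0.0, (0.0, 0.0), gm)

    from scipy.special import logit as _logit

    Q = _logit(np.clip(P, 1e-12, 1 - 1e-12)) if scale == "logit" else P
    counts = np.bincount(codes, minlength=G).astype(float)
    grand = Q.mean(axis=1)
    sst = ((Q - grand[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(P.shape[0])
    group_mean_point = np.empty(G)
    for g in range(G):
        qg = Q[:, codes == g].mean(axis=1)
        ssb += counts[g] * (qg - grand) ** 2
        group_mean_point[g] = P[:, codes == g].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssb / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)  # guard rounding at the boundaries
    order = np.argsort([str(c) for c in cats])
    gm = pd.Series(group_mean_point, index=list(cats), name="mean_risk").iloc[order]
    return AnovaResult(name, r2, float(r2.mean()), _interval(r2), gm)


def boxplot_summary(values, groups) -> pd.DataFrame:
    """Five-number summaries per group in Tukey boxplot convention.

    Quartiles use linear interpolation; whiskers reach the most extreme
    data points within 1.5 interquartile ranges of the quartiles, so
    outliers do not stretch them.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        v = values[groups == g]
        if v.size == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        rows.append((g, float(in_fence.min()), float(q1), float(med), float(q3), float(in_fence.max())))
    return pd.DataFrame(rows, columns=["group", "whisker_low", "q1", "median", "q3", "whisker_high"]).set_index("group")


@dataclass
class TargetingResult:
    """Risk-based vs poverty-based targeting of a fraction q of births."""

    q: float
    n_targeted: int
    mortality_poor: float
    mortality_highrisk_draws: np.ndarray
    efficiency_gain_draws: np.ndarray
    mortality_highrisk_mean: float
    mortality_highrisk_interval: tuple[float, float]
    efficiency_gain_mean: float
    efficiency_gain_interval: tuple[float, float]
    mortality_highrisk_point: float
    efficiency_gain_point: float
    gain_defined: bool = True


def _top_k_stable(score: np.ndarray, k: int, tiebreak: np.ndarray) -> np.ndarray:
    """Indices of the k largest scores; ties broken by ascending tiebreak."""
    order = np.lexsort((tiebreak, -score))
    return order[:k]


def targeting(risk, table: pd.DataFrame, q: float = 0.20) -> TargetingResult:
    """Compare death capture of the top-q risk set against the q poorest.

    ``PoorDeaths`` is the observed death fraction among the floor(qN)
    births with lowest wealth CDF; per draw, ``HRDeaths(s)`` is the
    observed death fraction among the floor(qN) births with highest risk
    under that draw.  The efficiency gain is
    ``(HRDeaths − PoorDeaths) / PoorDeaths × 100``; it is also computed
    once from the posterior-mean risk ranking as a point version.  Ties at
    the cutoff are broken by stable birth-id order.
    """
    P = _risk_draws(risk)
    y = table["died_u5"].to_numpy(dtype=float)
    wealth = table["wealth_cdf"].to_numpy(dtype=float)
    bid = table["birth_id"].to_numpy() if "birth_id" in table.columns else np.arange(len(table))
    N = len(table)
    k = int(np.floor(q * N))
    if k < 1:
        raise ValueError("q too small: empty target set")

    poor_idx = _top_k_stable(-wealth, k, bid)
    if np.unique(wealth).size < N:
        logger.info("targeting: ties in wealth_cdf broken by stable birth-id order")
    mortality_poor = float(y[poor_idx].mean())

    S = P.shape[0]
    hr = np.empty(S)
    for s in range(S):
        hr[s] = y[_top_k_stable(P[s], k, bid)].mean()
    point_hr = float(y[_top_k_stable(P.mean(axis=0), k, bid)].mean())

    defined = mortality_poor > 0
    if not defined:
        logger.warning("targeting: zero deaths among the poorest %d births; gain undefined", k)
        gains = np.full(S, np.nan)
        point_gain = float("nan")
    else:
        gains = (hr - mortality_poor) / mortality_poor * 100.0
        point_gain = (point_hr - mortality_poor) / mortality_poor * 100.0

    return TargetingResult(
        q=q,
        n_targeted=k,
        mortality_poor=mortality_poor,
        mortality_highrisk_draws=hr,
        efficiency_gain_draws=gains,
        mortality_highrisk_mean=float(hr.mean()),
        mortality_highrisk_interval=_interval(hr),
        efficiency_gain_mean=float(gains.mean()) if defined else float("nan"),
        efficiency_gain_interval=_interval(gains) if defined else (float("nan"), float("nan")),
        mortality_highrisk_point=point_hr,
        efficiency_gain_point=point_gain,
        gain_defined=defined,
    )


@dataclass
class GroupComparison:
    """High-risk (top q) vs lower-risk births, one row per risk factor."""

    q: float
    table: pd.DataFrame  # covariate, type, statistic, mean, lower, upper, significant
    draws: dict = field(repr=False, default_factory=dict)


def compare_groups(risk, table: pd.DataFrame, q: float = 0.20) -> GroupComparison:
    """Describe who the model ranks as highest risk.

    Per draw, births are split into the top-q and bottom-(1−q) of that
    draw's risk ranking.  Binary factors get the odds ratio of their
    prevalence (high vs low, with the Haldane–Anscombe +0.5 correction
    when a cell is empty); continuous factors get the mean difference
    (high − low).  A factor is flagged significant when its 95% interval
    excludes the null (1 for ratios, 0 for differences).
    """
    P = _risk_draws(risk)
    N = len(table)
    bid = table["birth_id"].to_numpy() if "birth_id" in table.columns else np.arange(N)
    k = int(np.floor(q * N))
    if k < 1 or k >= N:
        raise ValueError("q must leave both groups nonempty")

    binary_values = {}
    for cov in CATEGORICAL_COMPARISON:
        if cov not in table.columns:
            continue
        v = table[cov]
        if cov == "urban":
            x = (v == "urban").astype(float).to_numpy() if v.dtype == object else v.astype(float).to_numpy()
        elif cov == "sex":
            x = (v == "male").astype(float).to_numpy() if v.dtype == object else v.astype(float).to_numpy()
        else:
            x = v.astype(float).to_numpy()
        if np.all(x == x[0]):
            logger.warning("compare_groups: %s constant; skipped", cov)
            continue
        binary_values[cov] = x
    continuous_values = {}
    for cov in CONTINUOUS_COMPARISON:
        if cov not in table.columns:
            continue
        x = table[cov].astype(float).to_numpy()
        if np.all(x == x[0]):
            logger.warning("compare_groups: %s constant; skipped", cov)
            continue
        continuous_values[cov] = x

    S = P.shape[0]
    draws = {cov: np.empty(S) for cov in list(binary_values) + list(continuous_values)}
    corrected = False
    for s in range(S):
        top = _top_k_stable(P[s], k, bid)
        mask = np.zeros(N, dtype=bool)
        mask[top] = True
        n_hi, n_lo = k, N - k
        for cov, x in binary_values.items():
            a = x[mask].sum()  # high & factor present
            b = n_hi - a
            c = x[~mask].sum()
            d = n_lo - c
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                corrected = True
            draws[cov][s] = (a * d) / (b * c)
        for cov, x in continuous_values.items():
            draws[cov][s] = x[mask].mean() - x[~mask].mean()
    if corrected:
        logger.info("compare_groups: Haldane-Anscombe +0.5 correction applied to zero cells")

    rows = []
    for cov in draws:
        is_binary = cov in binary_values
        lo, hi = _interval(draws[cov])
        null = 1.0 if is_binary else 0.0
        rows.append(
            {
                "covariate": cov,
                "type": "categorical" if is_binary else "continuous",
                "statistic": "odds_ratio" if is_binary else "mean_difference",
                "mean": float(draws[cov].mean()),
                "lower": lo,
                "upper": hi,
                "significant": bool(lo > null or hi < null),
            }
        )
    return GroupComparison(q=q, table=pd.DataFrame(rows).set_index("covariate"), draws=draws)


@dataclass
class EquityReport:
    """All equity statistics for one survey, with posterior intervals."""

    npd: float
    anova: dict
    boxplots: pd.DataFrame
    targeting_result: TargetingResult
    comparison: GroupComparison

    def to_frame(self) -> pd.DataFrame:
        """One row per statistic: mean, lower, upper."""
        rows = [("npd", self.npd, float("nan"), float("nan"))]
        for name, res in self.anova.items():
            rows.append((f"anova_r2[{name}]", res.mean, *res.interval))
        t = self.targeting_result
        rows.append(("mortality_poor", t.mortality_poor, float("nan"), float("nan")))
        rows.append(("mortality_highrisk", t.mortality_highrisk_mean, *t.mortality_highrisk_interval))
        rows.append(("efficiency_gain_pct", t.efficiency_gain_mean, *t.efficiency_gain_interval))
        for cov, row in self.comparison.table.iterrows():
            rows.append((f"comparison[{cov}:{row['statistic']}]", row["mean"], row["lower"], row["upper"]))
        return pd.DataFrame(rows, columns=["statistic", "mean", "lower", "upper"]).set_index("statistic")

    def to_json(self, path=None):
        payload = {
            "schema_version": 1,
            "npd": _jsonify(self.npd),
            "anova_r2": {
                name: {
                    "mean": res.mean,
                    "interval": list(res.interval),
                    "group_means": {str(k): float(v) for k, v in res.group_means.items()},
                }
                for name, res in self.anova.items()
            },
            "boxplots": self.boxplots.reset_index().to_dict(orient="records"),
            "targeting": {
                k: _jsonify(v)
                for k, v in dataclasses.asdict(self.targeting_result).items()
                if not k.endswith("_draws")
            },
            "comparison": self.comparison.table.reset_index().to_dict(orient="records"),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload


def _jsonify(v):
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return None if np.isnan(f) else f
    if isinstance(v, (np.integer, int)):
        return int(v)
    if isinstance(v, (tuple, list)):
        return [_jsonify(x) for x in v]
    return v


def equity_report(risk, table: pd.DataFrame, q: float = 0.20, groupings=("wealth_quintile",)) -> EquityReport:
    """Assemble the full equity analysis for one survey."""
    P = _risk_draws(risk)
    anova = {g: anova_r2(P, table[g].to_numpy(), name=g) for g in groupings}
    post_mean = P.mean(axis=0)
    box = boxplot_summary(post_mean, table["wealth_quintile"].to_numpy())
    return EquityReport(
        npd=npd_fraction(table),
        anova=anova,
        boxplots=box,
        targeting_result=targeting(P, table, q=q),
        comparison=compare_groups(P, table, q=q),
    )
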