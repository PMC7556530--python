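"""Bayesian hierarchical logistic regression for per-birth mortality risk.

The model for birth *i* in cluster *c(i)*:

    died_i ~ Bernoulli(p_i),   logit(p_i) = alpha + x_i' beta + u_{c(i)}

with order-dependent shrinkage: a coefficient of an order-k term (k = 1 for
main effects, 2-4 for interactions) has prior Normal(0, sigma_k^2) with
sigma_k ~ Half-Normal(s_k) and s_k strictly decreasing in k, so
higher-order interactions are shrunk toward zero unless the data insist.
Cluster effects u_c ~ Normal(0, sigma_loc^2), sigma_loc ~ Half-Normal(1);
alpha ~ Normal(0, 5) on the log-odds scale.

Sampling is by adaptive Hamiltonian Monte Carlo on the non-centered
parameterization (beta = sigma_k * z), with analytic gradients.  The
posterior of the risk vector — an S x N matrix of probabilities, one row
per retained draw — is the input to all downstream equity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from riskequity.design import DesignMatrix, ModelSpec, build_design
from riskequity._hmc import hmc_chain

logger = logging.getLogger(__name__)

__all__ = ["RiskPosterior", "BayesianRiskModel", "sample_model", "posterior_risk"]

RHAT_THRESHOLD = 1.05


@dataclass
class RiskPosterior:
    """Per-birth posterior mortality-risk draws.

    ``draws`` is S x N (S retained MCMC draws, N births), every entry in
    (0, 1); ``posterior_mean`` is the per-birth average over draws.
    """

    draws: np.ndarray
    posterior_mean: np.ndarray
    diagnostics: dict | None = None

    def __post_init__(self):
        if self.draws.ndim != 2:
            raise ValueError("draws must be S x N")
        if np.any((self.draws <= 0) | (self.draws >= 1)):
            raise ValueError("risk draws must lie strictly inside (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame({"posterior_mean_risk": self.posterior_mean}).to_csv(path, index_label="row")

    def save_draws(self, path) -> None:
        np.savez_compressed(path, draws=self.draws)


def _pack_layout(design: DesignMatrix):
    orders_used = np.array(sorted(set(design.col_order.tolist())))
    slot_of_col = np.searchsorted(orders_used, design.col_order)
    p = design.X.shape[1]
    K = orders_used.size
    C = design.n_clusters
    return orders_used, slot_of_col, p, K, C


def _make_logp_grad(design: DesignMatrix, y: np.ndarray, spec: ModelSpec):
    X = design.X
    orders_used, slot, p, K, C = _pack_layout(design)
    scales = np.array([spec.prior_scale_schedule[int(k)] for k in orders_used])
    cl = design.cluster_index
    use_cluster = C > 0
    n = y.size

    def logp_grad(theta: np.ndarray):
        alpha = theta[0]
        z = theta[1 : 1 + p]
        lam = theta[1 + p : 1 + p + K]
        sigma = np.exp(lam)
        beta = sigma[slot] * z
        eta = alpha + X @ beta
        if use_cluster:
            zu = theta[1 + p + K : 1 + p + K + C]
            lam_loc = theta[-1]
            sigma_loc = np.exp(lam_loc)
            u = sigma_loc * zu
            eta = eta + u[cl]
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        lp = ll - 0.5 * float(z @ z) - alpha * alpha / 50.0
        lp += float(np.sum(-0.5 * sigma**2 / scales**2 + lam))

        r = y - expit(eta)
        g = np.empty_like(theta)
        g[0] = r.sum() - alpha / 25.0
        xtr = X.T @ r
        g[1 : 1 + p] = sigma[slot] * xtr - z
        bxtr = xtr * beta
        g[1 + p : 1 + p + K] = np.bincount(slot, weights=bxtr, minlength=K) - sigma**2 / scales**2 + 1.0
        if use_cluster:
            rc = np.bincount(cl, weights=r, minlength=C)
            lp += -0.5 * float(zu @ zu) - 0.5 * sigma_loc**2 + lam_loc
            g[1 + p + K : 1 + p + K + C] = sigma_loc * rc - zu
            g[-1] = sigma_loc * float(zu @ rc) - sigma_loc**2 + 1.0
        return lp, g

    dim = 1 + p + K + (C + 1 if use_cluster else 0)
    return logp_grad, dim


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Potential scale reduction via arviz (rank-normalized split R-hat)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(chains_draws[None] if chains_draws.ndim == 1 else chains_draws))


def sample_model(design: DesignMatrix, y, spec: ModelSpec) -> tuple[dict, dict]:
    """Draw from the posterior; returns (draws, diagnostics).

    ``draws`` pools exactly ``spec.draws_total`` post-warmup draws across
    chains: ``alpha`` (S,), ``beta`` (S, p) on the standardized-column
    scale, ``sigma`` (S, K) per interaction order, and — when a cluster
    effect is in the model — ``cluster`` (S, C) and ``sigma_loc`` (S,).
    A potential-scale-reduction above 1.05 for alpha or any scale
    parameter triggers a diagnostics warning, not a failure.
    """
    y = np.asarray(y, dtype=float)
    if y.size != design.X.shape[0]:
        raise ValueError("outcome length does not match design rows")
    deaths = int(y.sum())
    if deaths == 0:
        raise ValueError("no deaths in the data; the mortality model cannot be fit")
    if deaths == y.size:
        raise ValueError("no survivors in the data; the mortality model cannot be fit")

    logp_grad, dim = _make_logp_grad(design, y, spec)
    orders_used, slot, p, K, C = _pack_layout(design)
    scales = np.array([spec.prior_scale_schedule[int(k)] for k in orders_used])

    n_chains = spec.chains
    per_chain = [spec.draws_total // n_chains] * n_chains
    for i in range(spec.draws_total % n_chains):
        per_chain[i] += 1

    seeds = np.random.SeedSequence(spec.seed).spawn(n_chains)
    chain_draws = []
    infos = []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = np.zeros(dim)
        x0[0] = logit(max(min(y.mean(), 1 - 1e-6), 1e-6))
        x0[1 : 1 + p] = 0.1 * rng.normal(size=p)
        x0[1 + p : 1 + p + K] = np.log(scales / 2.0)
        if C > 0:
            x0[1 + p + K : 1 + p + K + C] = 0.1 * rng.normal(size=C)
            x0[-1] = np.log(0.3)
        draws, info = hmc_chain(logp_grad, x0, spec.warmup, per_chain[c], rng)
        chain_draws.append(draws)
        infos.append(info)

    pooled = np.concatenate(chain_draws, axis=0)
    lam = pooled[:, 1 + p : 1 + p + K]
    sigma = np.exp(lam)
    draws = {
        "alpha": pooled[:, 0],
        "beta": sigma[:, slot] * pooled[:, 1 : 1 + p],
        "sigma": sigma,
        "orders": orders_used,
    }
    if C > 0:
        sigma_loc = np.exp(pooled[:, -1])
        draws["cluster"] = sigma_loc[:, None] * pooled[:, 1 + p + K : 1 + p + K + C]
        draws["sigma_loc"] = sigma_loc

    # split-Rhat on the sampled (unconstrained) scale for the headline params
    m = min(per_chain)
    rhat = {"alpha": _split_rhat(np.stack([cd[:m, 0] for cd in chain_draws]))}
    for j, k in enumerate(orders_used):
        rhat[f"sigma_{int(k)}"] = _split_rhat(np.stack([cd[:m, 1 + p + j] for cd in chain_draws]))
    if C > 0:
        rhat["sigma_loc"] = _split_rhat(np.stack([cd[:m, -1] for cd in chain_draws]))

    worst = max(rhat.values())
    diagnostics = {
        "rhat": rhat,
        "max_rhat": worst,
        "accept_rate": float(np.mean([i["accept_rate"] for i in infos])),
        "divergences": int(np.sum([i["divergences"] for i in infos])),
        "converged": bool(worst < RHAT_THRESHOLD),
    }
    if worst >= RHAT_THRESHOLD:
        warnings.warn(
            f"MCMC convergence: max split-Rhat {worst:.3f} >= {RHAT_THRESHOLD}; "
            "increase warmup or chains",
            stacklevel=2,
        )
    bmax = float(np.abs(draws["beta"].mean(axis=0)).max()) if p else 0.0
    if bmax > 8.0:
        logger.warning("very large coefficient (|beta|=%.1f); possible separation — priors regularize", bmax)
    return draws, diagnostics


def posterior_risk(draws: dict, design: DesignMatrix, X: np.ndarray | None = None, cluster_index=None) -> RiskPosterior:
    """Per-birth risk draws: p_i^(s) = inverse-logit of draw s's linear predictor.

    With ``X``/``cluster_index`` omitted, risks are computed for the rows
    the design was built from.  Unseen clusters (index -1) get a zero
    cluster effect.
    """
    if X is None:
        X = design.X
        cluster_index = design.cluster_index
    if X.shape[1] != draws["beta"].shape[1]:
        raise ValueError("design columns do not match coefficient draws")
    eta = draws["alpha"][:, None] + draws["beta"] @ X.T
    if "cluster" in draws and cluster_index is not None:
        known = cluster_index >= 0
        eta[:, known] += draws["cluster"][:, cluster_index[known]]
    p = expit(eta)
    np.clip(p, 1e-12, 1 - 1e-12, out=p)
    return RiskPosterior(draws=p, posterior_mean=p.mean(axis=0))


class BayesianRiskModel(BaseEstimator):
    """Scikit-learn-style estimator for the hierarchical mortality model.

    ``fit`` takes the analysis table produced by
    :class:`riskequity.preprocessing.SurveyPreprocessor` (the death
    indicator is read from its ``died_u5`` column unless ``y`` is given)
    and samples the posterior; ``predict_risk`` returns the S x N
    :class:`RiskPosterior`, and ``predict_proba`` the posterior-mean risk
    in the two-column sklearn convention.

    Parameters mirror :class:`riskequity.design.ModelSpec`; one model is
    fit per survey.
    """

    def __init__(
        self,
        max_interaction_order: int = 4,
        spline_knots: dict | None = None,
        prior_scale_schedule: dict | None = None,
        cluster_effect: bool = True,
        chains: int = 4,
        warmup: int = 500,
        draws_total: int = 1000,
        seed: int = 0,
    ):
        self.max_interaction_order = max_interaction_order
        self.spline_knots = spline_knots
        self.prior_scale_schedule = prior_scale_schedule
        self.cluster_effect = cluster_effect
        self.chains = chains
        self.warmup = warmup
        self.draws_total = draws_total
        self.seed = seed

    def _spec(self) -> ModelSpec:
        kwargs = {}
        if self.spline_knots is not None:
            kwargs["spline_knots"] = dict(self.spline_knots)
        if self.prior_scale_schedule is not None:
            kwargs["prior_scale_schedule"] = dict(self.prior_scale_schedule)
        return ModelSpec(
            max_interaction_order=self.max_interaction_order,
            cluster_effect=self.cluster_effect,
            chains=self.chains,
            warmup=self.warmup,
            draws_total=self.draws_total,
            seed=self.seed,
            **kwargs,
        )

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        if y is None:
            y = X["died_u5"]
        y = np.asarray(y, dtype=float)
        self.spec_ = spec
        self.design_ = build_design(X, spec)
        self.draws_, self.diagnostics_ = sample_model(self.design_, y, spec)
        self.n_obs_ = len(X)
        return self

    def predict_risk(self, X: pd.DataFrame | None = None) -> RiskPosterior:
        """Posterior risk draws for the training table or a new one."""
        if X is None:
            post = posterior_risk(self.draws_, self.design_)
        else:
            Xd, cl = self.design_.transform(X)
            post = posterior_risk(self.draws_, self.design_, Xd, cl)
        post.diagnostics = self.diagnostics_
        return post

    def predict_proba(self, X: pd.DataFrame | None = None) -> np.ndarray:
        p = self.predict_risk(X).posterior_mean
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def save(self, path) -> None:
        """Serialize parameter draws, design metadata and standardization."""
        d = self.design_
        np.savez_compressed(
            path,
            alpha=self.draws_["alpha"],
            beta=self.draws_["beta"],
            sigma=self.draws_["sigma"],
            orders=self.draws_["orders"],
            cluster=self.draws_.get("cluster", np.empty((0, 0))),
            sigma_loc=self.draws_.get("sigma_loc", np.empty(0)),
            means=d.means,
            sds=d.sds,
            columns=np.array(d.columns, dtype=object),
        )
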