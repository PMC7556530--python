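"""Adaptive Hamiltonian Monte Carlo used by the risk model.

A compact HMC implementation with the standard adaptation recipe:
dual-averaged step size tuned to a target acceptance rate, a diagonal mass
matrix estimated from warmup draws, and jittered leapfrog path lengths.
The model supplies a callable returning the log posterior density and its
gradient; everything here is model-agnostic.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["hmc_chain"]


def _leapfrog(logp_grad, x, p, eps, inv_mass, n_steps):
    lp, g = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * inv_mass * p
        lp, g = logp_grad(x)
        p = p + 0.5 * eps * g
    return x, p, lp, g


def _find_initial_step(logp_grad, x, mass, inv_mass, rng):
    eps = 0.1
    lp0, _ = logp_grad(x)
    p0 = rng.normal(size=x.size) * np.sqrt(mass)
    h0 = lp0 - 0.5 * np.sum(p0 * p0 * inv_mass)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, inv_mass, 1)
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0 ** direction)
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, inv_mass, 1)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        crossed = (h1 - h0 > np.log(0.5)) != (direction > 0)
        if crossed:
            break
    return max(eps, 1e-6)


def hmc_chain(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 64,
    path_length: float = 1.2,
):
    """Run one HMC chain; returns (draws, info).

    ``logp_grad(x) -> (logp, grad)``.  Warmup adapts the step size by dual
    averaging throughout and re-estimates a diagonal mass matrix twice from
    trailing windows; draws are collected after warmup with adaptation
    frozen.  ``info`` reports acceptance rate and divergence count.
    """
    d = x0.size
    x = x0.copy()
    mass = np.ones(d)
    inv_mass = 1.0 / mass

    eps = _find_initial_step(logp_grad, x, mass, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_updates = [int(n_warmup * 0.5), int(n_warmup * 0.85)]
    window: list[np.ndarray] = []
    accepts = []
    divergences = 0
    draws = np.empty((n_draws, d))
    lp_cur, _ = logp_grad(x)

    total = n_warmup + n_draws
    adapt_iter = 0
    for it in range(total):
        adapting = it < n_warmup
        p0 = rng.normal(size=d) * np.sqrt(mass)
        h0 = lp_cur - 0.5 * np.sum(p0 * p0 * inv_mass)
        n_steps = max(1, min(max_leapfrog, int(path_length / eps)))
        n_steps = max(1, int(n_steps * rng.uniform(0.7, 1.3)))
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, inv_mass, n_steps)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        delta = h1 - h0
        if not np.isfinite(delta):
            delta = -np.inf
        if delta < -1000.0 and it >= n_warmup:
            divergences += 1
        accept_prob = min(1.0, np.exp(min(0.0, delta)))
        if rng.uniform() < accept_prob:
            x, lp_cur = x1, lp1
        if adapting:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            window.append(x.copy())
            if it + 1 in mass_updates:
                w = np.asarray(window[len(window) // 3 :])
                if w.shape[0] >= 10:
                    var = w.var(axis=0)
                    n = w.shape[0]
                    var = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-1
                    mass = 1.0 / np.maximum(var, 1e-10)
                    inv_mass = 1.0 / mass
                    # restart step-size adaptation against the new metric
                    eps = _find_initial_step(logp_grad, x, mass, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
                window = []
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if log_eps_bar != 0.0 else eps
        else:
            accepts.append(accept_prob)
            draws[it - n_warmup] = x

    info = {
        "accept_rate": float(np.mean(accepts)) if accepts else float("nan"),
        "divergences": divergences,
        "step_size": eps,
    }
    return draws, info
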