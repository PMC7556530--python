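"""Model specification and design-matrix construction.

The mortality model regresses the death indicator on eight base risk
factors: five continuous (maternal age at birth, relative wealth, maternal
education, calendar year of birth, birth order) and three binary (child
sex, urban residence, prior sibling death).  Continuous covariates enter
the main effects through piecewise-linear spline bases so non-linear trends
are captured; interactions of order 2-4 are products of the standardized
base covariates (one column per covariate subset), with per-order shrinkage
priors applied downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "DesignMatrix", "piecewise_linear_basis", "build_design"]

#: analysis-table column backing each model covariate
COVARIATE_COLUMNS = {
    "maternal_age": "maternal_age_at_birth",
    "wealth_cdf": "wealth_cdf",
    "maternal_education": "maternal_education",
    "birth_year": "birth_date",
    "birth_order": "birth_order",
    "sex": "sex",
    "urban": "urban",
    "prior_death": "prior_death",
}

DEFAULT_KNOTS = {
    "maternal_age": (20.0, 25.0, 30.0),
    "wealth_cdf": (0.2, 0.4, 0.6, 0.8),
    "maternal_education": (4.0, 8.0, 12.0),
    "birth_year": (),
    "birth_order": (3.0,),
}


@dataclass
class ModelSpec:
    """Covariates, splines, interaction order, priors, and MCMC settings.

    ``prior_scale_schedule`` maps interaction order k to the Half-Normal
    scale of the shared coefficient standard deviation for order-k terms;
    it must be strictly decreasing so higher-order interactions are
    shrunk harder (defaults halve per order: 1.0, 0.5, 0.25, 0.125).
    """

    continuous_covariates: tuple[str, ...] = (
        "maternal_age",
        "wealth_cdf",
        "maternal_education",
        "birth_year",
        "birth_order",
    )
    binary_covariates: tuple[str, ...] = ("sex", "urban", "prior_death")
    spline_knots: dict = field(default_factory=lambda: dict(DEFAULT_KNOTS))
    max_interaction_order: int = 4
    prior_scale_schedule: dict = field(
        default_factory=lambda: {1: 1.0, 2: 0.5, 3: 0.25, 4: 0.125}
    )
    cluster_effect: bool = True
    chains: int = 4
    warmup: int = 500
    draws_total: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.draws_total < 1:
            raise ValueError("draws_total must be >= 1")
        orders = sorted(self.prior_scale_schedule)
        scales = [self.prior_scale_schedule[k] for k in orders]
        if any(s <= 0 for s in scales):
            raise ValueError("prior scales must be positive")
        if any(b >= a for a, b in zip(scales, scales[1:])):
            raise ValueError("prior_scale_schedule must be strictly decreasing in order")
        if not 1 <= self.max_interaction_order <= 4:
            raise ValueError("max_interaction_order must be in 1..4")
        for cov, knots in self.spline_knots.items():
            if len(knots) > 1 and np.any(np.diff(knots) <= 0):
                raise ValueError(f"spline knots for {cov} must be strictly increasing")

    @property
    def base_covariates(self) -> tuple[str, ...]:
        return tuple(self.continuous_covariates) + tuple(self.binary_covariates)


def piecewise_linear_basis(x, knots) -> tuple[np.ndarray, list[float]]:
    """Hinge basis for continuous piecewise-linear functions.

    Returns the matrix ``[x, max(0, x - knot_1), ...]`` and the knots
    actually used.  Together with an intercept, any continuous
    piecewise-linear function with breaks at the knots is exactly a linear
    combination of these columns.  Knots outside the observed range produce
    constant columns and are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    used = []
    cols = [x]
    for k in knots:
        if k <= x.min() or k >= x.max():
            logger.warning("spline knot %g outside observed range [%g, %g]; dropped", k, x.min(), x.max())
            continue
        cols.append(np.maximum(0.0, x - k))
        used.append(float(k))
    return np.column_stack(cols), used


@dataclass
class DesignMatrix:
    """Standardized design with per-column block/order metadata.

    ``X`` holds the standardized columns; ``col_order[j]`` is the
    interaction order of column ``j`` (1 for main effects); ``col_block``
    names the covariate or covariate tuple the column belongs to.  The raw
    column means/sds and the spline knots are stored so the identical
    transform can be applied to new data.
    """

    X: np.ndarray
    columns: list
    col_block: list
    col_order: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    knots_used: dict
    base_means: dict
    base_sds: dict
    cluster_index: np.ndarray | None
    cluster_categories: np.ndarray | None
    spec: ModelSpec

    @property
    def n_clusters(self) -> int:
        return 0 if self.cluster_categories is None else len(self.cluster_categories)

    def transform(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
        """Apply the fitted standardization/splines to a new analysis table."""
        raw, names, _ = _raw_columns(table, self.spec, self.knots_used, self.base_means, self.base_sds)
        idx = [names.index(c) for c in self.columns]
        X = (raw[:, idx] - self.means) / self.sds
        cl = None
        if self.cluster_categories is not None:
            mapping = {c: i for i, c in enumerate(self.cluster_categories)}
            cl = np.array([mapping.get(c, -1) for c in table["cluster_id"]], dtype=int)
        return X, cl


def _binary_numeric(series: pd.Series, name: str) -> np.ndarray:
    if name == "sex":
        return (series == "male").astype(float).to_numpy()
    if name == "urban":
        return (series == "urban").astype(float).to_numpy()
    return series.astype(float).to_numpy()


def _raw_columns(table, spec, knots_map, base_means, base_sds):
    """Unstandardized design columns plus names and per-column order."""
    cols, names, orders, blocks = [], [], [], []
    base_values = {}
    for cov in spec.continuous_covariates:
        x = table[COVARIATE_COLUMNS[cov]].to_numpy(dtype=float)
        base_values[cov] = x
        knots = knots_map.get(cov, ())
        B = np.column_stack([x] + [np.maximum(0.0, x - k) for k in knots])
        for j in range(B.shape[1]):
            cols.append(B[:, j])
            names.append(cov if j == 0 else f"{cov}_hinge{knots[j - 1]:g}")
            orders.append(1)
            blocks.append(cov)
    for cov in spec.binary_covariates:
        x = _binary_numeric(table[COVARIATE_COLUMNS[cov]], cov)
        base_values[cov] = x
        cols.append(x)
        names.append(cov)
        orders.append(1)
        blocks.append(cov)

    # standardized base covariates for interaction products
    z = {}
    for cov in spec.base_covariates:
        mu, sd = base_means[cov], base_sds[cov]
        if sd == 0:
            continue
        z[cov] = (base_values[cov] - mu) / sd
    for k in range(2, spec.max_interaction_order + 1):
        for tup in combinations([c for c in spec.base_covariates if c in z], k):
            prod = np.ones(len(table))
            for cov in tup:
                prod = prod * z[cov]
            cols.append(prod)
            names.append(":".join(tup))
            orders.append(k)
            blocks.append(":".join(tup))
    mat = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return mat, names, (np.array(orders, dtype=int), blocks)


def build_design(table: pd.DataFrame, spec: ModelSpec | None = None) -> DesignMatrix:
    """Build the standardized design matrix for an analysis table.

    Main effects are piecewise-linear spline bases of the continuous
    covariates plus the binary covariates; order-k interaction columns
    (k up to ``spec.max_interaction_order``) are products of k distinct
    standardized base covariates — C(8, k) columns per order for the eight
    default covariates.  Every column is standardized to mean 0, sd 1 with
    the transform parameters stored for reuse at prediction time.  Constant
    covariates are excluded from interactions; constant columns are
    dropped.
    """
    spec = spec or ModelSpec()
    # resolve knots against the observed range once
    knots_map = {}
    for cov in spec.continuous_covariates:
        x = table[COVARIATE_COLUMNS[cov]].to_numpy(dtype=float)
        _, used = piecewise_linear_basis(x, spec.spline_knots.get(cov, ()))
        knots_map[cov] = tuple(used)

    base_means, base_sds = {}, {}
    for cov in spec.base_covariates:
        if cov in spec.continuous_covariates:
            x = table[COVARIATE_COLUMNS[cov]].to_numpy(dtype=float)
        else:
            x = _binary_numeric(table[COVARIATE_COLUMNS[cov]], cov)
        base_means[cov] = float(x.mean())
        base_sds[cov] = float(x.std())
        if base_sds[cov] == 0:
            logger.warning("covariate %s is constant; excluded from interactions", cov)

    raw, names, (orders, blocks) = _raw_columns(table, spec, knots_map, base_means, base_sds)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("dropping %d constant design column(s): %s", len(dropped), dropped)
    raw = raw[:, keep]
    means, sds = means[keep], sds[keep]
    names = [n for n, k in zip(names, keep) if k]
    blocks = [b for b, k in zip(blocks, keep) if k]
    orders = orders[keep]
    X = (raw - means) / sds

    cluster_index = cluster_categories = None
    if spec.cluster_effect and "cluster_id" in table.columns:
        codes, cats = pd.factorize(table["cluster_id"])
        cluster_index = codes.astype(int)
        cluster_categories = np.asarray(cats)

    return DesignMatrix(
        X=X,
        columns=names,
        col_block=blocks,
        col_order=orders,
        means=means,
        sds=sds,
        knots_used=knots_map,
        base_means=base_means,
        base_sds=base_sds,
        cluster_index=cluster_index,
        cluster_categories=cluster_categories,
        spec=spec,
    )
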