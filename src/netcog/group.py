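"""Hierarchical Bayesian group analysis of effective connectivity.

Subject-level EC posteriors (mean θ̂_i and variance σ_i² per connection)
are data for a group-level Gaussian GLM with random between-subject
effects:

    θ̂_i ~ N(x_iᵀ θ², σ_i² + v),      θ² ~ N(0, P),

where x_i is the subject's row of the design matrix (constant, ±1
diagnosis, centered age, gender, centered medication), v ≥ 0 is a
per-connection between-subject variance estimated by marginal maximum
likelihood, and P is a diagonal Gaussian prior — broad on the constant
column and a "precise null" (tight, zero-centered) on the effect columns,
which shrinks spurious effects and stringently adjusts for multiple
comparisons.  Inference per effect is the Gaussian posterior over θ²; a
connection is flagged when the equal-tailed credible interval excludes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .cohort import ECPosterior, ec_feature_names
from .layout import NetworkLayout

__all__ = ["DesignMatrix", "GroupEffectEstimate", "build_design",
           "HierarchicalBayesGLM", "fit_group_glm", "significant_effects"]

DESIGN_COLUMNS = ("constant", "diagnosis", "age", "gender", "medication")


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    column_names: tuple[str, ...]
    subject_ids: tuple[str, ...]


def build_design(
    covariate_table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "gender", "medication"),
) -> DesignMatrix:
    """Build the group design: constant, ±1 diagnosis, then covariates.

    Continuous covariates (age, medication) are mean-centered; gender is
    encoded 0/1 (M = 1).  SZ is coded +1, HC −1, so a diagnosis
    coefficient of c implies an SZ−HC difference of 2c.
    """
    required = {"subject_id", "group", *covariates}
    missing = required - set(covariate_table.columns)
    if missing:
        raise ValueError(f"covariate table missing columns {sorted(missing)}")
    if covariate_table[list(required)].isna().any().any():
        raise ValueError("covariate table contains missing values")
    cols = [np.ones(len(covariate_table))]
    names = ["constant", "diagnosis"]
    cols.append(np.where(covariate_table["group"] == "SZ", 1.0, -1.0))
    for c in covariates:
        v = covariate_table[c]
        if c == "gender":
            col = (v == "M").astype(float).to_numpy()
        else:
            col = v.to_numpy(dtype=float)
            col = col - col.mean()
        cols.append(col)
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix rank deficient; columns {names}")
    return DesignMatrix(matrix=X, column_names=tuple(names),
                        subject_ids=tuple(covariate_table["subject_id"]))


@dataclass
class GroupEffectEstimate:
    """Posterior group effects per connection and design column."""

    means: np.ndarray  # (n_connections, n_columns)
    sds: np.ndarray
    random_effect_var: np.ndarray  # (n_connections,)
    column_names: tuple[str, ...]
    feature_names: list[str]
    layout: NetworkLayout | None = None

    def column(self, name: str) -> int:
        return self.column_names.index(name)

    def diagnosis_difference(self) -> tuple[np.ndarray, np.ndarray]:
        """SZ−HC mean difference (2× the ±1-coded coefficient) and its SD."""
        j = self.column("diagnosis")
        return 2.0 * self.means[:, j], 2.0 * self.sds[:, j]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, fname in enumerate(self.feature_names):
            for j, cname in enumerate(self.column_names):
                rows.append((fname, cname, self.means[i, j], self.sds[i, j],
                             self.random_effect_var[i]))
        return pd.DataFrame(rows, columns=["connection", "column", "mean",
                                           "sd", "random_effect_var"])


class HierarchicalBayesGLM(BaseEstimator):
    """Random-effects Bayesian GLM over per-subject posterior summaries.

    Parameters
    ----------
    prior_var_constant, prior_var_effect : float
        Third-level prior variances: broad for the constant (group mean)
        column, tight ("precise null") for every effect column.
    random_effect : "estimate" or float
        Per-connection between-subject variance v; "estimate" maximizes
        the marginal likelihood over v >= 0, a float fixes it.

    Attributes
    ----------
    means_, sds_ : ndarray, (n_connections, n_columns)
        Gaussian posterior over the group effects.
    random_effect_var_ : ndarray, (n_connections,)
    """

    def __init__(self, prior_var_constant: float = 1.0,
                 prior_var_effect: float = 1.0 / 16.0,
                 random_effect: str | float = "estimate"):
        self.prior_var_constant = prior_var_constant
        self.prior_var_effect = prior_var_effect
        self.random_effect = random_effect

    def fit(self, theta: np.ndarray, theta_var: np.ndarray,
            design: DesignMatrix) -> "HierarchicalBayesGLM":
        """Fit per connection.

        ``theta``: (s, J) subject-level posterior means; ``theta_var``:
        matching posterior variances (> 0); ``design``: s-row design.
        """
        X = design.matrix
        s, c = X.shape
        theta = np.asarray(theta, dtype=float)
        theta_var = np.asarray(theta_var, dtype=float)
        if theta.ndim == 1:
            theta = theta[:, None]
            theta_var = theta_var[:, None]
        if theta.shape[0] != s or theta_var.shape != theta.shape:
            raise ValueError("theta/theta_var must be (n_subjects, J)")
        if np.any(theta_var <= 0):
            raise ValueError("subject posterior variances must be > 0")
        if s < c + 2:
            raise ValueError(f"need at least {c + 2} subjects for {c} "
                             "design columns")
        prior_var = np.full(c, self.prior_var_effect)
        prior_var[list(design.column_names).index("constant")] = \
            self.prior_var_constant
        P_inv = np.diag(1.0 / prior_var)

        J = theta.shape[1]
        means = np.empty((J, c))
        sds = np.empty((J, c))
        vs = np.empty(J)
        logdet_P = float(np.sum(np.log(prior_var)))
        for j in range(J):
            y = theta[:, j]
            sig2 = theta_var[:, j]

            def neg_marginal(v: float) -> float:
                d = sig2 + v
                Xw = X / d[:, None]
                M = P_inv + X.T @ Xw
                b = Xw.T @ y
                sign, logdet_M = np.linalg.slogdet(M)
                quad = y @ (y / d) - b @ np.linalg.solve(M, b)
                logdet_C = np.sum(np.log(d)) + logdet_M + logdet_P
                return 0.5 * (logdet_C + quad)

            if self.random_effect == "estimate":
                vmax = max(10.0 * float(np.var(y)), 1e-6)
                res = minimize_scalar(neg_marginal, bounds=(0.0, vmax),
                                      method="bounded",
                                      options={"xatol": 1e-10})
                v = max(float(res.x), 0.0)
                if neg_marginal(0.0) <= neg_marginal(v):
                    v = 0.0
            else:
                v = float(self.random_effect)
                if v < 0:
                    raise ValueError("fixed random-effect variance must "
                                     "be >= 0")
            d = sig2 + v
            Xw = X / d[:, None]
            M = P_inv + X.T @ Xw
            cov = np.linalg.inv(M)
            means[j] = cov @ (Xw.T @ y)
            sds[j] = np.sqrt(np.diag(cov))
            vs[j] = v
        self.means_ = means
        self.sds_ = sds
        self.random_effect_var_ = vs
        self.column_names_ = design.column_names
        return self


def fit_group_glm(
    posteriors: list[ECPosterior],
    covariate_table: pd.DataFrame,
    layout: NetworkLayout,
    covariates: tuple[str, ...] = ("age", "gender", "medication"),
    prior_var_constant: float = 1.0,
    prior_var_effect: float = 1.0 / 16.0,
    random_effect: str | float = "estimate",
) -> GroupEffectEstimate:
    """Fit the group GLM over all vectorized EC connections of a cohort."""
    order = {sid: i for i, sid in
             enumerate(covariate_table["subject_id"])}
    posteriors = sorted(posteriors, key=lambda p: order[p.subject_id])
    design = build_design(covariate_table, covariates=covariates)
    theta = np.vstack([p.vector(layout) for p in posteriors])
    theta_var = np.vstack([p.variance_vector(layout) for p in posteriors])
    est = HierarchicalBayesGLM(prior_var_constant=prior_var_constant,
                               prior_var_effect=prior_var_effect,
                               random_effect=random_effect)
    est.fit(theta, theta_var, design)
    return GroupEffectEstimate(
        means=est.means_, sds=est.sds_,
        random_effect_var=est.random_effect_var_,
        column_names=design.column_names,
        feature_names=ec_feature_names(layout), layout=layout)


def significant_effects(
    estimate: GroupEffectEstimate,
    credible_level: float = 0.95,
    column: str = "diagnosis",
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Flag connections whose credible interval excludes zero.

    Returns per-network binary matrices of flagged connections for the
    requested design column, and the per-network altered fraction
    (flagged / n² directed connections).
    """
    if not 0.0 < credible_level < 1.0:
        raise ValueError("credible_level must be in (0, 1)")
    if estimate.layout is None:
        raise ValueError("estimate carries no layout")
    z = stats.norm.ppf(0.5 + credible_level / 2.0)
    j = estimate.column(column)
    lo = estimate.means[:, j] - z * estimate.sds[:, j]
    hi = estimate.means[:, j] + z * estimate.sds[:, j]
    flagged = (lo > 0) | (hi < 0)

    masks: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    offset = 0
    for net, labels in estimate.layout.networks:
        n = len(labels)
        block = flagged[offset:offset + n * n].reshape(n, n)
        masks[net] = block.astype(int)
        fractions[net] = float(block.sum()) / (n * n)
        offset += n * n
    return masks, fractions
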