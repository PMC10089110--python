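"""Functional connectivity: per-subject matrices and group differences.

FC is the sample covariance (or correlation) of a subject's subnetwork
timeseries.  Group differences are assessed edgewise with ordinary least
squares — the FC entry regressed on an intercept, a ±1 diagnosis code and
covariates — with Benjamini–Hochberg FDR control across all unique edges
jointly and the display convention −sign(t)·log10(q) for q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .layout import NetworkLayout

__all__ = ["FCMatrix", "FCDifferenceMatrix", "compute_fc", "fc_group_diff",
           "fc_edge_counts"]


@dataclass
class FCMatrix:
    subject_id: str
    matrix: np.ndarray
    mode: str  # "covariance" or "correlation"


@dataclass
class FCDifferenceMatrix:
    """Edgewise diagnosis statistics arranged as symmetric matrices."""

    t_stats: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    display: np.ndarray
    n_significant: int
    edge_universe: int
    mode: str

    def long_table(self, labels: list[str] | None = None) -> pd.DataFrame:
        n = self.t_stats.shape[0]
        labels = labels or [str(i) for i in range(n)]
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((labels[i], labels[j], self.t_stats[i, j],
                             self.p_values[i, j], self.q_values[i, j],
                             self.display[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "t", "p",
                                           "q", "display"])


def compute_fc(timeseries: np.ndarray, mode: str = "covariance",
               subject_id: str = "", fisher: bool = False) -> FCMatrix:
    """Sample covariance (divisor n−1) or correlation of a timeseries.

    ``fisher`` applies the arctanh transform to off-diagonal correlations.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be 2-D with >= 2 timepoints")
    if np.isnan(ts).any():
        raise ValueError("timeseries contains missing values")
    cov = np.cov(ts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if mode == "covariance":
        return FCMatrix(subject_id=subject_id, matrix=cov, mode=mode)
    if mode != "correlation":
        raise ValueError(f"unknown mode {mode!r}")
    sd = np.sqrt(np.diag(cov))
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) {zero.tolist()} in "
                         "correlation mode")
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    if fisher:
        off = ~np.eye(corr.shape[0], dtype=bool)
        corr[off] = np.arctanh(np.clip(corr[off], -1 + 1e-15, 1 - 1e-15))
    return FCMatrix(subject_id=subject_id, matrix=corr, mode=mode)


def fc_group_diff(
    fc_set: list[FCMatrix],
    covariate_table: pd.DataFrame,
    covariate_columns: tuple[str, ...] = ("age", "gender", "medication"),
    alpha: float = 0.05,
) -> FCDifferenceMatrix:
    """Edgewise OLS of FC on diagnosis with covariate adjustment.

    ``covariate_table`` needs ``subject_id`` and ``group`` ("HC"/"SZ",
    coded −1/+1) plus the requested covariate columns; gender is encoded
    0/1 (M = 1).  Subjects with missing covariates are dropped.  The
    two-sided t-test on the diagnosis coefficient is corrected across all
    unique upper-triangle edges jointly (Benjamini–Hochberg).
    """
    table = covariate_table.set_index("subject_id")
    cols = ["group", *covariate_columns]
    table = table[cols].dropna()
    kept = [fc for fc in fc_set if fc.subject_id in table.index]
    if len(kept) < len(fc_set):
        import warnings
        warnings.warn(f"dropped {len(fc_set) - len(kept)} subjects with "
                      "missing covariates")
    groups = np.array([table.loc[fc.subject_id, "group"] for fc in kept])
    for g in ("HC", "SZ"):
        if (groups == g).sum() < 3:
            raise ValueError(f"need >= 3 subjects in group {g}")

    diag = np.where(groups == "SZ", 1.0, -1.0)
    X = [np.ones(len(kept)), diag]
    for c in covariate_columns:
        vals = table.loc[[fc.subject_id for fc in kept], c]
        if c == "gender":
            vals = (vals == "M").astype(float)
        X.append(np.asarray(vals, dtype=float))
    X = np.column_stack(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; check collinearity among "
            f"columns {['intercept', 'diagnosis', *covariate_columns]}")

    n = kept[0].matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    Y = np.vstack([fc.matrix[iu] for fc in kept])  # subjects × edges

    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough subjects for the design")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")

    disp = np.where(q < alpha, -np.sign(t) * np.log10(np.maximum(q, 1e-300)),
                    0.0)

    def to_matrix(vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        M = np.full((n, n), fill)
        M[iu] = vec
        M[(iu[1], iu[0])] = vec
        return M

    return FCDifferenceMatrix(
        t_stats=to_matrix(t), p_values=to_matrix(p, fill=1.0),
        q_values=to_matrix(q, fill=1.0), display=to_matrix(disp),
        n_significant=int((q < alpha).sum()), edge_universe=len(p),
        mode=kept[0].mode)


def fc_edge_counts(layout: NetworkLayout) -> dict[str, int]:
    """Unique undirected pair counts: total, within- and between-network."""
    n = layout.n_subnetworks
    total = n * (n - 1) // 2
    within = sum(k * (k - 1) // 2 for k in layout.sizes.values())
    return {"total": total, "within": within, "between": total - within}
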