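"""Brain-behavior canonical correlation analysis with ensemble selection.

Covariate-adjusted CCA between effective-connectivity parameters (X) and
cognitive domain scores (Y): canonical correlations via SVD of the
whitened cross-covariance; Wilks' Λ = Π(1−r_i²) with Bartlett χ² and Rao F
approximations and permutation inference; partial-Λ forward selection on X
and backward elimination on Y; bootstrap-aggregated (bagged) selection with
per-feature inclusion frequencies; and repeated k-fold cross-validation of
the out-of-sample first canonical correlation with in-fold re-selection.

The stepwise machinery exploits the identity that the partial Λ of a
candidate, given a selected set, equals 1 − R² of the candidate
residualized on the selected set against the other variable set
residualized the same way; this is algebraically equal to the Λ_full/Λ_reduced
ratio and is what makes bagging over hundreds of candidates tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CCAModel", "WilksResult", "SelectionResult", "CVResult",
    "residualize", "CanonicalCorrelation", "cca_fit", "wilks_lambda",
    "lambda_tests", "perm_cca_test", "partial_lambda", "forward_select",
    "backward_eliminate", "EnsembleCCASelector", "ensemble_select",
    "cv_cca",
]


# ---------------------------------------------------------------------------
# core CCA


@dataclass
class CCAModel:
    canonical_correlations: np.ndarray  # descending, in [0, 1]
    x_weights: np.ndarray  # (q, m) standardized weights
    y_weights: np.ndarray  # (p, m)
    x_variates: np.ndarray  # (s, m), unit sample variance
    y_variates: np.ndarray
    n_samples: int
    n_x: int
    n_y: int


def residualize(data: np.ndarray, covariates: np.ndarray | None
                ) -> np.ndarray:
    """Replace each column by its OLS residual on [intercept, covariates].

    With ``covariates=None`` this is column demeaning.  The output is
    orthogonal to the covariates and the operation is idempotent.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        Z = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank "
                         "deficient")
    Q, _ = np.linalg.qr(Z)
    return data - Q @ (Q.T @ data)


def _zscore(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column(s): "
                         f"{np.flatnonzero(sd == 0).tolist()}")
    return (M - mean) / sd, mean, sd


def _inv_sqrt(S: np.ndarray, ridge: float) -> np.ndarray:
    S = S + ridge * np.eye(S.shape[0])
    vals, vecs = np.linalg.eigh(S)
    if vals.min() <= 1e-12 * max(vals.max(), 1.0):
        raise np.linalg.LinAlgError
    return vecs * (1.0 / np.sqrt(vals)) @ vecs.T


class CanonicalCorrelation(BaseEstimator):
    """CCA via SVD of the whitened cross-covariance.

    Columns are z-scored internally; reported weights are standardized
    weights scaled so the canonical variates have unit sample variance.
    The sign convention makes the largest-magnitude x-weight of each
    component positive.

    Parameters
    ----------
    ridge : float
        Regularization added to the within-set covariances; 0 by default,
        auto-escalated to 1e-8 with a warning if a within-set covariance
        is numerically singular.

    Attributes
    ----------
    canonical_correlations_ : ndarray, descending in [0, 1]
    x_weights_, y_weights_ : ndarray
    x_variates_, y_variates_ : ndarray
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "CanonicalCorrelation":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        s, q = X.shape
        p = Y.shape[1]
        if s <= q + p:
            warnings.warn(f"sample size {s} <= q + p = {q + p}; canonical "
                          "correlations will be unstable")
        Zx, self.x_mean_, self.x_sd_ = _zscore(X)
        Zy, self.y_mean_, self.y_sd_ = _zscore(Y)
        Sxx = Zx.T @ Zx / (s - 1)
        Syy = Zy.T @ Zy / (s - 1)
        Sxy = Zx.T @ Zy / (s - 1)
        ridge = self.ridge
        try:
            Wx = _inv_sqrt(Sxx, ridge)
            Wy = _inv_sqrt(Syy, ridge)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                warnings.warn("singular within-set covariance; escalating "
                              "ridge to 1e-8")
                Wx = _inv_sqrt(Sxx, 1e-8)
                Wy = _inv_sqrt(Syy, 1e-8)
            else:
                raise ValueError("singular within-set covariance; increase "
                                 "the ridge parameter")
        U, svals, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
        m = min(q, p)
        r = np.clip(svals[:m], 0.0, 1.0)
        a = Wx @ U[:, :m]
        b = Wy @ Vt.T[:, :m]
        # sign convention: largest-|a| entry positive per component
        for i in range(m):
            j = int(np.argmax(np.abs(a[:, i])))
            if a[j, i] < 0:
                a[:, i] *= -1
                b[:, i] *= -1
        self.canonical_correlations_ = r
        self.x_weights_ = a
        self.y_weights_ = b
        self.x_variates_ = Zx @ a
        self.y_variates_ = Zy @ b
        self.n_samples_, self.n_x_, self.n_y_ = s, q, p
        return self

    def transform(self, X: np.ndarray, Y: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Project new rows using the training standardization and weights."""
        Zx = (np.atleast_2d(X) - self.x_mean_) / self.x_sd_
        Zy = (np.atleast_2d(Y) - self.y_mean_) / self.y_sd_
        return Zx @ self.x_weights_, Zy @ self.y_weights_

    def to_model(self) -> CCAModel:
        return CCAModel(
            canonical_correlations=self.canonical_correlations_,
            x_weights=self.x_weights_, y_weights=self.y_weights_,
            x_variates=self.x_variates_, y_variates=self.y_variates_,
            n_samples=self.n_samples_, n_x=self.n_x_, n_y=self.n_y_)


def cca_fit(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> CCAModel:
    """Fit CCA and return the model container; see
    :class:`CanonicalCorrelation`."""
    return CanonicalCorrelation(ridge=ridge).fit(X, Y).to_model()


# ---------------------------------------------------------------------------
# Wilks' Lambda inference


@dataclass
class WilksResult:
    lambdas: np.ndarray  # Λ_k for k = 1..m
    chi2: np.ndarray
    chi2_df: np.ndarray
    chi2_p: np.ndarray
    f_stat: np.ndarray
    f_df1: np.ndarray
    f_df2: np.ndarray
    f_p: np.ndarray
    n_significant: int
    alpha: float


def wilks_lambda(r: np.ndarray, k: int = 1) -> float:
    """Λ_k = Π_{i>=k} (1 − r_i²) over canonical correlations (1-based k)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("canonical correlations must lie in [0, 1]")
    if not 1 <= k <= len(r):
        raise ValueError("k out of range")
    return float(np.prod(1.0 - r[k - 1:] ** 2))


def lambda_tests(r: np.ndarray, dims: tuple[int, int, int],
                 alpha: float = 0.05) -> WilksResult:
    """Bartlett χ² and Rao F approximations for sequential Λ tests.

    ``dims`` is (s, q, p).  For start index k, the Bartlett statistic is
    −(s − 1 − (q + p + 1)/2)·ln Λ_k with (q−k+1)(p−k+1) degrees of
    freedom; Rao's F uses its standard transformation.  ``n_significant``
    counts the leading correlations whose sequential Bartlett test rejects
    at ``alpha``.
    """
    s, q, p = dims
    if s < (q + p) / 2 + 2 or q < 1 or p < 1:
        raise ValueError(f"invalid dims {dims}")
    r = np.asarray(r, dtype=float)
    m = min(q, p)
    if len(r) < m:
        raise ValueError("need min(q, p) canonical correlations")
    lambdas = np.array([wilks_lambda(r[:m], k) for k in range(1, m + 1)])
    chi2 = np.empty(m)
    chi2_df = np.empty(m)
    f_stat = np.empty(m)
    f_df1 = np.empty(m)
    f_df2 = np.empty(m)
    for i, k in enumerate(range(1, m + 1)):
        a, b = q - k + 1, p - k + 1
        mult = s - 1 - (a + b + 1) / 2.0
        lam = max(lambdas[i], np.finfo(float).tiny)
        chi2[i] = -mult * np.log(lam)
        chi2_df[i] = a * b
        denom = a * a + b * b - 5
        t = np.sqrt((a * a * b * b - 4.0) / denom) if denom > 0 else 1.0
        df1 = a * b
        df2 = mult * t - a * b / 2.0 + 1.0
        lam_t = lam ** (1.0 / t)
        f_stat[i] = (1.0 - lam_t) / lam_t * (df2 / df1)
        f_df1[i] = df1
        f_df2[i] = df2
    chi2_p = stats.chi2.sf(chi2, chi2_df)
    f_p = stats.f.sf(f_stat, f_df1, np.maximum(f_df2, 1e-9))
    n_sig = 0
    for pv in chi2_p:
        if pv < alpha:
            n_sig += 1
        else:
            break
    return WilksResult(lambdas=lambdas, chi2=chi2, chi2_df=chi2_df,
                       chi2_p=chi2_p, f_stat=f_stat, f_df1=f_df1,
                       f_df2=f_df2, f_p=f_p, n_significant=n_sig,
                       alpha=alpha)


def perm_cca_test(X: np.ndarray, Y: np.ndarray, B: int = 999,
                  rng: np.random.Generator | int | None = None,
                  ridge: float = 0.0) -> float:
    """Permutation p-value for the first canonical correlation.

    Rows of Y are permuted B times; p = (1 + #{r1_perm >= r1_obs})/(B+1).
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model = cca_fit(X, Y, ridge=ridge)
    r_obs = model.canonical_correlations[0]
    Y = np.asarray(Y, dtype=float)
    count = 0
    for _ in range(B):
        perm = rng.permutation(Y.shape[0])
        r_perm = cca_fit(X, Y[perm], ridge=ridge).canonical_correlations[0]
        if r_perm >= r_obs:
            count += 1
    return (1.0 + count) / (B + 1.0)


# ---------------------------------------------------------------------------
# stepwise selection


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _partial_lambda_fast(selected: np.ndarray | None,
                         candidates: np.ndarray,
                         other: np.ndarray) -> np.ndarray:
    """Partial Λ of each candidate column given the selected set.

    Equals 1 − R² of the candidate, residualized on [1, selected], against
    the other set residualized the same way.  Candidates that lie in the
    span of the selected set return Λ = 1 (no added information).
    """
    n = candidates.shape[0]
    if selected is None or selected.shape[1] == 0:
        C = _center(candidates)
        O = _center(other)
    else:
        Z = np.column_stack([np.ones(n), selected])
        Q, _ = np.linalg.qr(Z)
        C = candidates - Q @ (Q.T @ candidates)
        O = other - Q @ (Q.T @ other)
    Qo, Ro = np.linalg.qr(O)
    keep = np.abs(np.diag(Ro)) > 1e-10 * max(1.0, np.abs(Ro).max())
    Qo = Qo[:, keep]
    denom = (C ** 2).sum(axis=0)
    proj = Qo.T @ C
    num = (proj ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 1e-12 * max(denom.max(), 1.0),
                      num / denom, 0.0)
    return np.clip(1.0 - r2, 0.0, 1.0)


def partial_lambda(X_selected: np.ndarray, x_candidate: np.ndarray,
                   Y: np.ndarray) -> tuple[float, float]:
    """Partial Wilks Λ and partial F for adding one x to a selected set.

    Computed as the explicit ratio Λ_full / Λ_reduced of the Wilks
    statistics of the two nested CCA models.  The partial F for a single
    added variable is ((1 − Λ)/Λ)·((s − m − p)/p) with m the number of x's
    in the fuller model and p the number of y's, on (p, s − m − p)
    degrees of freedom.
    """
    X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
    if X_selected.shape[1] == 0:
        lam_r = 1.0
    else:
        r_red = cca_fit(X_selected, Y).canonical_correlations
        lam_r = wilks_lambda(r_red)
    x_candidate = np.asarray(x_candidate, dtype=float).reshape(-1, 1)
    for col in X_selected.T:
        if np.allclose(col, x_candidate.ravel()):
            raise ValueError("candidate already selected")
    X_full = np.column_stack([X_selected, x_candidate])
    r_full = cca_fit(X_full, Y).canonical_correlations
    lam_f = wilks_lambda(r_full)
    if lam_r <= 0:
        raise ValueError("reduced-model Lambda is zero; partial Lambda "
                         "undefined")
    lam = lam_f / lam_r
    s = X_full.shape[0]
    m = X_full.shape[1]
    p = np.atleast_2d(Y).shape[1]
    df2 = s - m - p
    if df2 <= 0:
        raise ValueError("not enough samples for the partial F test")
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    f = (1.0 - lam) / lam * (df2 / p)
    return lam, f


def forward_select(X: np.ndarray, Y: np.ndarray, max_features: int,
                   f_threshold: float = 1.0,
                   n_effective: int | None = None) -> list[int]:
    """Greedy forward selection of x columns by minimum (partial) Λ.

    At each step the candidate minimizing the partial Λ (given the current
    set) is taken; selection stops at ``max_features`` or when the
    candidate's partial F falls below ``f_threshold``.  Ties break toward
    the lowest column index.  ``n_effective`` overrides the sample size in
    the F statistic (used for bootstrap resamples, where duplicated rows
    carry no information).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    s, q = X.shape
    if n_effective is not None:
        s = int(n_effective)
    p = Y.shape[1]
    selected: list[int] = []
    remaining = list(range(q))
    while remaining and len(selected) < max_features:
        sel = X[:, selected] if selected else None
        lams = _partial_lambda_fast(sel, X[:, remaining], Y)
        best = int(np.argmin(lams))
        lam = float(lams[best])
        m = len(selected) + 1
        df2 = s - m - p
        if df2 <= 0:
            break
        lam_c = min(max(lam, np.finfo(float).tiny), 1.0)
        f = (1.0 - lam_c) / lam_c * (df2 / p)
        if f < f_threshold:
            break
        selected.append(remaining.pop(best))
    return selected


def backward_eliminate(Y: np.ndarray, X_selected: np.ndarray,
                       alpha: float = 0.05,
                       n_effective: int | None = None) -> list[int]:
    """Backward elimination of y columns by maximum partial Λ.

    Iteratively removes the y whose partial Λ (given the remaining y's) is
    largest, as long as its partial F test is non-significant at
    ``alpha``; stops when the largest partial Λ is significant.  Raises if
    every y is eliminated (no multivariate relation).  ``n_effective``
    overrides the sample size in the F statistic (see
    :func:`forward_select`).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
    s = Y.shape[0] if n_effective is None else int(n_effective)
    qp = X_selected.shape[1]
    retained = list(range(Y.shape[1]))
    if not retained:
        raise ValueError("need at least one y column")
    while retained:
        lams = np.empty(len(retained))
        for pos, j in enumerate(retained):
            others = [jj for jj in retained if jj != j]
            sel = Y[:, others] if others else None
            lams[pos] = _partial_lambda_fast(sel, Y[:, [j]], X_selected)[0]
        pos = int(np.argmax(lams))
        lam = float(min(max(lams[pos], np.finfo(float).tiny), 1.0))
        p_cur = len(retained)
        df2 = s - p_cur - qp
        if df2 <= 0:
            raise ValueError("not enough samples for the partial F test")
        f = (1.0 - lam) / lam * (df2 / qp)
        p_val = stats.f.sf(f, qp, df2)
        if p_val < alpha:
            break  # the least informative remaining y is significant
        retained.pop(pos)
    if not retained:
        raise ValueError("all y variables eliminated: no multivariate "
                         "relation detected")
    return retained


# ---------------------------------------------------------------------------
# ensemble (bagged) selection


@dataclass
class SelectionResult:
    x_frequency: np.ndarray
    y_frequency: np.ndarray
    top_x: list[int]
    top_y: list[int]
    per_resample_x: list[list[int]] = field(repr=False)
    per_resample_y: list[list[int]] = field(repr=False)
    n_resamples: int = 0
    n_skipped: int = 0


class EnsembleCCASelector(BaseEstimator):
    """Bootstrap-aggregated stepwise feature selection for CCA.

    Each of ``n_resamples`` bootstrap resamples of the subjects runs
    forward selection on X (capped at ``max(1, floor(cap_fraction·q))``
    features) followed by backward elimination on Y.  Inclusion
    frequencies are the proportion of resamples selecting each feature.
    Top sets are chosen by frequency (``n_top_x``/``n_top_y``, ties toward
    lower index), then trimmed from the low-frequency end until the total
    satisfies the sample-to-feature ratio >= 9.

    Attributes
    ----------
    x_frequency_, y_frequency_ : ndarray in [0, 1]
    top_x_, top_y_ : list of selected column indices
    """

    def __init__(self, n_resamples: int = 200, cap_fraction: float = 0.05,
                 n_top_x: int = 3, n_top_y: int = 3,
                 f_threshold: float = 1.0, alpha: float = 0.05,
                 seed: int = 0):
        self.n_resamples = n_resamples
        self.cap_fraction = cap_fraction
        self.n_top_x = n_top_x
        self.n_top_y = n_top_y
        self.f_threshold = f_threshold
        self.alpha = alpha
        self.seed = seed

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "EnsembleCCASelector":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not 0.0 < self.cap_fraction <= 1.0:
            raise ValueError("cap_fraction must be in (0, 1]")
        s, q = X.shape
        p = Y.shape[1]
        cap_frac = max(1, int(np.floor(self.cap_fraction * q)))
        x_count = np.zeros(q)
        y_count = np.zeros(p)
        logs_x: list[list[int]] = []
        logs_y: list[list[int]] = []
        skipped = 0
        for b in range(self.n_resamples):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 41, b]))
            idx = rng.integers(0, s, size=s)
            Xb, Yb = X[idx], Y[idx]
            if (Xb.std(axis=0) == 0).any() or (Yb.std(axis=0) == 0).any():
                skipped += 1
                logs_x.append([])
                logs_y.append([])
                continue
            n_eff = len(np.unique(idx))
            # sample-to-feature >= 9 during selection: x's plus the p y's
            # count against the unique-subject budget of the resample
            cap = max(1, min(cap_frac, n_eff // 9 - p))
            try:
                x_sel = forward_select(Xb, Yb, max_features=cap,
                                       f_threshold=self.f_threshold,
                                       n_effective=n_eff)
                if not x_sel:
                    raise ValueError("empty forward selection")
                y_sel = backward_eliminate(Yb, Xb[:, x_sel],
                                           alpha=self.alpha,
                                           n_effective=n_eff)
            except ValueError:
                skipped += 1
                logs_x.append([])
                logs_y.append([])
                continue
            x_count[x_sel] += 1
            y_count[y_sel] += 1
            logs_x.append(x_sel)
            logs_y.append(y_sel)
        self.x_frequency_ = x_count / self.n_resamples
        self.y_frequency_ = y_count / self.n_resamples
        top_x = list(np.argsort(-self.x_frequency_,
                                kind="stable")[:self.n_top_x])
        top_y = list(np.argsort(-self.y_frequency_,
                                kind="stable")[:self.n_top_y])
        budget = s // 9
        while top_x and top_y and len(top_x) + len(top_y) > budget:
            fx = self.x_frequency_[top_x[-1]]
            fy = self.y_frequency_[top_y[-1]]
            if fx <= fy and len(top_x) > 1:
                top_x.pop()
            elif len(top_y) > 1:
                top_y.pop()
            else:
                top_x.pop()
        self.top_x_ = [int(i) for i in top_x]
        self.top_y_ = [int(i) for i in top_y]
        self.n_skipped_ = skipped
        self.per_resample_x_ = logs_x
        self.per_resample_y_ = logs_y
        return self

    def to_result(self) -> SelectionResult:
        return SelectionResult(
            x_frequency=self.x_frequency_, y_frequency=self.y_frequency_,
            top_x=self.top_x_, top_y=self.top_y_,
            per_resample_x=self.per_resample_x_,
            per_resample_y=self.per_resample_y_,
            n_resamples=self.n_resamples, n_skipped=self.n_skipped_)


def ensemble_select(X: np.ndarray, Y: np.ndarray, n_resamples: int = 200,
                    cap_fraction: float = 0.05,
                    rng: np.random.Generator | int | None = None,
                    **kwargs) -> SelectionResult:
    """Functional wrapper over :class:`EnsembleCCASelector`."""
    seed = rng if isinstance(rng, int) else 0
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2 ** 31 - 1))
    sel = EnsembleCCASelector(n_resamples=n_resamples,
                              cap_fraction=cap_fraction, seed=seed, **kwargs)
    return sel.fit(X, Y).to_result()


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    correlations: np.ndarray  # (n_repeats, k)
    mean: float
    interval: tuple[float, float]  # 95% percentile interval of repeat means
    k: int
    n_repeats: int
    seed: int | None


def cv_cca(X: np.ndarray, Y: np.ndarray, k: int = 5, n_repeats: int = 100,
           rng: np.random.Generator | int | None = None,
           selector=None, ridge: float = 0.0) -> CVResult:
    """Repeated k-fold cross-validation of the first canonical correlation.

    Per repeat the subjects are randomly partitioned into k folds; the
    model (including feature selection, if a ``selector`` callable
    ``(X_train, Y_train) -> (x_idx, y_idx)`` is given) is built on the
    training folds, and the training weights — with training
    standardization — are applied to the held-out fold, recording the
    test-fold correlation of the first canonical variate pair.  Reported
    are the per-repeat fold means, their overall mean, and the 95%
    percentile interval across repeats.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    s = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if s < 2 * k:
        raise ValueError("need at least 2k samples")
    seed = rng if isinstance(rng, int) or rng is None else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fold_corrs = np.empty((n_repeats, k))
    for rep in range(n_repeats):
        perm = rng.permutation(s)
        folds = np.array_split(perm, k)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            Xtr, Ytr = X[train_idx], Y[train_idx]
            Xte, Yte = X[test_idx], Y[test_idx]
            if selector is not None:
                x_idx, y_idx = selector(Xtr, Ytr)
                Xtr, Ytr = Xtr[:, x_idx], Ytr[:, y_idx]
                Xte, Yte = Xte[:, x_idx], Yte[:, y_idx]
            if len(test_idx) <= max(Xtr.shape[1], Ytr.shape[1]):
                raise ValueError("test fold smaller than the feature "
                                 "count; use a smaller k")
            est = CanonicalCorrelation(ridge=ridge).fit(Xtr, Ytr)
            u, v = est.transform(Xte, Yte)
            u1, v1 = u[:, 0], v[:, 0]
            if u1.std() == 0 or v1.std() == 0:
                fold_corrs[rep, fi] = 0.0
            else:
                fold_corrs[rep, fi] = np.corrcoef(u1, v1)[0, 1]
    repeat_means = fold_corrs.mean(axis=1)
    lo, hi = np.percentile(repeat_means, [2.5, 97.5])
    return CVResult(correlations=fold_corrs,
                    mean=float(fold_corrs.mean()),
                    interval=(float(lo), float(hi)), k=k,
                    n_repeats=n_repeats,
                    seed=seed if isinstance(seed, int) else None)
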