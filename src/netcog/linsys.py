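"""Linear stochastic network primitives.

The latent dynamics of one network are modelled as a multivariate
Ornstein-Uhlenbeck (OU) process

    dx = A x dt + dW,   Cov(dW) = Q dt,

with ``A`` the effective-connectivity rate matrix in Hz.  Off-diagonal
(extrinsic) entries of ``A`` are free; diagonal (self) connections are
parametrized as log scalings ``a_ii`` of an inhibitory −0.5 Hz prior, i.e.
the effective diagonal is −0.5·exp(a_ii) < 0, which guarantees
self-inhibition.  Stability means all eigenvalues of ``A`` have negative
real part; the stationary covariance then solves the continuous Lyapunov
equation A Σ + Σ Aᵀ + Q = 0.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

__all__ = [
    "self_connection_hz",
    "effective_matrix",
    "spectral_abscissa",
    "is_stable",
    "stationary_covariance",
    "discretize_ou",
    "simulate_ou",
]

SELF_PRIOR_HZ = -0.5


def self_connection_hz(a: float) -> float:
    """Convert a log-scaling self-connection parameter to a rate in Hz.

    The self-connection prior is −0.5 Hz; a log-scaling value ``a`` yields
    −0.5·exp(a), which is strictly negative (inhibitory) for any finite
    ``a``.  ``a = 0`` returns the prior value −0.5 Hz.
    """
    a = float(a)
    if not np.isfinite(a):
        raise ValueError("self-connection log-scaling must be finite")
    return SELF_PRIOR_HZ * np.exp(a)


def effective_matrix(ec: np.ndarray) -> np.ndarray:
    """Convert an EC parameter matrix to the effective rate matrix in Hz.

    Off-diagonal entries are already rates in Hz and pass through; diagonal
    entries are log-scaling parameters converted via −0.5·exp(a_ii).
    """
    ec = np.asarray(ec, dtype=float)
    if ec.ndim != 2 or ec.shape[0] != ec.shape[1]:
        raise ValueError("EC matrix must be square")
    A = ec.copy()
    np.fill_diagonal(A, SELF_PRIOR_HZ * np.exp(np.diag(ec)))
    return A


def spectral_abscissa(A: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(A).real))


def is_stable(A: np.ndarray, tol: float = 0.0) -> bool:
    return spectral_abscissa(A) < -tol


def stationary_covariance(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve A Σ + Σ Aᵀ + Q = 0 for the stationary covariance Σ."""
    if not is_stable(A):
        raise ValueError("A must be stable (all eigenvalue real parts < 0)")
    sigma = solve_continuous_lyapunov(A, -np.asarray(Q, dtype=float))
    return 0.5 * (sigma + sigma.T)


def discretize_ou(A: np.ndarray, Q: np.ndarray, dt: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact discretization of the OU process at sampling interval ``dt``.

    Returns ``(F, W, sigma_inf)`` such that x_{k+1} = F x_k + w_k with
    F = exp(A dt), w_k ~ N(0, W), W = Σ∞ − F Σ∞ Fᵀ.  Exactness follows
    from the OU transition density, so there is no step-size bias.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = np.asarray(A, dtype=float)
    sigma_inf = stationary_covariance(A, Q)
    F = expm(A * dt)
    W = sigma_inf - F @ sigma_inf @ F.T
    W = 0.5 * (W + W.T)
    return F, W, sigma_inf


def _sqrt_psd(M: np.ndarray) -> np.ndarray:
    # symmetric PSD square root, tolerant of tiny negative eigenvalues
    vals, vecs = np.linalg.eigh(M)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals) @ vecs.T


def simulate_ou(A: np.ndarray, Q: np.ndarray, dt: float, n_timepoints: int,
                rng: np.random.Generator) -> np.ndarray:
    """Simulate a stationary OU path sampled at interval ``dt``.

    The initial state is drawn from the stationary distribution and the
    transition uses the exact discretization, so every finite sample has
    exactly the stationary marginal covariance in expectation.

    Returns an ``(n_timepoints, n)`` array.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    F, W, sigma_inf = discretize_ou(A, Q, dt)
    n = A.shape[0]
    L0 = _sqrt_psd(sigma_inf)
    Lw = _sqrt_psd(W)
    x = np.empty((n_timepoints, n))
    x[0] = L0 @ rng.standard_normal(n)
    noise = rng.standard_normal((n_timepoints - 1, n)) @ Lw.T
    for k in range(1, n_timepoints):
        x[k] = F @ x[k - 1] + noise[k - 1]
    return x
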