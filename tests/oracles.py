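"""Independent numerical oracles for the marginal likelihood and Bayes factor.

These deliberately avoid the package's analytic route (centering / reduced
problem): the coefficient block is integrated in the full design space with
an explicit flat intercept, and the noise variance is integrated numerically
(adaptive quadrature on the log-variance axis) or by importance sampling.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve
from scipy.special import logsumexp


def _conditional_log_ml(y: np.ndarray, X: np.ndarray, sigma_i) -> tuple[float, float]:
    """Pieces of log p(y | sigma^2): returns (const, S) with

    log p(y | s2) = -((m-1)/2) * log(2*pi*s2) + const - S / (2*s2),

    obtained by integrating the coefficients (flat intercept, N(0, s2*Sigma1)
    slopes) in the uncentred design space.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    m, ncol = X.shape
    k = ncol - 1
    s = np.atleast_1d(np.asarray(sigma_i, float))
    var_i = np.full(k, s[0] ** 2) if s.size == 1 else s[:k] ** 2
    P = np.zeros((ncol, ncol))
    if k:
        P[1:, 1:] = np.diag(1.0 / var_i)
    A = X.T @ X + P
    S = float(y @ y - y @ X @ solve(A, X.T @ y, assume_a="pos"))
    sign, logdet_a = np.linalg.slogdet(A)
    assert sign > 0
    const = -0.5 * logdet_a - 0.5 * float(np.sum(np.log(var_i)))
    return const, S


def log_ml_quadrature(y: np.ndarray, X: np.ndarray, sigma_i=1.0) -> float:
    """Log marginal likelihood by adaptive quadrature over t = log sigma^2.

    The scale-reference prior p(s2) ∝ 1/s2 turns into a flat measure dt.
    """
    m = np.asarray(y).size
    const, S = _conditional_log_ml(y, X, sigma_i)
    nu = m - 1

    def log_integrand(t: float) -> float:
        s2 = np.exp(t)
        return -0.5 * nu * (np.log(2.0 * np.pi) + t) + const - S / (2.0 * s2)

    t_star = np.log(S / nu)  # stationary point of the integrand
    f_star = log_integrand(t_star)
    val, _err = quad(
        lambda t: np.exp(log_integrand(t) - f_star), t_star - 60, t_star + 60, limit=400
    )
    return float(f_star + np.log(val))


def log_bf_quadrature(y: np.ndarray, X: np.ndarray, sigma_i=1.0) -> float:
    null = np.asarray(X, dtype=float)[:, :1]
    return log_ml_quadrature(y, X, sigma_i) - log_ml_quadrature(y, null, sigma_i)


def log_bf_importance_sampling(
    y: np.ndarray, X: np.ndarray, sigma_i=1.0, n_draws: int = 200_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo Bayes factor with importance weights, plus its standard error.

    The reference prior p(s2) ∝ 1/s2 is flat on the t = log s2 axis, so the
    proposal is uniform on a wide bracket around both models' residual
    scales: importance weights are then constant within the bracket and its
    (improper) normalizing constant cancels in the ratio of the two marginal
    likelihoods.  Returns (log_bf_hat, se_log_bf).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    m = y.size
    nu = m - 1
    const_a, S_a = _conditional_log_ml(y, X, sigma_i)
    const_0, S_0 = _conditional_log_ml(y, X[:, :1], sigma_i)
    lo = min(np.log(S_a / nu), np.log(S_0 / nu)) - 15.0
    hi = max(np.log(S_a / nu), np.log(S_0 / nu)) + 15.0
    t = rng.uniform(lo, hi, size=n_draws)
    s2 = np.exp(t)

    def log_p(const, S):
        return -0.5 * nu * np.log(2.0 * np.pi * s2) + const - S / (2.0 * s2)

    la = log_p(const_a, S_a)
    lb = log_p(const_0, S_0)
    ref = max(la.max(), lb.max())
    a = np.exp(la - ref)
    b = np.exp(lb - ref)
    log_bf = float(logsumexp(la) - logsumexp(lb))
    abar, bbar = a.mean(), b.mean()
    cov = np.cov(a, b)
    var_log = (
        cov[0, 0] / abar**2 + cov[1, 1] / bbar**2 - 2.0 * cov[0, 1] / (abar * bbar)
    ) / n_draws
    return log_bf, float(np.sqrt(max(var_log, 0.0)))


def auc_pair_counting(positives, controls) -> float:
    """Exhaustive Mann–Whitney AUC: wins + half-ties over all pairs."""
    wins = 0.0
    for p in positives:
        for c in controls:
            if p < c:
                wins += 1.0
            elif p == c:
                wins += 0.5
    return wins / (len(positives) * len(controls))
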