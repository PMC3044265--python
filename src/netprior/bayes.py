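"""Bayes factors for the phenotype-similarity regression.

Model
-----
The phenotype similarity vector of a query disease, y (length m), is
explained linearly by gene proximity vectors collected in a design matrix
X = [1, x_1, ..., x_k] whose first column is the intercept:

    y | beta, sigma^2  ~  Normal(X beta, sigma^2 I_m).

Conjugate priors are placed on the coefficients and the noise variance:

    beta | sigma^2  ~  Normal(0, sigma^2 Sigma),   Sigma = diag(s0^2, s1^2, ..., sk^2)
    p(sigma^2)      ∝  1 / sigma^2,

with the intercept prior taken flat (s0 -> +infinity) and s_i = 1 for the
proximity coefficients by default.  The reference prior on sigma^2 (the
vague limit of the conjugate inverse-gamma) makes the Bayes factor invariant
to rescaling of y, and the flat intercept makes it invariant to shifts —
the score does not depend on the units in which disease similarities are
measured.

Marginal likelihood
-------------------
The flat-intercept limit is handled analytically, never by plugging in a
large finite s0: projecting onto the orthogonal complement of the constant
vector centres y and the non-intercept columns of X and leaves nu = m - 1
effective observations.  Writing y~ and X~ for the centred quantities,
Sigma_1 = diag(s1^2, ..., sk^2), A = X~' X~ + Sigma_1^{-1} and

    |V| = |A| * |Sigma_1|,
    S   = y~' y~  -  y~' X~ A^{-1} X~' y~  ( = y~' (I + X~ Sigma_1 X~')^{-1} y~ ),

integrating out beta and sigma^2 in closed form gives

    log p(y | X) = -(nu/2) log(2 pi) - (1/2) log m + log Gamma(nu/2)
                   + (nu/2) log 2 - (1/2) log |V| - (nu/2) log S.

(The additive constant from the improper priors is fixed by this convention
and cancels in any Bayes factor.)  The null model is the intercept-only
design, for which |V| = 1 and S = y~' y~, so

    log BF = -(1/2) log |V| + (nu/2) [ log S_null - log S_alt ].

A is positive definite by construction even when X has collinear or all-zero
columns (the proper prior regularizes it), so no pseudo-inverse and no
column dropping is ever needed; an all-zero proximity column yields BF = 1
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

__all__ = ["ConjugatePrior", "BayesScore", "log_marginal_likelihood", "bayes_factor"]


@dataclass(frozen=True)
class ConjugatePrior:
    """Prior settings for the regression coefficients.

    ``sigma_i`` is the prior standard deviation (relative to sigma) of each
    non-intercept coefficient; a scalar is broadcast over all columns.  The
    intercept prior is always flat (sigma_0 -> +infinity) and the prior means
    are zero, encoding no prior association.
    """

    sigma_i: float | np.ndarray = 1.0

    def variances(self, k: int) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.sigma_i, dtype=float))
        if s.size == 1:
            s = np.full(k, float(s[0]))
        if s.size != k:
            raise ValueError(f"sigma_i has {s.size} entries for {k} non-intercept columns")
        if np.any(s <= 0):
            raise ValueError("sigma_i must be positive")
        return s**2


@dataclass(frozen=True)
class BayesScore:
    """Log marginal likelihoods of the two models and their ratio."""

    log_ml_alt: float
    log_ml_null: float

    @property
    def log_bf(self) -> float:
        return self.log_ml_alt - self.log_ml_null

    @property
    def bf(self) -> float:
        try:
            return math.exp(self.log_bf)
        except OverflowError:
            return math.inf


def _validate_design(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-d matrix with at least the intercept column")
    if X.shape[0] != y.size:
        raise ValueError("rows of X must align with entries of y")
    if not np.all(X[:, 0] == 1.0):
        raise ValueError("first column of X must be the all-ones intercept")
    return y, X


def _log_ml_centered(yc: np.ndarray, Xc: np.ndarray, var_i: np.ndarray) -> float:
    """Log marginal likelihood from centred data; shared fast path."""
    m = yc.size
    nu = m - 1
    ss_y = float(yc @ yc)
    if ss_y <= 0.0:
        raise ValueError("constant response: y has zero variance after centering")
    k = Xc.shape[1]
    if k == 0:
        logdet_v = 0.0
        S = ss_y
    else:
        A = Xc.T @ Xc + np.diag(1.0 / var_i)
        try:
            c, low = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - PD by construction
            raise FloatingPointError("prior-regularized normal matrix not positive definite") from exc
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c)))) + float(np.sum(np.log(var_i)))
        b = Xc.T @ yc
        S = ss_y - float(b @ cho_solve((c, low), b))
        if S <= 0.0:
            raise FloatingPointError("residual quadratic form is not positive")
    out = (
        -0.5 * nu * math.log(2.0 * math.pi)
        - 0.5 * math.log(m)
        + float(gammaln(nu / 2.0))
        + 0.5 * nu * math.log(2.0)
        - 0.5 * logdet_v
        - 0.5 * nu * math.log(S)
    )
    if not math.isfinite(out):
        raise FloatingPointError("non-finite log marginal likelihood")
    return out


def log_marginal_likelihood(
    y: np.ndarray, X: np.ndarray, prior: ConjugatePrior | None = None
) -> float:
    """Log marginal likelihood of y given X under the conjugate model.

    ``X`` must carry the intercept as its first column.  Requires
    m >= k + 2 so that the reduced problem has positive degrees of freedom.
    """
    prior = prior or ConjugatePrior()
    y, X = _validate_design(y, X)
    m, ncol = X.shape
    k = ncol - 1
    if m < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} observations, got {m}")
    yc = y - y.mean()
    Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
    return _log_ml_centered(yc, Xc, prior.variances(k))


def bayes_factor(y: np.ndarray, X: np.ndarray, prior: ConjugatePrior | None = None) -> BayesScore:
    """Bayes factor of the proximity model against the intercept-only null."""
    prior = prior or ConjugatePrior()
    y, X = _validate_design(y, X)
    m, ncol = X.shape
    k = ncol - 1
    if m < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} observations, got {m}")
    yc = y - y.mean()
    Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
    log_alt = _log_ml_centered(yc, Xc, prior.variances(k))
    log_null = _log_ml_centered(yc, np.empty((m, 0)), np.empty(0))
    return BayesScore(log_ml_alt=log_alt, log_ml_null=log_null)
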