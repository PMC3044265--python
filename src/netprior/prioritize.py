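"""Candidate-gene scoring and ranking.

A candidate gene is scored against a query disease by the Bayes factor of
the regression of the disease's phenotype-similarity vector on diffusion
gene-proximity vectors.  Two schemes are supported: scheme 1 scores the
candidate as if it were the disease's only associated gene (the "novel
disease" setting and the default), scheme 2 scores it jointly with the
disease's known genes.  With q proximity kernels and p model genes the
design matrix has p*q + 1 columns (kernel-major: columns 2..p+1 from the
first kernel, and so on), so the method integrates several PPI networks in
one regression; a gene absent from a network contributes an all-zero column
there, which is inert.

Two baselines are included: the CIPHER concordance score (Pearson
correlation of the similarity and proximity vectors, with proximity from a
Gaussian kernel on shortest-path distances) and the coefficient of
determination R^2 of the ordinary least-squares fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.stats import rankdata

from .bayes import ConjugatePrior, bayes_factor
from .kernel import GeneProximity, diffusion_kernel
from .network import PPINetwork
from .profiles import (
    AssociationSet,
    PhenotypeProfile,
    association_proximity_matrix,
    gene_proximity_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RankEntry",
    "RankedList",
    "build_design_matrix",
    "score_candidate_bf",
    "rank_candidates",
    "cipher_proximity",
    "cipher_score",
    "ols_r2_score",
    "BatchScorer",
]


# ---------------------------------------------------------------------------
# reference (per-candidate) scoring path
# ---------------------------------------------------------------------------

def build_design_matrix(
    disease: str,
    model_genes: tuple[str, ...],
    kernels: list[GeneProximity],
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    exclude_self: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Response y and design X for a hypothesized gene set of one disease.

    The query disease's gene set is overridden by ``model_genes`` when the
    proximity columns are built, so the hypothesis "these are the disease's
    genes" enters every column consistently.  By default the query
    disease's own row is dropped: its response entry is the constant
    self-similarity 1, so at moderate m it contributes no discriminative
    information but couples the score to the candidate's kernel diagonal
    (a pure degree effect).  Pass ``exclude_self=False`` to regress over
    all m diseases including the query itself.
    """
    y = profile.row(disease)
    override = {disease: tuple(model_genes)}
    cols = [np.ones(profile.m)]
    for kernel in kernels:
        for g in model_genes:
            cols.append(gene_proximity_vector(kernel, g, profile, assoc, override))
    X = np.column_stack(cols)
    if exclude_self:
        keep = np.arange(profile.m) != profile.position(disease)
        y, X = y[keep], X[keep]
    return y, X


def score_candidate_bf(
    disease: str,
    candidate: str,
    kernels: list[GeneProximity],
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    scheme: int = 1,
    prior: ConjugatePrior | None = None,
    exclude_self: bool = True,
) -> float:
    """Log Bayes factor of one candidate gene for one query disease."""
    if scheme not in (1, 2):
        raise ValueError("scheme must be 1 or 2")
    if scheme == 1:
        model_genes: tuple[str, ...] = (candidate,)
    else:
        model_genes = (candidate, *sorted(assoc.G(disease) - {candidate}))
    y, X = build_design_matrix(disease, model_genes, kernels, profile, assoc, exclude_self)
    return bayes_factor(y, X, prior).log_bf


def cipher_proximity(net: PPINetwork, bandwidth: float = 1.0) -> GeneProximity:
    """Gaussian kernel on the unweighted shortest-path distance matrix.

    w(g, g') = exp(-(d/bandwidth)^2); w = 1 at d = 0 and w = 0 for
    disconnected pairs.  This is the proximity used by the CIPHER baseline.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    A = csr_matrix(net.adjacency())
    d = shortest_path(A, method="D", unweighted=True, directed=False)
    with np.errstate(over="ignore"):
        W = np.exp(-((d / bandwidth) ** 2))
    W[~np.isfinite(d)] = 0.0
    return GeneProximity(gene_index=net.genes, Z=W)


def cipher_score(
    disease: str,
    candidate: str,
    net: PPINetwork | GeneProximity,
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    sp_kernel: bool = True,
    bandwidth: float = 1.0,
    gamma: float = 0.2,
    exclude_self: bool = True,
) -> float:
    """CIPHER concordance: Pearson r between y_d and the candidate's x_g.

    ``net`` may be a prebuilt proximity object; otherwise the shortest-path
    Gaussian kernel (default) or the diffusion kernel (``sp_kernel=False``)
    is computed from it.  Degenerate vectors (zero variance, e.g. a
    candidate with zero proximity everywhere) score 0 with a warning.
    """
    if isinstance(net, GeneProximity):
        prox = net
    elif sp_kernel:
        prox = cipher_proximity(net, bandwidth)
    else:
        prox = diffusion_kernel(net, gamma)
    y = profile.row(disease)
    x = gene_proximity_vector(prox, candidate, profile, assoc, override={disease: (candidate,)})
    if exclude_self:
        keep = np.arange(profile.m) != profile.position(disease)
        y, x = y[keep], x[keep]
    yc = y - y.mean()
    xc = x - x.mean()
    denom = np.sqrt((yc @ yc) * (xc @ xc))
    if denom == 0.0:
        warnings.warn(f"zero-variance vector for ({disease}, {candidate}); CIPHER score 0")
        return 0.0
    return float((yc @ xc) / denom)


def ols_r2_score(
    disease: str,
    candidate: str,
    kernels: list[GeneProximity],
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    exclude_self: bool = True,
) -> float:
    """Coefficient of determination of the ordinary least-squares fit.

    Uses the same scheme-1 design matrix as the Bayes-factor score;
    collinear or all-zero columns are handled by the minimum-norm solution.
    """
    y, X = build_design_matrix(disease, (candidate,), kernels, profile, assoc, exclude_self)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y <= 0.0:
        raise ValueError("constant response: y has zero variance")
    Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    return float(1.0 - (resid @ resid) / ss_y)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankEntry:
    gene: str
    score: float
    rank: float
    rank_ratio: float


@dataclass(frozen=True)
class RankedList:
    """Candidates of one disease ordered by non-increasing score.

    Ranks are average ranks over ties (so rank_ratio statistics are
    unbiased); the display order is deterministic: score descending, then
    gene identifier.
    """

    disease: str
    entries: tuple[RankEntry, ...]
    method: str = ""
    scheme: int = 1

    def rank_ratio(self, gene: str) -> float:
        for e in self.entries:
            if e.gene == gene:
                return e.rank_ratio
        raise KeyError(f"gene {gene!r} not in ranked list")


def rank_candidates(
    disease: str,
    candidates: list[str],
    scorer,
    tie_rule: str = "average",
    method: str = "",
    scheme: int = 1,
) -> RankedList:
    """Score and rank candidate genes for a disease.

    ``scorer`` is called as ``scorer(disease, candidates)`` and must return
    one score per candidate; larger is better.  Rank ratios are rank / N.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate genes")
    scores = np.asarray(scorer(disease, list(candidates)), dtype=float)
    if scores.shape != (len(candidates),):
        raise ValueError("scorer returned wrong number of scores")
    ranks = rankdata(-scores, method=tie_rule)
    n = len(candidates)
    order = sorted(range(n), key=lambda i: (-scores[i], candidates[i]))
    entries = tuple(
        RankEntry(candidates[i], float(scores[i]), float(ranks[i]), float(ranks[i]) / n)
        for i in order
    )
    return RankedList(disease=disease, entries=entries, method=method, scheme=scheme)


# ---------------------------------------------------------------------------
# vectorized scheme-1 scorer (the LOOCV workhorse)
# ---------------------------------------------------------------------------

class BatchScorer:
    """Score many candidates at once under scheme 1.

    Precomputes, per kernel, the stacked proximity matrix P (genes x
    diseases) so that a candidate's design column is a row lookup plus the
    scheme-1 override of the query disease's entry (z_gg, since the
    candidate is hypothesized to be the disease's only gene).  Because that
    override replaces the query column entirely, holding out the association
    being tested is automatic here and needs no rebuild of P.

    ``method`` is ``"bf"`` (log Bayes factor), ``"ols"`` (R^2) or
    ``"cipher"`` (Pearson r; exactly one proximity object required).
    Agrees with the per-candidate reference functions entrywise.
    """

    def __init__(
        self,
        kernels: list[GeneProximity],
        profile: PhenotypeProfile,
        assoc: AssociationSet,
        method: str = "bf",
        prior: ConjugatePrior | None = None,
        exclude_self: bool = True,
    ) -> None:
        if method not in ("bf", "ols", "cipher"):
            raise ValueError(f"unknown method {method!r}")
        if method == "cipher" and len(kernels) != 1:
            raise ValueError("CIPHER scoring uses exactly one proximity matrix")
        if not kernels:
            raise ValueError("need at least one kernel")
        self.method = method
        self.kernels = list(kernels)
        self.profile = profile
        self.assoc = assoc
        self.prior = prior or ConjugatePrior()
        self.exclude_self = exclude_self
        self._P = [association_proximity_matrix(k, profile, assoc) for k in kernels]
        self._diag = [np.diag(k.Z).copy() for k in kernels]

    @property
    def universe(self) -> tuple[str, ...]:
        """Union of the genes of all supplied kernels (the scoreable pool)."""
        genes: set[str] = set()
        for k in self.kernels:
            genes |= set(k.gene_index)
        return tuple(sorted(genes))

    def _candidate_columns(self, d_pos: int, candidates: list[str]) -> np.ndarray:
        """(q, n_cand, m) array of scheme-1 proximity columns."""
        m = self.profile.m
        out = np.zeros((len(self.kernels), len(candidates), m))
        for qi, (kern, P, diag) in enumerate(zip(self.kernels, self._P, self._diag)):
            idx = [kern.position(c) for c in candidates]
            present = [j for j, i in enumerate(idx) if i is not None]
            if present:
                rows = np.array([idx[j] for j in present])
                out[qi, present, :] = P[rows, :]
                out[qi, :, d_pos] = 0.0
                out[qi, present, d_pos] = diag[rows]
        return out

    def __call__(self, disease: str, candidates: list[str], holdout: str | None = None) -> np.ndarray:
        d_pos = self.profile.position(disease)
        y = self.profile.S[d_pos].copy()
        C = self._candidate_columns(d_pos, candidates)
        if self.exclude_self:
            keep = np.arange(self.profile.m) != d_pos
            y = y[keep]
            C = C[:, :, keep]
        yc = y - y.mean()
        ss_y = float(yc @ yc)
        Cc = C - C.mean(axis=2, keepdims=True)
        if self.method == "bf":
            return self._score_bf(yc, ss_y, Cc)
        if self.method == "ols":
            return self._score_ols(yc, ss_y, Cc)
        return self._score_cipher(yc, ss_y, Cc)

    def _score_bf(self, yc: np.ndarray, ss_y: float, Cc: np.ndarray) -> np.ndarray:
        if ss_y <= 0.0:
            raise ValueError("constant response: y has zero variance after centering")
        q, n_cand, m = Cc.shape
        nu = m - 1
        var_i = self.prior.variances(q)
        G = np.einsum("qjm,rjm->jqr", Cc, Cc)
        b = np.einsum("qjm,m->jq", Cc, yc)
        A = G + np.diag(1.0 / var_i)[None, :, :]
        L = np.linalg.cholesky(A)
        logdet_v = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1) + float(
            np.sum(np.log(var_i))
        )
        sol = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        S_alt = ss_y - np.einsum("jq,jq->j", b, sol)
        if np.any(S_alt <= 0.0):
            raise FloatingPointError("residual quadratic form is not positive")
        return -0.5 * logdet_v + 0.5 * nu * (np.log(ss_y) - np.log(S_alt))

    def _score_ols(self, yc: np.ndarray, ss_y: float, Cc: np.ndarray) -> np.ndarray:
        if ss_y <= 0.0:
            raise ValueError("constant response: y has zero variance")
        G = np.einsum("qjm,rjm->jqr", Cc, Cc)
        b = np.einsum("qjm,m->jq", Cc, yc)
        Ginv = np.linalg.pinv(G, hermitian=True)
        explained = np.einsum("jq,jqr,jr->j", b, Ginv, b)
        return explained / ss_y

    def _score_cipher(self, yc: np.ndarray, ss_y: float, Cc: np.ndarray) -> np.ndarray:
        x = Cc[0]  # (n_cand, m), already centred
        sx = np.einsum("jm,jm->j", x, x)
        denom = np.sqrt(sx * ss_y)
        degenerate = denom == 0.0
        if np.any(degenerate):
            logger.debug("%d candidate(s) with zero-variance vectors; score 0", int(degenerate.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x @ yc) / denom
        r[degenerate] = 0.0
        return r
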