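"""Leave-one-out cross-validation, ranking metrics and permutation nulls.

Every known disease–gene association is held out in turn and the held-out
gene is prioritized (scheme 1) against a control set: either 99 randomly
selected genes or the genes lying within 10 Mbp up/downstream of the true
gene (the simulated linkage interval).  Ranks are normalized by the list
length to rank ratios; performance is summarized by the mean rank ratio
(lower is better) and the AUC of the ROC curve obtained by sweeping a rank
threshold, where sensitivity is the fraction of disease genes ranked above
the threshold and specificity the fraction of control genes ranked below.

The permutation suite probes the core assumption that gene proximity
implies phenotype similarity: Bayes factors of the known associations are
recomputed after destroying, in turn, disease–disease structure (relabeling
the similarity profile), disease–gene structure (shuffling the association
table, or replacing disease genes with random genes) and gene–gene
structure (degree-preserving rewiring of the PPI network), and the original
Bayes factors are tested against 1 with a one-sided Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.stats
from scipy.stats import rankdata

from .bayes import ConjugatePrior
from .kernel import GeneProximity, diffusion_kernel
from .network import PPINetwork, degree_preserving_rewire
from .prioritize import BatchScorer
from .profiles import AssociationSet, PhenotypeProfile

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationOutcome",
    "ValidationResult",
    "PermutationResult",
    "roc_auc",
    "loocv_random_controls",
    "loocv_linkage_interval",
    "load_coordinates",
    "write_coordinates",
    "permutation_suite",
    "PERMUTATION_MODES",
]


@dataclass(frozen=True)
class AssociationOutcome:
    disease: str
    gene: str
    n_candidates: int
    rank: float
    rank_ratio: float


@dataclass(frozen=True)
class ValidationResult:
    """Per-association ranks plus aggregate metrics for one protocol run."""

    records: tuple[AssociationOutcome, ...]
    control_rank_ratios: np.ndarray
    mean_rank_ratio: float
    auc: float
    roc_points: np.ndarray
    protocol: str
    seed: int | None = None
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def rank_ratios(self) -> np.ndarray:
        return np.array([r.rank_ratio for r in self.records])

    def summary(self) -> dict:
        return {
            "protocol": self.protocol,
            "mean_rank_ratio": self.mean_rank_ratio,
            "auc": self.auc,
            "n": self.n,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
        }


def roc_auc(
    positive_rank_ratios: Sequence[float], control_rank_ratios: Sequence[float]
) -> tuple[float, np.ndarray]:
    """AUC and ROC points from rank ratios (lower = better).

    The threshold sweeps over all distinct observed values; ties contribute
    one half, so the AUC equals the Mann–Whitney statistic
    U / (n_pos * n_ctrl) counting pairs where the disease gene outranks the
    control.  Returned points are (1 - specificity, sensitivity) pairs.
    """
    pos = np.asarray(positive_rank_ratios, dtype=float)
    ctrl = np.asarray(control_rank_ratios, dtype=float)
    if pos.size == 0 or ctrl.size == 0:
        raise ValueError("both rank-ratio lists must be nonempty")
    n1, n2 = pos.size, ctrl.size
    ranks = rankdata(np.concatenate([pos, ctrl]))
    r_pos = float(ranks[:n1].sum())
    u_pos_larger = r_pos - n1 * (n1 + 1) / 2.0  # pairs where the positive ranks worse
    auc = 1.0 - u_pos_larger / (n1 * n2)
    thresholds = np.unique(np.concatenate([pos, ctrl]))
    points = [(0.0, 0.0)]
    for t in thresholds:
        points.append((float(np.mean(ctrl <= t)), float(np.mean(pos <= t))))
    return float(auc), np.array(points)


def _call_scorer(scorer, disease: str, candidates: list[str], holdout: str):
    try:
        return scorer(disease, candidates, holdout=holdout)
    except TypeError:
        return scorer(disease, candidates)


def _ratios(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    return rankdata(-scores, method="average") / scores.size


def _kernel_universe(kernels: Sequence[GeneProximity]) -> tuple[str, ...]:
    genes: set[str] = set()
    for k in kernels:
        genes |= set(k.gene_index)
    return tuple(sorted(genes))


def loocv_random_controls(
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    kernels: Sequence[GeneProximity],
    scorer: Callable,
    n_controls: int = 99,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> ValidationResult:
    """LOOCV against randomly selected control genes.

    For every association (d, g), the pair is held out, ``n_controls``
    controls are drawn without replacement from the scoreable universe
    (genes of any supplied kernel by default, or ``universe``) minus the
    disease's known genes, and g is ranked among the 1 + n_controls
    candidates.  Deterministic given ``seed``.
    """
    uni = tuple(universe) if universe is not None else _kernel_universe(kernels)
    rng = np.random.default_rng(seed)
    records: list[AssociationOutcome] = []
    ctrl_ratios: list[np.ndarray] = []
    for d, g in sorted(assoc.pairs):
        known = assoc.G(d)
        pool = [u for u in uni if u not in known and u != g]
        if len(pool) < n_controls:
            raise ValueError(
                f"control pool for {d!r} has {len(pool)} genes, fewer than {n_controls}"
            )
        take = rng.choice(len(pool), size=n_controls, replace=False)
        candidates = [g] + [pool[i] for i in take]
        ratios = _ratios(_call_scorer(scorer, d, candidates, g))
        n_cand = len(candidates)
        records.append(
            AssociationOutcome(d, g, n_cand, float(ratios[0] * n_cand), float(ratios[0]))
        )
        ctrl_ratios.append(ratios[1:])
    pos = np.array([r.rank_ratio for r in records])
    ctrl = np.concatenate(ctrl_ratios)
    auc, points = roc_auc(pos, ctrl)
    return ValidationResult(
        records=tuple(records),
        control_rank_ratios=ctrl,
        mean_rank_ratio=float(pos.mean()),
        auc=auc,
        roc_points=points,
        protocol="random_controls",
        seed=seed,
    )


def load_coordinates(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a BED-like 4-column file (chrom, start, end, gene; 0-based).

    The gene's anchor position is its start coordinate.
    """
    coords: dict[str, tuple[str, int]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {line!r}")
            chrom, start, _end, gene = fields[:4]
            coords[gene] = (chrom, int(start))
    return coords


def write_coordinates(coords: Mapping[str, tuple[str, int]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(coords):
            chrom, start = coords[gene]
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{gene}\n")


def loocv_linkage_interval(
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    kernels: Sequence[GeneProximity],
    scorer: Callable,
    coords: Mapping[str, tuple[str, int]],
    window_bp: int = 10_000_000,
) -> ValidationResult:
    """LOOCV against simulated linkage-interval controls.

    Controls for association (d, g) are the genes on g's chromosome within
    ``window_bp`` up/downstream of g's position, excluding g and d's known
    genes.  Associations whose gene lacks coordinates or whose interval
    holds no controls are skipped (counted in ``n_skipped``).  Genes without
    coordinates cannot appear in control sets; their count is logged.
    """
    if not coords:
        raise ValueError("empty coordinate table")
    uni = _kernel_universe(kernels)
    n_without = sum(1 for g in uni if g not in coords)
    if n_without:
        logger.info("%d of %d network genes lack coordinates", n_without, len(uni))
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for gene, (chrom, pos) in coords.items():
        by_chrom.setdefault(chrom, []).append((gene, pos))
    records: list[AssociationOutcome] = []
    ctrl_ratios: list[np.ndarray] = []
    n_skipped = 0
    for d, g in sorted(assoc.pairs):
        if g not in coords:
            n_skipped += 1
            continue
        chrom, pos = coords[g]
        known = assoc.G(d)
        pool = sorted(
            u
            for u, p in by_chrom[chrom]
            if abs(p - pos) <= window_bp and u != g and u not in known
        )
        if not pool:
            n_skipped += 1
            continue
        candidates = [g] + pool
        ratios = _ratios(_call_scorer(scorer, d, candidates, g))
        n_cand = len(candidates)
        records.append(
            AssociationOutcome(d, g, n_cand, float(ratios[0] * n_cand), float(ratios[0]))
        )
        ctrl_ratios.append(ratios[1:])
    if not records:
        pos_arr = np.array([])
        return ValidationResult(
            records=(),
            control_rank_ratios=np.array([]),
            mean_rank_ratio=float("nan"),
            auc=float("nan"),
            roc_points=np.empty((0, 2)),
            protocol="linkage_interval",
            n_skipped=n_skipped,
        )
    pos_arr = np.array([r.rank_ratio for r in records])
    ctrl = np.concatenate(ctrl_ratios)
    auc, points = roc_auc(pos_arr, ctrl)
    return ValidationResult(
        records=tuple(records),
        control_rank_ratios=ctrl,
        mean_rank_ratio=float(pos_arr.mean()),
        auc=auc,
        roc_points=points,
        protocol="linkage_interval",
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# permutation suite
# ---------------------------------------------------------------------------

PERMUTATION_MODES = (
    "original",
    "permute_pps",
    "permute_assoc",
    "random_seed_genes",
    "permute_ppi",
)


@dataclass(frozen=True)
class PermutationResult:
    """Per-mode Bayes factors of the known associations."""

    log_bf: dict[str, np.ndarray]
    wilcoxon_p: float
    seed: int
    n_perm: int

    @property
    def bf(self) -> dict[str, np.ndarray]:
        with np.errstate(over="ignore"):
            return {mode: np.exp(v) for mode, v in self.log_bf.items()}

    @property
    def median_bf(self) -> dict[str, float]:
        return {mode: float(np.median(v)) for mode, v in self.bf.items()}


def wilcoxon_log_bf_greater_than_zero(log_bf: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p-value for log BF > 0.

    Exact distribution for n <= 25 without zeros, else the normal
    approximation with continuity correction.
    """
    log_bf = np.asarray(log_bf, dtype=float)
    nonzero = log_bf[log_bf != 0.0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if log_bf.size <= 25 and nonzero.size == log_bf.size else "approx"
    res = scipy.stats.wilcoxon(
        log_bf, alternative="greater", correction=True, method=method
    )
    return float(res.pvalue)


def _association_log_bfs(
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    kernel: GeneProximity,
    pairs: Sequence[tuple[str, str]],
    prior: ConjugatePrior | None,
) -> np.ndarray:
    scorer = BatchScorer([kernel], profile, assoc, method="bf", prior=prior)
    return np.array([float(scorer(d, [g])[0]) for d, g in pairs])


def permutation_suite(
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    net: PPINetwork,
    gamma: float = 0.2,
    modes: Sequence[str] = PERMUTATION_MODES,
    n_perm: int = 1,
    seed: int = 0,
    prior: ConjugatePrior | None = None,
    holdout: bool = False,
) -> PermutationResult:
    """Bayes factors of known associations under the original and permuted data.

    Modes: ``permute_pps`` relabels the similarity profile (one permutation
    applied jointly to rows and columns, so the matrix stays a valid
    profile); ``permute_assoc`` shuffles the gene column of the association
    table; ``random_seed_genes`` replaces each associated gene with a
    uniformly drawn network gene; ``permute_ppi`` rewires the network
    degree-preservingly and recomputes the kernel.  Each permuted mode is
    repeated ``n_perm`` times with derived seeds and the Bayes factors are
    pooled; ``n_perm = 0`` computes the original mode only.

    Scores use scheme 1, whose query-disease override makes the result
    identical whether the association scored is first removed from the
    table (``holdout=True``) or left in (the default); the flag is kept for
    symmetry with protocols where the two differ.
    """
    for mode in modes:
        if mode not in PERMUTATION_MODES:
            raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    base_pairs = sorted(assoc.pairs)
    kernel = diffusion_kernel(net, gamma)
    out: dict[str, np.ndarray] = {}

    if "original" in modes:
        out["original"] = _association_log_bfs(profile, assoc, kernel, base_pairs, prior)

    active = [m for m in modes if m != "original"] if n_perm > 0 else []
    for mode in active:
        samples: list[np.ndarray] = []
        for _ in range(n_perm):
            child = int(rng.integers(0, 2**31 - 1))
            crng = np.random.default_rng(child)
            if mode == "permute_pps":
                perm = crng.permutation(profile.m)
                S2 = profile.S[np.ix_(perm, perm)]
                prof2 = PhenotypeProfile(disease_index=profile.disease_index, S=S2)
                samples.append(
                    _association_log_bfs(prof2, assoc, kernel, base_pairs, prior)
                )
            elif mode == "permute_assoc":
                genes = [g for _, g in base_pairs]
                crng.shuffle(genes)
                pairs2 = sorted({(d, g) for (d, _), g in zip(base_pairs, genes)})
                assoc2 = AssociationSet.from_pairs(pairs2)
                samples.append(
                    _association_log_bfs(profile, assoc2, kernel, pairs2, prior)
                )
            elif mode == "random_seed_genes":
                gene_pool = list(net.genes)
                pairs2 = sorted(
                    {
                        (d, gene_pool[int(i)])
                        for (d, _), i in zip(
                            base_pairs, crng.integers(0, len(gene_pool), len(base_pairs))
                        )
                    }
                )
                assoc2 = AssociationSet.from_pairs(pairs2)
                samples.append(
                    _association_log_bfs(profile, assoc2, kernel, pairs2, prior)
                )
            else:  # permute_ppi
                net2 = degree_preserving_rewire(net, seed=child)
                kernel2 = diffusion_kernel(net2, gamma)
                samples.append(
                    _association_log_bfs(profile, assoc, kernel2, base_pairs, prior)
                )
        out[mode] = np.concatenate(samples)

    p = (
        wilcoxon_log_bf_greater_than_zero(out["original"])
        if "original" in out
        else float("nan")
    )
    return PermutationResult(log_bf=out, wilcoxon_p=p, seed=seed, n_perm=n_perm)
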