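"""Self-contained synthetic fixtures with a planted linear signal.

The generator emulates, at desk scale, the inputs the prioritization method
consumes: several partially overlapping PPI networks, a phenotype similarity
profile, a disease–gene association table and gene genomic coordinates.
The similarity of two diseases is constructed as

    S(d, d') = a + b * sum of cross-proximities of their gene sets + noise,

with proximities taken from the diffusion kernel of one designated "truth"
network — i.e. the data realize exactly the linear assumption the regression
scores against.  The remaining networks are induced subgraphs of the truth
network on an overlapping gene subset, corrupted by degree-preserving
rewiring of a fraction of their edges, so that multi-network integration has
both missing coverage and noise to contend with.

Regeneration with the same parameters and seed is bitwise identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .kernel import diffusion_kernel
from .network import PPINetwork, degree_preserving_rewire, load_network, write_network
from .profiles import (
    AssociationSet,
    PhenotypeProfile,
    load_associations,
    load_phenotype_profile,
    write_associations,
    write_phenotype_profile,
)
from .validate import load_coordinates, write_coordinates

__all__ = ["ScenarioParams", "SyntheticScenario", "make_network", "make_scenario",
           "write_scenario", "load_scenario"]


@dataclass(frozen=True)
class ScenarioParams:
    """Generator parameters; the defaults define the standard benchmark."""

    n_genes: int = 500
    n_diseases: int = 120
    q: int = 3                      # number of networks (first one is the truth network)
    overlap: float = 0.6            # gene-coverage fraction of the corrupted copies
    genes_per_disease: tuple[int, int] = (1, 3)
    n_families: int = 30            # groups of phenotypically related diseases
    family_pool_size: int = 8       # genes in a family's network neighbourhood
    signal: float = 1.0             # slope b of the planted linear relationship
    noise_sd: float = 0.1
    baseline: float = 0.2           # intercept a of the similarity model
    rewire_fraction: float = 0.2    # fraction of edges double-swapped in the copies
    network_model: str = "erdos_renyi"
    density_param: float = 0.006    # edge probability (or attachment m for PA)
    gamma: float = 0.2
    n_chromosomes: int = 5
    chrom_length_bp: int = 60_000_000
    seed: int = 1


@dataclass(frozen=True)
class SyntheticScenario:
    networks: tuple[PPINetwork, ...]
    profile: PhenotypeProfile
    assoc: AssociationSet
    coords: dict[str, tuple[str, int]]
    truth: frozenset[tuple[str, str]]
    params: ScenarioParams


def make_network(
    n_genes: int,
    model: str = "erdos_renyi",
    density_param: float = 0.05,
    seed: int = 0,
) -> PPINetwork:
    """Random simple graph over genes g0000..; deterministic given seed."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if model == "erdos_renyi":
        if density_param * n_genes * (n_genes - 1) / 2 < 1:
            warnings.warn("edge probability implies fewer than one expected edge")
        g = nx.gnp_random_graph(n_genes, density_param, seed=seed)
    elif model == "preferential_attachment":
        g = nx.barabasi_albert_graph(n_genes, int(density_param), seed=seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    name = {i: f"g{i:04d}" for i in range(n_genes)}
    edges = [(name[a], name[b]) for a, b in g.edges()]
    return PPINetwork.from_edges(edges, genes=name.values())


def make_scenario(params: ScenarioParams | None = None) -> SyntheticScenario:
    """Generate the full scenario (networks, profile, associations, coords)."""
    p = params or ScenarioParams()
    lo, hi = p.genes_per_disease
    if hi > p.n_genes:
        raise ValueError("genes_per_disease exceeds the number of genes")
    if not (0 < lo <= hi):
        raise ValueError("genes_per_disease bounds must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(p.seed)

    truth_net = make_network(
        p.n_genes, p.network_model, p.density_param, seed=int(rng.integers(2**31 - 1))
    )
    networks = [truth_net]
    n_sub = int(round(p.overlap * p.n_genes))
    for _ in range(p.q - 1):
        subset = sorted(
            np.asarray(truth_net.genes)[rng.choice(p.n_genes, n_sub, replace=False)]
        )
        sub = truth_net.induced_subgraph(subset)
        n_swaps = int(round(p.rewire_fraction * sub.n_edges))
        networks.append(
            degree_preserving_rewire(sub, n_swaps=n_swaps, seed=int(rng.integers(2**31 - 1)))
        )

    diseases = tuple(f"D{i:03d}" for i in range(p.n_diseases))
    gene_arr = np.asarray(truth_net.genes)
    gene_pos = {g: i for i, g in enumerate(truth_net.genes)}
    neighbors: dict[int, list[int]] = {i: [] for i in range(p.n_genes)}
    for a, b in truth_net.edges:
        neighbors[gene_pos[a]].append(gene_pos[b])
        neighbors[gene_pos[b]].append(gene_pos[a])
    pairs: set[tuple[str, str]] = set()
    gene_sets: list[np.ndarray] = []
    # Disease families: groups of phenotypically related diseases whose gene
    # sets are drawn from a shared network neighbourhood (a breadth-first
    # ball around a seed gene).  Real disease–gene data are modular in
    # exactly this way — similar phenotypes map to proximal genes — and the
    # family structure is what gives the planted linear signal the magnitude
    # real phenotype-similarity profiles exhibit.
    n_fam = max(1, min(p.n_families, p.n_diseases))
    pools: list[np.ndarray] = []
    for _ in range(n_fam):
        seed_gene = int(rng.integers(0, p.n_genes))
        pool = [seed_gene]
        frontier = sorted(set(neighbors[seed_gene]))
        while len(pool) < min(p.family_pool_size, p.n_genes):
            if frontier:
                pick = int(frontier[rng.integers(0, len(frontier))])
            else:  # isolated corner of the graph: fall back to a uniform draw
                pick = int(rng.integers(0, p.n_genes))
                if pick in pool:
                    continue
            pool.append(pick)
            frontier = sorted(
                (set(frontier) | set(neighbors[pick])) - set(pool)
            )
        pools.append(np.array(sorted(pool)))
    for i, d in enumerate(diseases):
        pool = pools[i % n_fam]
        k = int(rng.integers(lo, hi + 1))
        idx = np.sort(pool[rng.choice(len(pool), min(k, len(pool)), replace=False)])
        gene_sets.append(idx)
        for g in gene_arr[idx]:
            pairs.add((d, str(g)))

    kern = diffusion_kernel(truth_net, p.gamma)
    M = np.zeros((p.n_genes, p.n_diseases))
    for j, idx in enumerate(gene_sets):
        M[idx, j] = 1.0
    B = M.T @ kern.Z @ M
    noise = np.triu(rng.normal(0.0, p.noise_sd, (p.n_diseases, p.n_diseases)), 1)
    S = p.baseline + p.signal * (B + B.T) / 2.0 + noise + noise.T  # exact symmetry
    np.fill_diagonal(S, 1.0)
    np.clip(S, 0.0, 1.0, out=S)
    profile = PhenotypeProfile(disease_index=diseases, S=S)

    chrom_idx = rng.integers(0, p.n_chromosomes, p.n_genes)
    positions = rng.integers(0, p.chrom_length_bp, p.n_genes)
    coords = {
        str(g): (f"chr{chrom_idx[i] + 1}", int(positions[i]))
        for i, g in enumerate(gene_arr)
    }

    return SyntheticScenario(
        networks=tuple(networks),
        profile=profile,
        assoc=AssociationSet.from_pairs(pairs),
        coords=coords,
        truth=frozenset(pairs),
        params=p,
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> None:
    """Write all scenario files (edge lists, TSVs, BED, truth, params)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, net in enumerate(scenario.networks):
        write_network(net, out / f"network_{i}.tsv")
    write_phenotype_profile(scenario.profile, out / "profile.tsv")
    write_associations(scenario.assoc, out / "associations.tsv")
    write_coordinates(scenario.coords, out / "coords.bed")
    with (out / "truth.tsv").open("w") as fh:
        for d, g in sorted(scenario.truth):
            fh.write(f"{d}\t{g}\n")
    with (out / "params.json").open("w") as fh:
        json.dump(asdict(scenario.params), fh, indent=2)


def load_scenario(indir: str | Path) -> SyntheticScenario:
    """Round-trip loader for a directory written by :func:`write_scenario`."""
    ind = Path(indir)
    with (ind / "params.json").open() as fh:
        raw = json.load(fh)
    raw["genes_per_disease"] = tuple(raw["genes_per_disease"])
    params = ScenarioParams(**raw)
    networks = tuple(
        load_network(path) for path in sorted(ind.glob("network_*.tsv"))
    )
    profile = load_phenotype_profile(ind / "profile.tsv")
    assoc = load_associations(ind / "associations.tsv", profile)
    coords = load_coordinates(ind / "coords.bed")
    truth: set[tuple[str, str]] = set()
    with (ind / "truth.tsv").open() as fh:
        for line in fh:
            if line.strip():
                d, g = line.split()
                truth.add((d, g))
    return SyntheticScenario(
        networks=networks,
        profile=profile,
        assoc=assoc,
        coords=coords,
        truth=frozenset(truth),
        params=params,
    )
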