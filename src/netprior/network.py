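"""Protein–protein interaction networks as simple undirected graphs.

A :class:`PPINetwork` is a set of gene identifiers plus a set of unordered
gene pairs (interactions).  Self-interactions and duplicate pairs are removed
on construction, mirroring the usual cleaning applied to interaction
databases.  Gene identifiers are opaque, case-sensitive strings; no symbol
normalization is attempted.  Networks may be disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

Edge = tuple[str, str]

__all__ = [
    "PPINetwork",
    "load_network",
    "write_network",
    "combine_networks",
    "high_confidence_network",
    "degree_preserving_rewire",
]


def _norm_edge(a: str, b: str) -> Edge:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """Simple undirected graph over gene identifiers.

    ``genes`` is lexicographically sorted and defines the row/column order of
    the adjacency matrix; ``edges`` holds unordered pairs stored as sorted
    2-tuples.  The implied adjacency matrix is symmetric 0/1 with a zero
    diagonal.
    """

    genes: tuple[str, ...]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge {(a, b)!r} not stored in sorted order")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"edge {(a, b)!r} has endpoint outside gene list")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], genes: Iterable[str] = ()
    ) -> "PPINetwork":
        """Build a network, dropping self-loops and duplicate pairs.

        ``genes`` may list extra (isolated) nodes beyond edge endpoints.
        """
        clean = {_norm_edge(a, b) for a, b in edges if a != b}
        node_set = set(genes)
        for a, b in clean:
            node_set.add(a)
            node_set.add(b)
        return cls(genes=tuple(sorted(node_set)), edges=frozenset(clean))

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.genes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in ``genes`` order."""
        pos = {g: i for i, g in enumerate(self.genes)}
        A = np.zeros((self.n, self.n))
        for a, b in self.edges:
            i, j = pos[a], pos[b]
            A[i, j] = A[j, i] = 1.0
        return A

    def induced_subgraph(self, genes: Iterable[str]) -> "PPINetwork":
        keep = set(genes)
        missing = keep - set(self.genes)
        if missing:
            raise KeyError(f"genes not in network: {sorted(missing)[:5]}")
        edges = {e for e in self.edges if e[0] in keep and e[1] in keep}
        return PPINetwork(genes=tuple(sorted(keep)), edges=frozenset(edges))


def load_network(path: str | Path) -> PPINetwork:
    """Read an edge list: two whitespace-separated gene ids per line.

    Lines starting with ``#`` and blank lines are ignored.  Duplicate pairs
    (in either orientation) and self-interactions are removed.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#%isolated"):
                isolated.extend(line.split()[1:])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns, got {line!r}")
            edges.append((fields[0], fields[1]))
    if not edges and not isolated:
        raise ValueError(f"{path}: no interactions found")
    return PPINetwork.from_edges(edges, genes=isolated)


def write_network(net: PPINetwork, path: str | Path) -> None:
    """Write an edge list with sorted pairs in sorted order (reproducible).

    Isolated genes (no interactions) are recorded on ``#%isolated``
    directive lines so that a written network loads back identically; plain
    ``#`` comments are still ignored by the reader.
    """
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
        isolated = sorted(set(net.genes) - {g for e in net.edges for g in e})
        for g in isolated:
            fh.write(f"#%isolated\t{g}\n")


def combine_networks(nets: list[PPINetwork]) -> PPINetwork:
    """Union network: union of gene sets and of edge sets."""
    if not nets:
        raise ValueError("need at least one network")
    genes: set[str] = set()
    edges: set[Edge] = set()
    for net in nets:
        genes |= set(net.genes)
        edges |= net.edges
    return PPINetwork(genes=tuple(sorted(genes)), edges=frozenset(edges))


def high_confidence_network(nets: list[PPINetwork], min_support: int = 2) -> PPINetwork:
    """Keep edges supported by at least ``min_support`` input networks.

    The gene set of the result is the set of endpoints of kept edges.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(nets):
        raise ValueError(
            f"min_support={min_support} exceeds the number of networks ({len(nets)})"
        )
    counts: dict[Edge, int] = {}
    for net in nets:
        for e in net.edges:
            counts[e] = counts.get(e, 0) + 1
    kept = {e for e, c in counts.items() if c >= min_support}
    genes = sorted({g for e in kept for g in e})
    return PPINetwork(genes=tuple(genes), edges=frozenset(kept))


def degree_preserving_rewire(
    net: PPINetwork, n_swaps: int | None = None, seed: int = 0
) -> PPINetwork:
    """Randomize edges by double-edge swaps, preserving every node's degree.

    Two disjoint edges (a,b), (c,d) are replaced by (a,c), (b,d); proposals
    that would create a self-loop or a duplicate edge are rejected, so the
    result is again a simple graph with the same degree sequence.  Default
    ``n_swaps`` is ten times the edge count.  Graphs where no swap is possible
    are returned unchanged.
    """
    if n_swaps is None:
        n_swaps = 10 * net.n_edges
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    edges = [list(e) for e in sorted(net.edges)]
    if n_swaps == 0 or len(edges) < 2:
        return PPINetwork(genes=net.genes, edges=net.edges)
    rng = np.random.default_rng(seed)
    edge_set = set(net.edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # orientation of the second edge
            c, d = d, c
        if a == c or b == d:
            continue
        new1, new2 = _norm_edge(a, c), _norm_edge(b, d)
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.remove(_norm_edge(a, b))
        edge_set.remove(_norm_edge(c, d))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = list(new1)
        edges[j] = list(new2)
    return PPINetwork(genes=net.genes, edges=frozenset(edge_set))
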