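"""Phenotype similarity profiles and disease–gene associations.

The phenotype similarity profile is an m x m symmetric matrix S with entries
in [0, 1] and unit diagonal; row d is the disease's similarity vector y_d.
An association set records the known disease→gene map G(d).  From a gene
proximity kernel these are turned into the regression ingredients: the
proximity between gene g and disease d is the sum of kernel proximities
between g and every gene in G(d), and the gene proximity vector x_g collects
that quantity over all m diseases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .kernel import GeneProximity

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeProfile",
    "AssociationSet",
    "load_phenotype_profile",
    "write_phenotype_profile",
    "load_associations",
    "write_associations",
    "gene_disease_proximity",
    "gene_proximity_vector",
    "association_proximity_matrix",
]


@dataclass(frozen=True)
class PhenotypeProfile:
    """Symmetric disease–disease similarity matrix with entries in [0, 1]."""

    disease_index: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.disease_index)
        if self.S.shape != (m, m):
            raise ValueError("similarity matrix shape does not match disease index")
        if not np.allclose(self.S, self.S.T, atol=1e-6):
            raise ValueError("similarity matrix is not symmetric")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("similarity diagonal must be 1 (self-similarity)")
        object.__setattr__(self, "_pos", {d: i for i, d in enumerate(self.disease_index)})

    @property
    def m(self) -> int:
        return len(self.disease_index)

    def position(self, disease: str) -> int:
        try:
            return self._pos[disease]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"disease {disease!r} not in profile") from None

    def row(self, disease: str) -> np.ndarray:
        """Similarity vector y_d between ``disease`` and all m diseases."""
        return self.S[self.position(disease)].copy()


@dataclass(frozen=True)
class AssociationSet:
    """Known (disease, gene) associations and the induced map G(d)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        G: dict[str, frozenset[str]] = {}
        tmp: dict[str, set[str]] = {}
        for d, g in self.pairs:
            tmp.setdefault(d, set()).add(g)
        for d, gs in tmp.items():
            G[d] = frozenset(gs)
        object.__setattr__(self, "_G", G)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationSet":
        return cls(pairs=frozenset(pairs))

    def G(self, disease: str) -> frozenset[str]:
        """Genes known associated with ``disease`` (empty set if none)."""
        return self._G.get(disease, frozenset())  # type: ignore[attr-defined]

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self._G))  # type: ignore[attr-defined]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for _, g in self.pairs}))

    def remove(self, disease: str, gene: str) -> "AssociationSet":
        """Copy with one pair removed (used to hold out an association)."""
        return AssociationSet(pairs=self.pairs - {(disease, gene)})


def load_phenotype_profile(path: str | Path) -> PhenotypeProfile:
    """Read a TSV similarity matrix with disease ids as header and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"profile must be square, got shape {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError("row and column disease labels differ")
    S = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("profile contains non-numeric or non-finite entries")
    if not np.allclose(S, S.T, atol=1e-6):
        raise ValueError("profile is asymmetric beyond 1e-6")
    S = (S + S.T) / 2.0
    if S.min() < 0 or S.max() > 1:
        raise ValueError("profile entries outside [0, 1]")
    if not np.allclose(np.diag(S), 1.0):
        warnings.warn("profile diagonal is not 1; forcing self-similarity to 1")
        np.fill_diagonal(S, 1.0)
    return PhenotypeProfile(disease_index=tuple(df.index), S=S)


def write_phenotype_profile(profile: PhenotypeProfile, path: str | Path) -> None:
    pd.DataFrame(
        profile.S, index=list(profile.disease_index), columns=list(profile.disease_index)
    ).to_csv(path, sep="\t")


def load_associations(
    path: str | Path,
    profile: PhenotypeProfile,
    networks: Iterable = (),
) -> AssociationSet:
    """Read a two-column (disease, gene) TSV, keeping diseases in the profile.

    Genes need not appear in any network: absent genes are scored through the
    zero-proximity convention.  Duplicates are dropped; counts are logged.
    """
    known = set(profile.disease_index)
    pairs: set[tuple[str, str]] = set()
    n_lines = 0
    n_dropped = 0
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            n_lines += 1
            d, g = fields[0], fields[1]
            if d not in known:
                n_dropped += 1
                continue
            pairs.add((d, g))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} association(s) with diseases absent from the profile")
    logger.info(
        "loaded %d association lines -> %d unique pairs (%d dropped)",
        n_lines, len(pairs), n_dropped,
    )
    if not pairs:
        raise ValueError(f"{path}: no usable associations after filtering")
    return AssociationSet.from_pairs(pairs)


def write_associations(assoc: AssociationSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d, g in sorted(assoc.pairs):
            fh.write(f"{d}\t{g}\n")


def gene_disease_proximity(kernel: GeneProximity, g: str, genes_d: Iterable[str]) -> float:
    """Sum of kernel proximities between gene ``g`` and each gene of a disease."""
    return float(sum(kernel.proximity(g, g2) for g2 in genes_d))


def gene_proximity_vector(
    kernel: GeneProximity,
    g: str,
    profile: PhenotypeProfile,
    assoc: AssociationSet,
    override: Mapping[str, Iterable[str]] | None = None,
) -> np.ndarray:
    """Proximity vector x_g over all m diseases of the profile.

    Entry k is the summed proximity between ``g`` and the gene set of disease
    d_k — taken from ``override`` when present there, else from the
    association set.  Diseases with no associated genes contribute zero.
    """
    x = np.zeros(profile.m)
    for k, d in enumerate(profile.disease_index):
        genes_d = override[d] if override is not None and d in override else assoc.G(d)
        x[k] = gene_disease_proximity(kernel, g, genes_d)
    return x


def association_proximity_matrix(
    kernel: GeneProximity, profile: PhenotypeProfile, assoc: AssociationSet
) -> np.ndarray:
    """Vectorized stack of gene proximity vectors: P[i, k] = x_{gene i}[d_k].

    Row order follows ``kernel.gene_index``; genes in G(d) that are absent
    from the kernel's network contribute zero.  This is the fast path used by
    the batch scorers; it agrees entrywise with
    :func:`gene_proximity_vector`.
    """
    M = np.zeros((kernel.n, profile.m))
    for k, d in enumerate(profile.disease_index):
        for g in assoc.G(d):
            i = kernel.position(g)
            if i is not None:
                M[i, k] = 1.0
    return kernel.Z @ M
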