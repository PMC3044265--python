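"""Diffusion-kernel gene proximity.

Gene–gene proximity on a PPI network is quantified by the diffusion kernel

    Z = exp(-gamma * L),        L = D - A,

where A is the adjacency matrix, D the diagonal degree matrix and
``gamma`` (0 < gamma < 1) controls the magnitude of diffusion.  Because the
Laplacian annihilates the constant vector, every row of Z sums to one, and Z
is symmetric, entrywise nonnegative and positive definite.  The proximity of
genes i and j is the entry z_ij; a gene absent from the network has proximity
zero to everything (the minimum), which is the convention used when several
networks with different coverage are combined.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .network import PPINetwork

__all__ = [
    "GeneProximity",
    "DiffusionKernel",
    "laplacian",
    "diffusion_kernel",
    "proximity",
    "save_kernel",
    "load_kernel",
]


@dataclass(frozen=True)
class GeneProximity:
    """A symmetric gene-proximity matrix over an ordered gene index.

    Base container shared by the diffusion kernel and the shortest-path
    Gaussian kernel used by the CIPHER baseline.
    """

    gene_index: tuple[str, ...]
    Z: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_index)
        if self.Z.shape != (n, n):
            raise ValueError("proximity matrix shape does not match gene index")
        object.__setattr__(self, "_pos", {g: i for i, g in enumerate(self.gene_index)})

    @property
    def n(self) -> int:
        return len(self.gene_index)

    def position(self, gene: str) -> int | None:
        return self._pos.get(gene)  # type: ignore[attr-defined]

    def proximity(self, g: str, g2: str) -> float:
        """z at (g, g2); 0.0 if either gene is absent from the network."""
        i = self.position(g)
        j = self.position(g2)
        if i is None or j is None:
            return 0.0
        return float(self.Z[i, j])


@dataclass(frozen=True)
class DiffusionKernel(GeneProximity):
    gamma: float = 0.2


def laplacian(net: PPINetwork) -> np.ndarray:
    """Graph Laplacian L = D - A in the network's gene order."""
    if net.n == 0:
        raise ValueError("empty network")
    A = net.adjacency()
    return np.diag(A.sum(axis=1)) - A


def diffusion_kernel(net: PPINetwork, gamma: float = 0.2) -> DiffusionKernel:
    """Compute Z = exp(-gamma * L) by symmetric eigendecomposition.

    The eigendecomposition is exact for the symmetric Laplacian; the result
    is re-symmetrized to remove round-off, tiny negative entries are clipped
    to zero, and the structural invariants (symmetry, nonnegativity, unit row
    sums) are asserted to 1e-8.
    """
    if not (0.0 < gamma < 1.0):
        warnings.warn(
            f"gamma={gamma} outside the recommended open interval (0, 1)",
            stacklevel=2,
        )
    L = laplacian(net)
    w, V = eigh(L)
    Z = (V * np.exp(-gamma * w)) @ V.T
    Z = (Z + Z.T) / 2.0
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("diffusion kernel contains non-finite entries")
    if Z.min() < -1e-8:
        raise FloatingPointError(f"diffusion kernel entry below zero: {Z.min()}")
    np.clip(Z, 0.0, None, out=Z)
    row_err = np.abs(Z.sum(axis=1) - 1.0).max()
    if row_err > 1e-8:
        raise FloatingPointError(f"diffusion kernel row sums deviate from 1 by {row_err}")
    return DiffusionKernel(gene_index=net.genes, Z=Z, gamma=gamma)


def proximity(kernel: GeneProximity, g: str, g2: str) -> float:
    """Module-level alias for :meth:`GeneProximity.proximity`."""
    return kernel.proximity(g, g2)


def save_kernel(kernel: DiffusionKernel, path: str | Path) -> None:
    """Cache a kernel (gene index, gamma, Z, checksum) in a .npz container."""
    crc = zlib.crc32(np.ascontiguousarray(kernel.Z).tobytes())
    np.savez_compressed(
        path,
        genes=np.array(kernel.gene_index),
        gamma=np.array(kernel.gamma),
        Z=kernel.Z,
        crc=np.array(crc, dtype=np.uint32),
    )


def load_kernel(path: str | Path) -> DiffusionKernel:
    with np.load(path, allow_pickle=False) as data:
        genes = tuple(str(g) for g in data["genes"])
        Z = data["Z"]
        gamma = float(data["gamma"])
        crc = int(data["crc"])
    if zlib.crc32(np.ascontiguousarray(Z).tobytes()) != crc:
        raise ValueError(f"kernel cache {path} is corrupt (checksum mismatch)")
    return DiffusionKernel(gene_index=genes, Z=Z, gamma=gamma)
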