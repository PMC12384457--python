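"""Electrode montage graphs for EEG decoding.

The spatial prior of the model is a graph over scalp electrodes: nodes are
channels, edges connect physically neighbouring electrodes of the 10-20
layout.  This module builds the binary adjacency matrix (with unit diagonal),
its symmetric normalisation

    A_hat = D~^{-1/2} (A + I) D~^{-1/2},   D~ = degree matrix of (A + I),

and the Chebyshev polynomial basis T_0..T_{K-1} evaluated at A_hat
(T_0 = I, T_1 = A_hat, T_k = 2 A_hat T_{k-1} - T_{k-2}) that the graph
convolution consumes.  Note that A already carries a unit diagonal, so the
operator normalised is A + I with diagonal 2; this is the literal form of
the normalisation used here.

Two montages ship with the package as plain-text data: the 22-channel
10-20 subset used by BCI Competition IV 2a (edges from a Delaunay
triangulation of the projected positions) and the 3-channel bipolar
C3/Cz/C4 montage of BCI Competition IV 2b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "SpatialGraph",
    "MontageError",
    "load_builtin_montage",
    "build_adjacency",
    "normalize_adjacency",
    "chebyshev_basis",
    "build_spatial_graph",
]


class MontageError(ValueError):
    """Raised for inconsistent montage definitions or adjacency inputs."""


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels, 2-D projected positions and neighbour pairs.

    Positions are unitless head-circle projections; they are used only to
    build/justify the edge set, never as model features.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (C, 2) float
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.names) == 0:
            raise MontageError("montage needs at least one electrode")
        if len(set(self.names)) != len(self.names):
            raise MontageError("electrode labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 2):
            raise MontageError(
                f"positions must be ({len(self.names)}, 2), got {pos.shape}"
            )
        object.__setattr__(self, "positions", pos)
        known = set(self.names)
        for a, b in self.edges:
            if a not in known:
                raise MontageError(f"edge references unknown electrode {a!r}")
            if b not in known:
                raise MontageError(f"edge references unknown electrode {b!r}")
            if a == b:
                raise MontageError(
                    f"self-pair {a!r} not allowed; the self-connection is "
                    "added by the adjacency rule"
                )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise MontageError(f"unknown electrode {label!r}") from None


@dataclass
class SpatialGraph:
    """Adjacency, its symmetric normalisation and the Chebyshev basis."""

    A: np.ndarray
    A_hat: np.ndarray | None = None
    cheb_basis: list[np.ndarray] = field(default_factory=list)
    K: int = 0

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]


def load_builtin_montage(name: str) -> ElectrodeMontage:
    """Load a montage shipped with the package ("2a" or "2b")."""
    if name not in {"2a", "2b"}:
        raise MontageError(f"unknown builtin montage {name!r}; choose '2a' or '2b'")
    data = resources.files("gahtnet.data")
    labels, coords = [], []
    for line in (data / f"montage_{name}.tsv").read_text().splitlines():
        if not line.strip():
            continue
        lab, x, y = line.split("\t")
        labels.append(lab)
        coords.append((float(x), float(y)))
    edges = []
    for line in (data / f"montage_{name}_edges.txt").read_text().splitlines():
        if not line.strip():
            continue
        a, b = line.split(",")
        edges.append((a.strip(), b.strip()))
    return ElectrodeMontage(tuple(labels), np.array(coords), tuple(edges))


def build_adjacency(montage: ElectrodeMontage) -> SpatialGraph:
    """Binary adjacency: A_ij = 1 iff i = j or {i, j} is a montage edge."""
    C = montage.n_channels
    A = np.eye(C)
    for a, b in montage.edges:
        i, j = montage.index(a), montage.index(b)
        A[i, j] = A[j, i] = 1.0
    return SpatialGraph(A=A)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetrically normalise A + I by the degree matrix of A + I.

    A must be symmetric with unit diagonal (as produced by
    :func:`build_adjacency`), so A + I carries diagonal 2.  The result is
    symmetric with spectrum in (-1, 1] and largest eigenvalue exactly 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MontageError(f"adjacency must be square, got {A.shape}")
    if not np.allclose(A, A.T):
        raise MontageError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 1.0):
        raise MontageError("adjacency must have a unit diagonal")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * A_tilde * inv_sqrt[None, :]


def chebyshev_basis(A_hat: np.ndarray, K: int) -> list[np.ndarray]:
    """Chebyshev polynomials T_0..T_{K-1} of the normalised operator.

    T_0 = I, T_1 = A_hat, T_k = 2 A_hat T_{k-1} - T_{k-2}.
    """
    if K < 1:
        raise MontageError(f"Chebyshev order must be >= 1, got {K}")
    A_hat = np.asarray(A_hat, dtype=float)
    C = A_hat.shape[0]
    basis = [np.eye(C)]
    if K > 1:
        basis.append(A_hat.copy())
    for _ in range(2, K):
        basis.append(2.0 * A_hat @ basis[-1] - basis[-2])
    return basis


def build_spatial_graph(montage: ElectrodeMontage, K: int = 3) -> SpatialGraph:
    """Full pipeline: adjacency -> normalisation -> order-K Chebyshev basis."""
    g = build_adjacency(montage)
    g.A_hat = normalize_adjacency(g.A)
    g.cheb_basis = chebyshev_basis(g.A_hat, K)
    g.K = K
    return g
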