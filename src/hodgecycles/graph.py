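"""Weighted graphs on a canonical edge ordering.

Every module in this package works with a complete (or connected) undirected
graph on ``n`` nodes whose edges are stored as a flat vector ``w`` of length
``m = n(n-1)/2``.  The ordering is the single global convention: unordered
pairs ``(i, j)`` with ``i < j``, sorted lexicographically — i.e. the row-major
upper triangle of the adjacency matrix.  All vectorization, basis
construction and projection code relies on this ordering; round-trip tests
enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedGraph",
    "n_edges",
    "edge_list",
    "edge_index",
    "vectorize_upper",
    "devectorize_upper",
]


def n_edges(n: int) -> int:
    """Number of edges of the complete graph on ``n`` nodes."""
    return n * (n - 1) // 2


def edge_list(n: int) -> np.ndarray:
    """Canonical ``(m, 2)`` array of node pairs ``(i, j)``, ``i < j``,
    lexicographic order."""
    iu, ju = np.triu_indices(n, k=1)
    return np.column_stack([iu, ju])


def edge_index(n: int, i, j) -> np.ndarray:
    """Map node pairs to their canonical edge index (vectorized).

    For ``i < j``: index = i*n - i*(i+1)/2 + (j - i - 1).
    """
    i = np.asarray(i)
    j = np.asarray(j)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    if np.any(lo == hi) or np.any(lo < 0) or np.any(hi >= n):
        raise ValueError("invalid node pair for edge_index")
    return lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)


def vectorize_upper(M: np.ndarray, *, tol: float = 1e-10) -> np.ndarray:
    """Vectorize the strict upper triangle of a symmetric matrix.

    Parameters
    ----------
    M : (n, n) array, symmetric within ``tol``.

    Returns
    -------
    w : (m,) vector in canonical edge order.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected square matrix, got shape {M.shape}")
    asym = np.max(np.abs(M - M.T)) if M.size else 0.0
    if asym > tol:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}")
    iu, ju = np.triu_indices(M.shape[0], k=1)
    return M[iu, ju].copy()


def devectorize_upper(w: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; diagonal is set to zero."""
    w = np.asarray(w, dtype=float)
    if w.shape != (n_edges(n),):
        raise ValueError(f"expected edge vector of length {n_edges(n)}, got {w.shape}")
    M = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    M[iu, ju] = w
    M[ju, iu] = w
    return M


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph in canonical upper-triangular edge order.

    Attributes
    ----------
    n : node count.
    w : edge-weight vector of length ``n(n-1)/2`` (Fisher-z units for
        functional connectomes; any real weights are admitted, including
        negative ones).
    """

    n: int
    w: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (n_edges(self.n),):
            raise ValueError(
                f"weight vector has length {w.shape}, expected {n_edges(self.n)} "
                f"for n={self.n}"
            )
        object.__setattr__(self, "w", w)

    @property
    def m(self) -> int:
        return n_edges(self.n)

    @property
    def edges(self) -> np.ndarray:
        return edge_list(self.n)

    def to_matrix(self) -> np.ndarray:
        return devectorize_upper(self.w, self.n)

    @classmethod
    def from_matrix(cls, M: np.ndarray, *, tol: float = 1e-10) -> "WeightedGraph":
        return cls(n=M.shape[0], w=vectorize_upper(M, tol=tol))
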