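"""Projection of subject edge vectors onto the common harmonic cycle basis.

A subject's vectorized FC pattern ``w`` (length m) is expressed in the
template's fundamental 1-cycle basis ``phi`` (Q x m) by least squares,
``alpha = (phi phi^T)^{-1} phi w``; the residual lies in the orthogonal
complement of the cycle space (the gradient/cut space), so the coefficients
isolate higher-order loop structure from pairwise connection strength.

Also provided: the Hodge decomposition of an edge flow into gradient and
harmonic parts (the curl part vanishes on a graph with no 2-simplices) and
the MST/off-tree split of the coefficients used to check whether the
spanning-tree skeleton or the cycle-closing edges drive a group difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import WeightedGraph
from .topology import CycleBasis, TreeDecomposition, incidence_matrix

__all__ = [
    "MstExtraSplit",
    "project",
    "hodge_decompose",
    "decompose_mst_extra",
]

COND_WARN = 1e8


@dataclass(frozen=True)
class MstExtraSplit:
    """Cycle coefficients split into spanning-tree and off-tree parts.

    ``alpha_mst + alpha_extra == alpha`` by linearity of the projection.
    """

    alpha_mst: np.ndarray = field(repr=False)
    alpha_extra: np.ndarray = field(repr=False)

    @property
    def alpha(self) -> np.ndarray:
        return self.alpha_mst + self.alpha_extra


def _gram_solve(basis: CycleBasis, W: np.ndarray) -> np.ndarray:
    # sparse normal equations: alpha = (phi phi^T)^{-1} phi w
    phi = basis.phi
    G = (phi @ phi.T).tocsc()
    rhs = phi @ W.T  # (Q, N)
    lu = spla.splu(G)
    q = G.shape[0]
    inv_op = spla.LinearOperator((q, q), matvec=lu.solve, rmatvec=lu.solve)
    est_cond = spla.norm(G, 1) * spla.onenormest(inv_op)
    if est_cond > COND_WARN:
        warnings.warn(
            f"cycle-basis Gram matrix is ill-conditioned (~{est_cond:.2g}); "
            "coefficients may be inaccurate",
            stacklevel=3,
        )
    return lu.solve(np.asarray(rhs)).T


def project(
    w: np.ndarray, basis: CycleBasis, method: str = "qr"
) -> np.ndarray:
    """Least-squares cycle coefficients of one or many edge vectors.

    Parameters
    ----------
    w : (m,) edge vector or (N, m) stack of subject edge vectors.
    basis : common cycle basis from the group template.
    method : ``"qr"`` — dense rank-revealing least squares (default);
        ``"normal"`` — sparse normal equations with an LU factorization and
        a condition-number warning, for the large-Q regime.

    Returns
    -------
    alpha : (Q,) or (N, Q) coefficients in the same units as ``w``
        (Fisher z along unit cycle directions).
    """
    W = np.atleast_2d(np.asarray(w, dtype=float))
    if W.shape[1] != basis.m:
        raise ValueError(f"edge vector length {W.shape[1]} != m={basis.m}")
    if method == "normal":
        A = _gram_solve(basis, W)
    elif method == "qr":
        phiT = basis.phi.T.toarray()  # (m, Q)
        sol, _, rank, _ = scipy.linalg.lstsq(phiT, W.T, lapack_driver="gelsy")
        if rank < basis.q:
            raise ValueError(
                f"cycle basis is rank deficient (rank {rank} < Q={basis.q}); "
                "basis appears corrupted"
            )
        A = sol.T
    else:
        raise ValueError(f"unknown method {method!r}")
    return A[0] if np.asarray(w).ndim == 1 else A


def hodge_decompose(
    w: np.ndarray, b1: sp.spmatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal split of an edge flow into gradient and harmonic parts.

    The gradient part is the projection onto ``img(B1^T)`` (flows induced by
    node potentials); the harmonic part is the remainder, a circulation in
    ``ker(B1)``.  With no triangles in the complex the curl component is
    identically zero, so the two parts reconstruct ``w`` exactly and
    ``||w||^2 = ||grad||^2 + ||harm||^2``.
    """
    w = np.asarray(w, dtype=float)
    B = b1.toarray() if sp.issparse(b1) else np.asarray(b1, dtype=float)
    if w.shape != (B.shape[1],):
        raise ValueError(f"edge vector length {w.shape} != m={B.shape[1]}")
    f, *_ = scipy.linalg.lstsq(B.T, w)  # node potential
    grad = B.T @ f
    return grad, w - grad


def decompose_mst_extra(
    w: np.ndarray,
    tree: TreeDecomposition,
    basis: CycleBasis,
    method: str = "qr",
) -> MstExtraSplit:
    """Split a subject's cycle coefficients by the subject's own MST.

    ``w_MST`` is the edge vector masked to the subject-specific maximum
    spanning tree, ``w_Extra = w - w_MST`` the off-tree remainder; each part
    is projected onto the common (template) basis.  Additivity
    ``alpha_MST + alpha_Extra = alpha`` holds by linearity.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (basis.m,):
        raise ValueError(f"edge vector length {w.shape} != m={basis.m}")
    w_mst = np.zeros_like(w)
    w_mst[tree.mst_edges] = w[tree.mst_edges]
    alpha_mst = project(w_mst, basis, method=method)
    alpha_extra = project(w - w_mst, basis, method=method)
    return MstExtraSplit(alpha_mst=alpha_mst, alpha_extra=alpha_extra)


def subject_splits(
    W: np.ndarray, n: int, basis: CycleBasis, method: str = "qr"
) -> MstExtraSplit:
    """MST/extra split for a cohort: each row of ``W`` is masked by its own
    subject-specific MST, then projected onto the common basis."""
    from .topology import maximum_spanning_tree  # local import avoids cycle

    W = np.asarray(W, dtype=float)
    W_mst = np.zeros_like(W)
    for i in range(W.shape[0]):
        tr = maximum_spanning_tree(WeightedGraph(n=n, w=W[i]))
        W_mst[i, tr.mst_edges] = W[i, tr.mst_edges]
    alpha_mst = project(W_mst, basis, method=method)
    alpha_extra = project(W - W_mst, basis, method=method)
    return MstExtraSplit(alpha_mst=alpha_mst, alpha_extra=alpha_extra)


def gradient_flow(n: int, f: np.ndarray) -> np.ndarray:
    """Edge flow induced by a node potential, ``B1^T f`` — useful for
    constructing pure-gradient test inputs."""
    B = incidence_matrix(n)
    return np.asarray(B.T @ np.asarray(f, dtype=float))
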