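"""Algebraic-topology core: filtration, boundary matrices, Hodge Laplacians
and the fundamental harmonic 1-cycle basis.

The graph filtration (deleting edges in decreasing weight order) partitions
the edge set into *birth* edges — a maximum spanning tree (MST), which
creates connected components — and *death* (off-tree) edges, each of which
destroys exactly one independent loop.  Adding an off-tree edge back to the
MST creates a unique fundamental 1-cycle; the set of all such cycles is a
linearly independent basis of the cycle space (the kernel of the
node-edge incidence matrix B1, equivalently the kernel of the 1-Hodge
Laplacian L1 = B1^T B1 since no 2-simplices are included).

Two equivalent constructions of each harmonic cycle are provided:

* ``method="eig"`` — eigendecompose L1 of the subgraph MST + closing edge
  and extract the unique zero-eigenvalue eigenvector (the spectral
  definition of the harmonic component);
* ``method="path"`` — walk the tree path between the closing edge's
  endpoints and assign equal-magnitude signed coefficients (the closed-form
  circulation).

Both return the same vector (tests enforce this); the path route is the
default because it scales to the full connectome (m ≈ 5e4 edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import WeightedGraph, edge_list, n_edges

__all__ = [
    "TreeDecomposition",
    "CycleBasis",
    "HarmonicCycle",
    "maximum_spanning_tree",
    "graph_filtration",
    "incidence_matrix",
    "hodge_laplacians",
    "betti_numbers",
    "harmonic_cycle",
    "build_cycle_basis",
]

# Relative zero tolerance for eigenvalue multiplicity counts; scale-free and
# robust up to m ~ 5e4.
ZERO_TOL = 1e-8


@dataclass(frozen=True)
class TreeDecomposition:
    """Birth-death partition of the edge set of a connected graph.

    Attributes
    ----------
    n : node count.
    mst_edges : indices (into the canonical edge order) of the maximum
        spanning tree — the birth set, size ``n - 1``.
    offtree_edges : complementary death set, size ``m - n + 1``, ascending.
    filtration_order : all edge indices sorted by ascending weight, i.e. the
        thresholds eps_1 < ... < eps_m of the nested subgraph sequence.
    thresholds : the sorted weights themselves.
    """

    n: int
    mst_edges: np.ndarray = field(repr=False)
    offtree_edges: np.ndarray = field(repr=False)
    filtration_order: np.ndarray | None = field(default=None, repr=False)
    thresholds: np.ndarray | None = field(default=None, repr=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, a: int) -> int:
        p = self.parent
        root = a
        while p[root] != root:
            root = p[root]
        while p[a] != root:
            p[a], a = root, p[a]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(g: WeightedGraph) -> TreeDecomposition:
    """Kruskal maximum spanning tree with deterministic tie-breaking.

    Edges are taken in descending weight, ties broken by ascending canonical
    edge index, so degenerate (equal-weight) inputs still give a
    reproducible birth-death partition.

    Raises
    ------
    ValueError if the graph is disconnected.
    """
    m = g.m
    edges = g.edges
    # non-finite weights mark absent edges (the graph need not be complete)
    present = np.flatnonzero(np.isfinite(g.w))
    # stable sort on -w keeps ascending-index order within ties
    order = present[np.argsort(-g.w[present], kind="stable")]
    uf = _UnionFind(g.n)
    mst = []
    for e in order:
        if uf.union(int(edges[e, 0]), int(edges[e, 1])):
            mst.append(int(e))
            if len(mst) == g.n - 1:
                break
    if len(mst) != g.n - 1:
        raise ValueError("graph is disconnected: no spanning tree exists")
    mst_idx = np.sort(np.asarray(mst, dtype=np.int64))
    mask = np.ones(m, dtype=bool)
    mask[mst_idx] = False
    return TreeDecomposition(
        n=g.n, mst_edges=mst_idx, offtree_edges=np.flatnonzero(mask)
    )


def graph_filtration(g: WeightedGraph) -> TreeDecomposition:
    """Birth-death decomposition with the filtration threshold sequence.

    Identical partition to :func:`maximum_spanning_tree`, plus the sorted
    edge-weight thresholds defining the nested subgraph sequence obtained by
    repeatedly removing the highest-weight edge.
    """
    tree = maximum_spanning_tree(g)
    order = np.argsort(g.w, kind="stable")
    return TreeDecomposition(
        n=g.n,
        mst_edges=tree.mst_edges,
        offtree_edges=tree.offtree_edges,
        filtration_order=order,
        thresholds=g.w[order],
    )


def incidence_matrix(n: int, edges: np.ndarray | None = None) -> sp.csc_matrix:
    """Signed node-edge incidence matrix B1 (the 1st boundary matrix).

    Orientation is ascending node index: the column for edge ``(i, j)`` with
    ``i < j`` has ``-1`` at row ``i`` (tail) and ``+1`` at row ``j`` (head).

    Parameters
    ----------
    n : node count.
    edges : (k, 2) integer array of node pairs; defaults to the complete
        canonical edge list.
    """
    if edges is None:
        edges = edge_list(n)
    edges = np.asarray(edges, dtype=np.int64)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise ValueError("edges must be a (k, 2) array")
    if np.any(edges < 0) or np.any(edges >= n):
        raise ValueError("edge endpoint out of range")
    if np.any(edges[:, 0] >= edges[:, 1]):
        raise ValueError("edges must satisfy i < j (canonical orientation)")
    if len({(int(i), int(j)) for i, j in edges}) != len(edges):
        raise ValueError("duplicate edges")
    k = edges.shape[0]
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([np.arange(k), np.arange(k)])
    data = np.concatenate([-np.ones(k), np.ones(k)])
    return sp.csc_matrix((data, (rows, cols)), shape=(n, k))


def hodge_laplacians(b1: sp.spmatrix) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """The 0- and 1-dimensional Hodge Laplacians of a graph complex.

    With no 2-simplices the boundary map B2 is the zero map, so
    ``L0 = B1 B1^T`` (the ordinary graph Laplacian: node degrees on the
    diagonal, -1 for each edge) and ``L1 = B1^T B1`` acting on edge flows.
    """
    b1 = sp.csc_matrix(b1)
    L0 = (b1 @ b1.T).tocsr()
    L1 = (b1.T @ b1).tocsr()
    return L0, L1


def _zero_multiplicity(L: np.ndarray, tol: float) -> int:
    evals = np.linalg.eigvalsh(L)
    lam_max = max(float(evals[-1]), 1.0)
    return int(np.sum(evals < tol * lam_max))


def betti_numbers(
    L0: sp.spmatrix | np.ndarray,
    L1: sp.spmatrix | np.ndarray,
    tol: float = ZERO_TOL,
) -> tuple[int, int]:
    """Betti numbers from zero-eigenvalue multiplicities.

    beta_0 (connected components) is the multiplicity of the zero eigenvalue
    of L0; beta_1 (independent loops) that of L1.  An eigenvalue counts as
    zero when it is below ``tol * max(lambda_max, 1)``.
    """
    out = []
    for L in (L0, L1):
        A = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
        if A.size and np.max(np.abs(A - A.T)) > 1e-10:
            raise ValueError("Laplacian must be symmetric")
        out.append(_zero_multiplicity(A, tol))
    return out[0], out[1]


@dataclass(frozen=True)
class HarmonicCycle:
    """A fundamental 1-cycle embedded in the full m-dimensional edge space.

    ``coeffs`` is unit Euclidean norm with equal-magnitude entries on the
    cycle's support (the tree path between the closing edge's endpoints plus
    the closing edge itself) and sign fixed so the closing-edge coefficient
    is positive.  It spans the kernel of L1 of the subgraph MST + closing
    edge.
    """

    coeffs: np.ndarray = field(repr=False)
    support: np.ndarray = field(repr=False)
    closing_edge: int

    @property
    def length(self) -> int:
        """Number of edges in the loop."""
        return int(self.support.size)


class _RootedTree:
    """MST rooted at node 0 with parent pointers, for fast path walks."""

    def __init__(self, n: int, mst_edges: np.ndarray, edges: np.ndarray):
        adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for e in mst_edges:
            i, j = int(edges[e, 0]), int(edges[e, 1])
            adj[i].append((j, int(e)))
            adj[j].append((i, int(e)))
        parent = np.full(n, -1, dtype=np.int64)
        parent_edge = np.full(n, -1, dtype=np.int64)
        depth = np.zeros(n, dtype=np.int64)
        seen = np.zeros(n, dtype=bool)
        seen[0] = True
        stack = [0]
        while stack:
            u = stack.pop()
            for v, e in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    parent[v] = u
                    parent_edge[v] = e
                    depth[v] = depth[u] + 1
                    stack.append(v)
        if not seen.all():
            raise ValueError("mst_edges do not span all nodes")
        self.parent = parent
        self.parent_edge = parent_edge
        self.depth = depth
        self.edges = edges

    def cycle_of(self, closing_edge: int) -> tuple[np.ndarray, np.ndarray]:
        """Edge indices and orientation signs of the fundamental cycle.

        The loop is traversed starting along the closing edge (i, j), i < j,
        in its own orientation i -> j, then back along the tree path from j
        to i; a traversed tree edge gets +1 when walked tail -> head
        (ascending node index) and -1 otherwise.
        """
        i, j = int(self.edges[closing_edge, 0]), int(self.edges[closing_edge, 1])
        idx: list[int] = [closing_edge]
        sgn: list[float] = [1.0]
        u, v = j, i  # walk from j back to i through the tree
        up_u: list[tuple[int, float]] = []
        up_v: list[tuple[int, float]] = []
        while self.depth[u] > self.depth[v]:
            p = self.parent[u]
            # traversal u -> p matches edge orientation iff u is the tail
            up_u.append((int(self.parent_edge[u]), 1.0 if u < p else -1.0))
            u = p
        while self.depth[v] > self.depth[u]:
            p = self.parent[v]
            up_v.append((int(self.parent_edge[v]), 1.0 if v < p else -1.0))
            v = p
        while u != v:
            pu, pv = self.parent[u], self.parent[v]
            up_u.append((int(self.parent_edge[u]), 1.0 if u < pu else -1.0))
            up_v.append((int(self.parent_edge[v]), 1.0 if v < pv else -1.0))
            u, v = pu, pv
        # path j -> lca uses up_u as-is; lca -> i reverses up_v's traversal
        for e, s in up_u:
            idx.append(e)
            sgn.append(s)
        for e, s in reversed(up_v):
            idx.append(e)
            sgn.append(-s)
        return np.asarray(idx, dtype=np.int64), np.asarray(sgn)


def _harmonic_from_path(
    tree: _RootedTree, closing_edge: int, m: int
) -> HarmonicCycle:
    idx, sgn = tree.cycle_of(closing_edge)
    coeffs = np.zeros(m)
    coeffs[idx] = sgn / np.sqrt(idx.size)
    return HarmonicCycle(
        coeffs=coeffs, support=np.sort(idx), closing_edge=int(closing_edge)
    )


def _harmonic_from_eig(
    tree_dec: TreeDecomposition, closing_edge: int, g: WeightedGraph
) -> HarmonicCycle:
    sub = np.sort(np.append(tree_dec.mst_edges, closing_edge))
    edges = g.edges[sub]
    b1 = incidence_matrix(g.n, edges)
    L1 = (b1.T @ b1).toarray()
    evals, evecs = np.linalg.eigh(L1)
    lam_max = max(float(evals[-1]), 1.0)
    kernel = np.flatnonzero(evals < ZERO_TOL * lam_max)
    if kernel.size != 1:
        raise ValueError(
            f"L1 kernel of MST + edge {closing_edge} has dimension "
            f"{kernel.size}, expected 1 (broken tree?)"
        )
    v = evecs[:, kernel[0]]
    pos = int(np.searchsorted(sub, closing_edge))
    if v[pos] < 0:
        v = -v
    coeffs = np.zeros(g.m)
    coeffs[sub] = v
    support = sub[np.abs(v) > 1e-10]
    return HarmonicCycle(coeffs=coeffs, support=support, closing_edge=int(closing_edge))


def harmonic_cycle(
    tree: TreeDecomposition,
    closing_edge: int,
    g: WeightedGraph,
    method: str = "path",
) -> HarmonicCycle:
    """The unique fundamental 1-cycle closed by an off-tree edge.

    Parameters
    ----------
    tree : birth-death decomposition of ``g``.
    closing_edge : canonical index of an off-tree edge.
    g : the graph (supplies node count and edge order; for ``method="eig"``
        also the subgraph construction).
    method : ``"path"`` (closed-form tree-path circulation, default) or
        ``"eig"`` (zero-eigenvector of the subgraph L1).
    """
    if closing_edge not in set(tree.offtree_edges.tolist()):
        raise ValueError(f"edge {closing_edge} is not an off-tree edge")
    if method == "eig":
        return _harmonic_from_eig(tree, closing_edge, g)
    if method == "path":
        rooted = _RootedTree(g.n, tree.mst_edges, g.edges)
        return _harmonic_from_path(rooted, closing_edge, g.m)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class CycleBasis:
    """The fundamental 1-cycle basis of a connected graph.

    Attributes
    ----------
    phi : sparse ``(Q, m)`` matrix of unit-norm cycle vectors, one row per
        off-tree edge, ordered by ascending closing-edge index.
    closing_edges : the off-tree edge index closing each cycle.
    n, m : node and edge counts of the underlying graph.
    """

    phi: sp.csr_matrix = field(repr=False)
    closing_edges: np.ndarray = field(repr=False)
    n: int
    m: int

    @property
    def q(self) -> int:
        """Number of cycles, Q = m - n + 1."""
        return self.phi.shape[0]

    def cycle(self, k: int) -> HarmonicCycle:
        row = self.phi.getrow(k)
        coeffs = np.asarray(row.todense()).ravel()
        return HarmonicCycle(
            coeffs=coeffs,
            support=np.sort(row.indices.astype(np.int64)),
            closing_edge=int(self.closing_edges[k]),
        )

    def cycle_lengths(self) -> np.ndarray:
        """Edges per cycle (support sizes)."""
        return np.diff(self.phi.indptr)


def build_cycle_basis(g: WeightedGraph, method: str = "path") -> CycleBasis:
    """Construct the full fundamental 1-cycle basis of a connected graph.

    One harmonic cycle per off-tree (death) edge of the maximum spanning
    tree, ordered by ascending canonical closing-edge index, assembled into
    a sparse ``Q x m`` matrix with ``Q = m - n + 1``.
    """
    tree = maximum_spanning_tree(g)
    if method == "eig":
        rows = [
            _harmonic_from_eig(tree, int(e), g).coeffs for e in tree.offtree_edges
        ]
        phi = sp.csr_matrix(np.vstack(rows)) if rows else sp.csr_matrix((0, g.m))
        return CycleBasis(
            phi=phi, closing_edges=tree.offtree_edges.copy(), n=g.n, m=g.m
        )
    rooted = _RootedTree(g.n, tree.mst_edges, g.edges)
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for e in tree.offtree_edges:
        idx, sgn = rooted.cycle_of(int(e))
        order = np.argsort(idx)
        indices.append(idx[order])
        data.append(sgn[order] / np.sqrt(idx.size))
        indptr.append(indptr[-1] + idx.size)
    phi = sp.csr_matrix(
        (
            np.concatenate(data) if data else np.empty(0),
            np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
            np.asarray(indptr, dtype=np.int64),
        ),
        shape=(len(tree.offtree_edges), g.m),
    )
    return CycleBasis(phi=phi, closing_edges=tree.offtree_edges.copy(), n=g.n, m=g.m)
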