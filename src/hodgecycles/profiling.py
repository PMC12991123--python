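"""Network-level functional profiles of significant cycles.

Each edge is assigned to one of ``K(K+1)/2`` categories — intra-network plus
unordered inter-network pairs over the K large brain networks labeling the
nodes (K = 10 gives the canonical 55 categories).  A cycle's binarized edge
support is counted over the categories and normalized by the cycle length,
giving a profile on the probability simplex.  Profiles are compared by
cosine distance and grouped by average-linkage agglomerative clustering cut
at similarity 0.5 (= cosine distance 0.5); clusters are summarized by the
three quantities of the radial plot: cycle count, mean fraction of
edge-wise-significant edges, and mean cycle length normalized by the
maximum cluster mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .graph import edge_list
from .topology import CycleBasis

__all__ = [
    "NetworkLabels",
    "CycleProfile",
    "edge_categories",
    "cycle_profile",
    "profile_distances",
    "cluster_profiles",
    "summarize_clusters",
]


@dataclass(frozen=True)
class NetworkLabels:
    """One network name per node, over a label set of size K >= 2."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) < 2:
            raise ValueError("need at least 2 distinct network labels")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def networks(self) -> tuple[str, ...]:
        """Sorted distinct network names."""
        return tuple(sorted(set(self.labels)))

    @property
    def k(self) -> int:
        return len(self.networks)


def category_names(labels: NetworkLabels) -> list[str]:
    """Names of the K(K+1)/2 categories: intra first by network order, then
    unordered inter pairs, lexicographic."""
    nets = labels.networks
    names = [f"{a}-{a}" for a in nets]
    for i, a in enumerate(nets):
        for b in nets[i + 1 :]:
            names.append(f"{a}-{b}")
    return names


def edge_categories(labels: NetworkLabels, n: int) -> np.ndarray:
    """Category index of every canonical edge.

    The category of edge (i, j) is the unordered pair of its endpoint
    network labels; symmetric in node order.  Returns an (m,) integer array
    indexing into :func:`category_names`.
    """
    if len(labels.labels) != n:
        raise ValueError(
            f"{len(labels.labels)} labels for {n} nodes; every node needs one"
        )
    nets = labels.networks
    pair_to_cat: dict[tuple[str, str], int] = {}
    c = 0
    for a in nets:
        pair_to_cat[(a, a)] = c
        c += 1
    for i, a in enumerate(nets):
        for b in nets[i + 1 :]:
            pair_to_cat[(a, b)] = c
            c += 1
    edges = edge_list(n)
    out = np.empty(edges.shape[0], dtype=np.int64)
    for e, (i, j) in enumerate(edges):
        a, b = sorted((labels.labels[i], labels.labels[j]))
        out[e] = pair_to_cat[(a, b)]
    return out


@dataclass(frozen=True)
class CycleProfile:
    """Normalized category counts of one cycle's edge support."""

    counts: np.ndarray = field(repr=False)  # sums to 1
    cycle_length: int
    frac_significant_edges: float = np.nan


def cycle_profile(
    support: np.ndarray,
    categories: np.ndarray,
    n_categories: int,
    significant_edges: np.ndarray | None = None,
) -> CycleProfile:
    """Profile of a cycle from its (binarized) edge support.

    Counts the support edges per category and divides by the cycle length;
    if an edge-wise significance mask is supplied, also records the fraction
    of the cycle's edges passing it.
    """
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("cycle has empty support")
    counts = np.bincount(categories[support], minlength=n_categories).astype(float)
    counts /= support.size
    frac = np.nan
    if significant_edges is not None:
        frac = float(np.asarray(significant_edges, dtype=bool)[support].mean())
    return CycleProfile(
        counts=counts, cycle_length=support.size, frac_significant_edges=frac
    )


def profiles_for_cycles(
    basis: CycleBasis,
    cycles: Sequence[int],
    labels: NetworkLabels,
    significant_edges: np.ndarray | None = None,
) -> list[CycleProfile]:
    """Profiles of selected basis cycles."""
    cats = edge_categories(labels, basis.n)
    ncat = labels.k * (labels.k + 1) // 2
    out = []
    for k in cycles:
        row = basis.phi.getrow(int(k))
        out.append(
            cycle_profile(
                row.indices.astype(np.int64), cats, ncat, significant_edges
            )
        )
    return out


def profile_distances(profiles: Sequence[CycleProfile]) -> np.ndarray:
    """Pairwise cosine distances, ``1 - a.b / (|a||b|)``; symmetric, zero
    diagonal, in [0, 1] for the nonnegative profile vectors."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    P = np.stack([p.counts for p in profiles])
    norms = np.linalg.norm(P, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm profile")
    C = (P @ P.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(C, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def cluster_profiles(distances: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Average-linkage agglomerative clustering cut at a cosine-distance
    threshold (similarity = 1 - distance, so the default 0.5 matches a
    similarity threshold of 0.5).

    Returns 0-based cluster ids ordered by first appearance; a single
    profile forms one cluster.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 2:
        return np.zeros(D.shape[0], dtype=int)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    raw = sch.fcluster(Z, t=threshold, criterion="distance")
    # relabel by first appearance for deterministic, order-stable ids
    out = np.empty_like(raw)
    seen: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen)
        out[i] = seen[r]
    return out.astype(int)


def summarize_clusters(
    assignment: np.ndarray, profiles: Sequence[CycleProfile]
) -> pd.DataFrame:
    """Cluster-level radial-plot quantities.

    Per cluster: cycle count, mean fraction of edge-wise-significant edges
    (wedge height), mean cycle length and the same normalized by the
    maximum of the cluster means (the dot position, in (0, 1] with max 1).
    """
    assignment = np.asarray(assignment, dtype=int)
    if assignment.size != len(profiles):
        raise ValueError("assignment and profiles are misaligned")
    rows = []
    for c in np.unique(assignment):
        members = [profiles[i] for i in np.flatnonzero(assignment == c)]
        rows.append(
            {
                "cluster": int(c),
                "n_cycles": len(members),
                "mean_frac_significant": float(
                    np.mean([p.frac_significant_edges for p in members])
                ),
                "mean_length": float(np.mean([p.cycle_length for p in members])),
            }
        )
    df = pd.DataFrame(rows)
    df["norm_mean_length"] = df["mean_length"] / df["mean_length"].max()
    return df


def radial_plot(summary: pd.DataFrame, path: str) -> None:
    """Radial bar plot of the cluster summary: wedge height = mean fraction
    of significant edges, color = cycle count, dot = normalized mean
    length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(summary)
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    width = 2 * np.pi / max(k, 1) * 0.9
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    colors = plt.cm.viridis(summary["n_cycles"] / summary["n_cycles"].max())
    ax.bar(theta, summary["mean_frac_significant"], width=width, color=colors)
    ax.plot(theta, summary["norm_mean_length"], "o", color="crimson")
    ax.set_ylim(0, 1.05)
    ax.set_title("Cycle clusters: wedge = frac significant edges, dot = norm length")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def distance_heatmap(distances: np.ndarray, assignment: np.ndarray, path: str) -> None:
    """Heatmap of pairwise cosine distances, rows ordered by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(assignment, kind="stable")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(distances[np.ix_(order, order)], cmap="magma", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="cosine distance")
    ax.set_title("Pairwise cycle-profile distances (cluster-ordered)")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
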