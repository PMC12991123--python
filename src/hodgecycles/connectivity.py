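"""From ROI time series to Fisher-z functional-connectivity graphs.

Pipeline stage one: temporal high-pass filtering of regional BOLD signals,
Pearson correlation with Fisher z-transformation, canonical edge
vectorization, and the group-averaged template graph from which the common
cycle basis is later built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .graph import WeightedGraph, vectorize_upper

__all__ = [
    "RoiTimeSeries",
    "gaussian_highpass",
    "fisher_z_fc",
    "group_average",
]

# |r| is clipped just inside 1 so that atanh stays finite on degenerate
# (perfectly collinear) inputs.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class RoiTimeSeries:
    """A ``T x n`` matrix of regional time series.

    Attributes
    ----------
    values : (T, n) array, one column per ROI (arbitrary signal units).
    tr_s : repetition time in seconds.
    node_ids : ordered ROI identifiers; defaults to ``["roi0", ...]``.
    """

    values: np.ndarray = field(repr=False)
    tr_s: float = 1.0
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError(f"time series must be T x n with T >= 2, got {v.shape}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        ids = self.node_ids
        if ids is None:
            ids = tuple(f"roi{k}" for k in range(v.shape[1]))
        elif len(ids) != v.shape[1]:
            raise ValueError("node_ids length does not match number of columns")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_ids", tuple(ids))

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def _gaussian_running_mean(x: np.ndarray, sigma: float) -> np.ndarray:
    # Gaussian-weighted running mean with the kernel renormalized at the
    # boundaries (truncated at +/-4 sigma), applied along axis 0.
    radius = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    smoothed = correlate1d(x, kernel, axis=0, mode="constant", cval=0.0)
    norm = correlate1d(np.ones(x.shape[0]), kernel, mode="constant", cval=0.0)
    return smoothed / norm[:, None]


def gaussian_highpass(ts: RoiTimeSeries, width_s: float) -> RoiTimeSeries:
    """High-pass filter each column by subtracting a Gaussian-weighted
    running mean.

    The filter width is given in seconds; the Gaussian kernel standard
    deviation in samples is ``width_s / (2 * tr_s)`` (the common
    width-equals-2-sigma convention of FSL-style detrending), truncated at
    four standard deviations and renormalized at the series boundaries.

    Parameters
    ----------
    ts : input time series.
    width_s : filter width in seconds; must exceed the repetition time.
    """
    if width_s <= ts.tr_s:
        raise ValueError(f"width_s={width_s} must exceed tr_s={ts.tr_s}")
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to high-pass filter")
    sigma = width_s / (2.0 * ts.tr_s)
    trend = _gaussian_running_mean(ts.values, sigma)
    return RoiTimeSeries(values=ts.values - trend, tr_s=ts.tr_s, node_ids=ts.node_ids)


def fisher_z_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Fisher z-transformed Pearson correlation matrix of the columns.

    Correlations are clipped to ``+/-(1 - 1e-7)`` before ``atanh`` so that
    perfectly collinear columns yield a large finite z rather than infinity.
    The diagonal is set to zero by convention.

    Returns
    -------
    (n, n) symmetric matrix of Fisher-z values, zero diagonal.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = ts.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.node_ids[k] for k in bad[:5])
        raise ValueError(f"zero-variance ROI column(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


def group_average(graphs: Sequence[WeightedGraph]) -> WeightedGraph:
    """Element-wise mean of subject edge-weight vectors — the network
    template from which the common cycle basis is derived."""
    if not graphs:
        raise ValueError("need at least one graph to average")
    n = graphs[0].n
    for g in graphs:
        if g.n != n:
            raise ValueError(f"node-count mismatch: {g.n} vs {n}")
    W = np.stack([g.w for g in graphs])
    return WeightedGraph(n=n, w=W.mean(axis=0))


def fc_graph(ts: RoiTimeSeries) -> WeightedGraph:
    """Convenience: Fisher-z FC matrix vectorized into a WeightedGraph."""
    return WeightedGraph(n=ts.n_nodes, w=vectorize_upper(fisher_z_fc(ts)))
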