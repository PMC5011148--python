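"""Projections of multiplex snapshots and the three distance series.

A time series of multiplex networks is reduced to real-valued series in two
steps: each snapshot is projected to a single graph, and the HIM distance
from the first element of the projected sequence is recorded at every time
step.

Two projections are available.  The *metric projection* is the complete
weighted graph on the λ layers whose edge weights are the HIM similarities
1 - HIM(L_i, L_j) between layers — a network of networks that retains the
inter-layer structure.  The *collapsed projection* merges the layers into a
single graph on the original ν nodes (boolean OR for binary layers, the
entrywise mean for weighted ones) and discards which layer a link came from.

The distance series are:

* D1 (per layer i):  HIM(L_i(t), L_i(1))
* D1-mean:           the average of the λ D1 series
* D2:                HIM(CN(t), CN(1)) on collapsed projections
* D3:                HIM(LN(t), LN(1)) on metric projections

Each series is materialized for t = 1..τ with value 0 at t = 1 (the anchor
compared against itself), so changepoint indices are reported on the full
1-based time axis.

Caveat on D2: if at every time step every node pair is covered by at least
one layer, the collapsed projection is constantly the full graph and D2 is
identically zero regardless of how the individual layers evolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph, MultiplexSeries, MultiplexSnapshot
from .him import HIMParams, him_distance, him_similarity

__all__ = [
    "MetricProjectionGraph",
    "CollapsedGraph",
    "DistanceSeries",
    "metric_projection",
    "collapsed_projection",
    "distance_series_d1",
    "distance_series_d1_mean",
    "distance_series_d2",
    "distance_series_d3",
]


@dataclass(frozen=True)
class DistanceSeries:
    """Real-valued HIM-distance-from-t=1 series.

    ``kind`` is one of ``"d1"`` (with ``layer`` set), ``"d1mean"``, ``"d2"``,
    ``"d3"``.  ``values[0]`` (t = 1) is 0 by construction.
    """

    values: np.ndarray
    kind: str
    timestamps: tuple[str, ...] = ()
    layer: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a distance series needs at least two values")
        if abs(v[0]) > 1e-12:
            raise ValueError("the anchor value (t=1) must be 0")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("distance values must lie in [0, 1]")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        stamps = tuple(str(x) for x in self.timestamps) or tuple(
            str(t + 1) for t in range(v.size)
        )
        if len(stamps) != v.size:
            raise ValueError("one timestamp per value required")
        object.__setattr__(self, "timestamps", stamps)

    @property
    def tau(self) -> int:
        return self.values.size

    def label(self) -> str:
        return f"d1[{self.layer}]" if self.kind == "d1" else self.kind


class MetricProjectionGraph(Graph):
    """Complete weighted graph on layer-nodes, weights = HIM similarities."""


class CollapsedGraph(Graph):
    """Single-layer merge of a snapshot (boolean OR or entrywise mean)."""

    mode: str = "binary"


def metric_projection(
    snap: MultiplexSnapshot, params: HIMParams | None = None
) -> MetricProjectionGraph:
    """Project a snapshot to the complete weighted graph on its λ layers.

    The weight of edge (i, j) is 1 - HIM(L_i, L_j); λ(λ-1)/2 HIM
    evaluations are performed.
    """
    lam = snap.n_layers
    if lam < 2:
        raise ValueError("the metric projection needs at least two layers")
    a = np.zeros((lam, lam))
    for i in range(lam):
        for j in range(i + 1, lam):
            a[i, j] = a[j, i] = him_similarity(snap.layers[i], snap.layers[j], params)
    # rounding in the distance can overshoot the unit interval by ~1e-16
    np.clip(a, 0.0, 1.0, out=a)
    return MetricProjectionGraph(a, snap.layer_names)


def collapsed_projection(
    snap: MultiplexSnapshot, mode: str = "auto"
) -> CollapsedGraph:
    """Merge all layers of a snapshot into one graph on the original nodes.

    ``mode``: ``"binary"`` (boolean OR), ``"weighted"`` (entrywise mean), or
    ``"auto"`` (OR iff every layer is binary).
    """
    if mode not in ("auto", "binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    stacked = np.stack([lay.adjacency for lay in snap.layers])
    if mode == "auto":
        mode = "binary" if all(lay.is_binary for lay in snap.layers) else "weighted"
    if mode == "binary":
        a = (stacked > 0).any(axis=0).astype(np.float64)
    else:
        a = stacked.mean(axis=0)
    g = CollapsedGraph(a, snap.node_labels)
    object.__setattr__(g, "mode", mode)
    return g


def _anchored_series(graphs, params, kind, timestamps, layer=None) -> DistanceSeries:
    ref = graphs[0]
    vals = np.zeros(len(graphs))
    for t in range(1, len(graphs)):
        vals[t] = him_distance(ref, graphs[t], params)
    return DistanceSeries(vals, kind, timestamps, layer=layer)


def distance_series_d1(
    series: MultiplexSeries, layer: int, params: HIMParams | None = None
) -> DistanceSeries:
    """D1 for one layer (0-based index): HIM(L_i(t), L_i(1)) over t."""
    if not 0 <= layer < series.n_layers:
        raise IndexError(f"layer {layer} out of range 0..{series.n_layers - 1}")
    graphs = [snap.layers[layer] for snap in series.snapshots]
    return _anchored_series(
        graphs, params, "d1", series.timestamps, layer=series.layer_names[layer]
    )


def distance_series_d1_mean(
    series: MultiplexSeries, params: HIMParams | None = None
) -> DistanceSeries:
    """Pointwise mean of the λ per-layer D1 series."""
    stack = np.stack(
        [distance_series_d1(series, i, params).values for i in range(series.n_layers)]
    )
    return DistanceSeries(stack.mean(axis=0), "d1mean", series.timestamps)


def distance_series_d2(
    series: MultiplexSeries,
    params: HIMParams | None = None,
    mode: str = "auto",
) -> DistanceSeries:
    """D2: HIM between each collapsed projection and the first one."""
    graphs = [collapsed_projection(snap, mode) for snap in series.snapshots]
    return _anchored_series(graphs, params, "d2", series.timestamps)


def distance_series_d3(
    series: MultiplexSeries, params: HIMParams | None = None
) -> DistanceSeries:
    """D3: HIM between each metric projection and the first one.

    The compared graphs live on λ nodes and are weighted, so both the
    weighted Hamming and the weighted-Laplacian IM paths are exercised; γ̄
    is calibrated at N = λ here, separately from any layer-level N = ν
    calibration (both are cached).
    """
    graphs = [metric_projection(snap, params) for snap in series.snapshots]
    return _anchored_series(graphs, params, "d3", series.timestamps)
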