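"""Graph and multiplex data model.

All networks handled by this package are simple and undirected, with weights
in the unit interval: the adjacency matrix is symmetric, has a zero diagonal
and entries in [0, 1].  Node identity is by label; the matrix index order is
the declared label order, and two graphs are comparable only when their label
sequences match exactly (use :func:`align_nodes` to reorder explicitly).

A multiplex network is a set of layers (graphs on one shared node set), one
per link source; a multiplex series is a time-ordered sequence of such
snapshots on shared layers and nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Graph",
    "MultiplexSnapshot",
    "MultiplexSeries",
    "empty_graph",
    "full_graph",
    "cycle_graph",
    "star_graph",
    "graph_from_edges",
    "align_nodes",
    "laplacian_matrix",
    "laplacian_spectrum",
]

_ATOL = 0.0  # adjacency symmetry is required exactly; see module docstring


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"v{i}" for i in range(n))


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with weights in [0, 1].

    Parameters
    ----------
    adjacency
        Symmetric ``(n, n)`` float matrix, zero diagonal, entries in [0, 1].
    node_labels
        Ordered node identifiers; defaults to ``v0 .. v{n-1}``.
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        n = a.shape[0]
        if n < 2:
            raise ValueError(f"graphs need at least 2 nodes, got {n}")
        labels = tuple(str(x) for x in self.node_labels) or _default_labels(n)
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} nodes")
        if len(set(labels)) != n:
            raise ValueError("node labels must be distinct")
        if not np.array_equal(a, a.T):
            i, j = np.argwhere(a != a.T)[0]
            raise ValueError(f"adjacency not symmetric at ({i}, {j})")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed (nonzero diagonal)")
        if np.any(a < 0) or np.any(a > 1) or not np.all(np.isfinite(a)):
            raise ValueError("weights must lie in [0, 1]")
        a = a.copy()
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def is_binary(self) -> bool:
        a = self.adjacency
        return bool(np.all((a == 0.0) | (a == 1.0)))

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree (row sum) per node."""
        return self.adjacency.sum(axis=1)

    def edge_count(self) -> int:
        """Number of node pairs with nonzero weight."""
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def same_nodes(self, other: "Graph") -> bool:
        return self.node_labels == other.node_labels

    def require_comparable(self, other: "Graph") -> None:
        if not self.same_nodes(other):
            raise ValueError(
                "graphs are not comparable: node label sequences differ "
                f"({self.node_labels[:4]}... vs {other.node_labels[:4]}...)"
            )


def empty_graph(n: int, labels: Sequence[str] | None = None) -> Graph:
    """The empty network E_n: n nodes, no links."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return Graph(np.zeros((n, n)), tuple(labels) if labels else ())


def full_graph(n: int, labels: Sequence[str] | None = None) -> Graph:
    """The clique F_n: all n(n-1) links present."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return Graph(np.ones((n, n)) - np.eye(n), tuple(labels) if labels else ())


def cycle_graph(n: int) -> Graph:
    """Ring network on n nodes."""
    edges = [(i, (i + 1) % n) for i in range(n)]
    return graph_from_edges(n, edges)


def star_graph(n: int, hub: int = 0) -> Graph:
    """Star on n nodes with the given hub index."""
    edges = [(hub, i) for i in range(n) if i != hub]
    return graph_from_edges(n, edges)


def graph_from_edges(
    n: int,
    edges: Iterable[tuple[int, int] | tuple[int, int, float]],
    labels: Sequence[str] | None = None,
) -> Graph:
    """Build a graph from (i, j) or (i, j, weight) index pairs."""
    a = np.zeros((n, n))
    for e in edges:
        i, j = int(e[0]), int(e[1])
        w = float(e[2]) if len(e) > 2 else 1.0
        if i == j:
            raise ValueError(f"self-loop at node {i}")
        a[i, j] = a[j, i] = w
    return Graph(a, tuple(labels) if labels else ())


def align_nodes(g: Graph, labels: Sequence[str]) -> Graph:
    """Reorder a graph's nodes to the requested label order."""
    labels = tuple(str(x) for x in labels)
    if sorted(labels) != sorted(g.node_labels):
        raise ValueError("label sets differ; cannot align")
    idx = [g.node_labels.index(x) for x in labels]
    return Graph(g.adjacency[np.ix_(idx, idx)], labels)


def laplacian_matrix(g: Graph) -> np.ndarray:
    """L = D - A with D the diagonal matrix of (weighted) degrees."""
    return np.diag(g.degrees) - g.adjacency


def laplacian_spectrum(g: Graph, tol: float = 1e-9) -> np.ndarray:
    """Eigenvalues of the graph Laplacian, sorted ascending.

    The smallest eigenvalue of a valid Laplacian is 0; values in
    ``(-tol, 0)`` are clipped to 0, anything more negative raises.
    """
    ev = np.linalg.eigvalsh(laplacian_matrix(g))
    if ev[0] < -tol:
        raise ValueError(f"Laplacian eigenvalue {ev[0]} < -{tol}: invalid input")
    return np.clip(ev, 0.0, None)


@dataclass(frozen=True)
class MultiplexSnapshot:
    """One time step of a multiplex network: λ layers on ν shared nodes."""

    layers: tuple[Graph, ...]
    layer_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if len(layers) < 1:
            raise ValueError("a snapshot needs at least one layer")
        labels = layers[0].node_labels
        for k, lay in enumerate(layers):
            if lay.node_labels != labels:
                raise ValueError(f"layer {k} has a different node label sequence")
        names = tuple(str(x) for x in self.layer_names) or tuple(
            f"L{i + 1}" for i in range(len(layers))
        )
        if len(names) != len(layers) or len(set(names)) != len(names):
            raise ValueError("layer names must be distinct, one per layer")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "layer_names", names)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.layers[0].node_labels

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n


@dataclass(frozen=True)
class MultiplexSeries:
    """Time series of τ multiplex snapshots on shared layers and nodes."""

    snapshots: tuple[MultiplexSnapshot, ...]
    timestamps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        snaps = tuple(self.snapshots)
        if len(snaps) < 2:
            raise ValueError("a series needs at least two snapshots")
        ref = snaps[0]
        for t, s in enumerate(snaps):
            if s.layer_names != ref.layer_names:
                raise ValueError(f"snapshot {t} has different layer names")
            if s.node_labels != ref.node_labels:
                raise ValueError(f"snapshot {t} has different node labels")
        stamps = tuple(str(x) for x in self.timestamps) or tuple(
            str(t + 1) for t in range(len(snaps))
        )
        if len(stamps) != len(snaps):
            raise ValueError("one timestamp per snapshot required")
        object.__setattr__(self, "snapshots", snaps)
        object.__setattr__(self, "timestamps", stamps)

    @property
    def tau(self) -> int:
        return len(self.snapshots)

    @property
    def n_layers(self) -> int:
        return self.snapshots[0].n_layers

    @property
    def layer_names(self) -> tuple[str, ...]:
        return self.snapshots[0].layer_names

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.snapshots[0].node_labels
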