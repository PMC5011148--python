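"""Reading and writing graphs.

Three on-disk formats are supported:

``edgelist``
    UTF-8 text, one ``source target [weight]`` triple per line, whitespace
    separated, ``#`` comments.  An optional directive line
    ``%nodes a,b,c,...`` declares the node set and its order (required to
    represent isolated nodes).
``adjacency``
    Dense CSV; first row and first column carry the node labels.  The matrix
    must be exactly symmetric — silent symmetrization would hide data errors.
``graphml``
    Standard GraphML with undirected edges; the weight is the edge attribute
    ``weight`` (delegated to networkx).
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx
import numpy as np

from .graph import Graph

__all__ = ["read_graph", "write_graph", "graph_to_networkx", "graph_from_networkx"]

FORMATS = ("edgelist", "adjacency", "graphml")


class GraphFormatError(ValueError):
    """A file does not parse under the declared graph dialect."""


def _check_weight(w: float, where: str) -> float:
    if not (0.0 <= w <= 1.0) or not np.isfinite(w):
        raise GraphFormatError(f"weight {w} outside [0, 1] at {where}")
    return w


def _read_edgelist(path: str) -> Graph:
    declared: list[str] | None = None
    edges: list[tuple[str, str, float]] = []
    seen: dict[frozenset, tuple[float, int]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("%nodes"):
                declared = [x.strip() for x in line[len("%nodes"):].strip().split(",") if x.strip()]
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(f"{path}:{lineno}: expected 'source target [weight]'")
            u, v = parts[0], parts[1]
            if u == v:
                raise GraphFormatError(f"{path}:{lineno}: self-loop on node {u!r}")
            w = _check_weight(float(parts[2]) if len(parts) == 3 else 1.0, f"{path}:{lineno}")
            key = frozenset((u, v))
            if key in seen:
                w0, ln0 = seen[key]
                if w0 != w:
                    raise GraphFormatError(
                        f"{path}:{lineno}: duplicate edge {u}-{v} with conflicting "
                        f"weight {w} (line {ln0} had {w0})"
                    )
                continue
            seen[key] = (w, lineno)
            edges.append((u, v, w))
    if declared is None:
        declared = []
        for u, v, _ in edges:
            for x in (u, v):
                if x not in declared:
                    declared.append(x)
    if len(declared) < 2:
        raise GraphFormatError(f"{path}: fewer than two nodes")
    index = {lab: i for i, lab in enumerate(declared)}
    a = np.zeros((len(declared), len(declared)))
    for u, v, w in edges:
        if u not in index or v not in index:
            missing = u if u not in index else v
            raise GraphFormatError(f"{path}: edge endpoint {missing!r} not in %nodes declaration")
        a[index[u], index[v]] = a[index[v], index[u]] = w
    return Graph(a, tuple(declared))


def _write_edgelist(g: Graph, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%nodes " + ",".join(g.node_labels) + "\n")
        a = g.adjacency
        for i in range(g.n):
            for j in range(i + 1, g.n):
                if a[i, j] != 0.0:
                    w = float(a[i, j])
                    tail = "" if w == 1.0 else f" {w!r}"
                    fh.write(f"{g.node_labels[i]} {g.node_labels[j]}{tail}\n")


def _read_adjacency(path: str) -> Graph:
    with open(path, "r", encoding="utf-8") as fh:
        rows = [line.rstrip("\n") for line in fh if line.strip()]
    header = [x.strip() for x in rows[0].split(",")]
    labels = header[1:]
    n = len(labels)
    if len(rows) - 1 != n:
        raise GraphFormatError(f"{path}: {len(rows) - 1} data rows for {n} labels")
    a = np.zeros((n, n))
    for i, row in enumerate(rows[1:], start=0):
        cells = [x.strip() for x in row.split(",")]
        if cells[0] != labels[i]:
            raise GraphFormatError(
                f"{path}: row label {cells[0]!r} != column label {labels[i]!r} (row {i + 2})"
            )
        if len(cells) - 1 != n:
            raise GraphFormatError(f"{path}: row {i + 2} has {len(cells) - 1} values, want {n}")
        for j, cell in enumerate(cells[1:]):
            a[i, j] = _check_weight(float(cell), f"{path}: row {i + 2}, column {j + 2}")
    if not np.array_equal(a, a.T):
        i, j = np.argwhere(a != a.T)[0]
        raise GraphFormatError(f"{path}: adjacency not symmetric at ({labels[i]}, {labels[j]})")
    if np.any(np.diag(a) != 0):
        k = int(np.argwhere(np.diag(a) != 0)[0])
        raise GraphFormatError(f"{path}: self-loop on node {labels[k]!r}")
    return Graph(a, tuple(labels))


def _write_adjacency(g: Graph, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(g.node_labels) + "\n")
        for i, lab in enumerate(g.node_labels):
            fh.write(lab + "," + ",".join(repr(float(x)) for x in g.adjacency[i]) + "\n")


def graph_to_networkx(g: Graph) -> nx.Graph:
    gx = nx.Graph()
    gx.add_nodes_from(g.node_labels)
    a = g.adjacency
    for i in range(g.n):
        for j in range(i + 1, g.n):
            if a[i, j] != 0.0:
                gx.add_edge(g.node_labels[i], g.node_labels[j], weight=float(a[i, j]))
    return gx


def graph_from_networkx(gx: nx.Graph, node_order: Iterable[str] | None = None) -> Graph:
    labels = tuple(str(x) for x in (node_order if node_order is not None else gx.nodes()))
    index = {lab: i for i, lab in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)))
    for u, v, data in gx.edges(data=True):
        u, v = str(u), str(v)
        if u == v:
            raise GraphFormatError(f"self-loop on node {u!r}")
        w = _check_weight(float(data.get("weight", 1.0)), f"edge {u}-{v}")
        a[index[u], index[v]] = a[index[v], index[u]] = w
    return Graph(a, labels)


def _read_graphml(path: str) -> Graph:
    gx = nx.read_graphml(path)
    if gx.is_directed():
        raise GraphFormatError(f"{path}: directed graphs are not supported")
    return graph_from_networkx(gx)


def _write_graphml(g: Graph, path: str) -> None:
    nx.write_graphml(graph_to_networkx(g), path)


_READERS = {"edgelist": _read_edgelist, "adjacency": _read_adjacency, "graphml": _read_graphml}
_WRITERS = {"edgelist": _write_edgelist, "adjacency": _write_adjacency, "graphml": _write_graphml}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return {".graphml": "graphml", ".csv": "adjacency"}.get(ext, "edgelist")


def read_graph(path: str, format: str | None = None) -> Graph:
    """Read a graph; the format is inferred from the extension if omitted."""
    fmt = format or _infer_format(path)
    if fmt not in _READERS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    return _READERS[fmt](path)


def write_graph(g: Graph, path: str, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt not in _WRITERS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    _WRITERS[fmt](g, path)
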