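"""Weighted acupoint co-occurrence network: construction and standard exports.

Edge weights are co-occurrence proportions p_ij derived from the joint
study counts n_ij of an incidence matrix.  Three normalisations are
supported:

``global``
    p_ij = n_ij / N, the joint frequency over all N studies (default).
``jaccard``
    p_ij = n_ij / (f_i + f_j - n_ij), joint over union of study sets.
``conditional-max``
    p_ij = n_ij / min(f_i, f_j), joint over the rarer point's studies.

All three lie in [0, 1] and are zero exactly when the two points never
co-occur; zero-weight edges are never materialized.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import OccurrenceMatrix
from .errors import ValidationError

PROPORTION_MODES = ("global", "jaccard", "conditional-max")


class WeightedGraph:
    """Undirected graph with positively weighted edges and an ordered node list.

    The node order is significant: it defines the deterministic
    tie-breaking order used by the spanning-tree backbone and the default
    Louvain sweep order.  Edges are stored keyed on ``(u, v)`` with ``u``
    preceding ``v`` in node order.
    """

    def __init__(self, nodes: list[str]) -> None:
        if len(set(nodes)) != len(nodes):
            raise ValidationError("duplicate node labels")
        self.nodes: list[str] = list(nodes)
        self.rank: dict[str, int] = {u: i for i, u in enumerate(self.nodes)}
        self._adj: dict[str, dict[str, float]] = {u: {} for u in self.nodes}
        self.counts: dict[tuple[str, str], int] = {}

    # -- construction -----------------------------------------------------

    def add_edge(self, u: str, v: str, weight: float, count: int | None = None) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r} not allowed")
        if u not in self.rank or v not in self.rank:
            raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
        if not (weight > 0):
            raise ValidationError(f"edge weight must be positive, got {weight}")
        self._adj[u][v] = weight
        self._adj[v][u] = weight
        if count is not None:
            self.counts[self.edge_key(u, v)] = int(count)

    @classmethod
    def from_edges(cls, nodes: list[str],
                   edges: list[tuple[str, str, float]]) -> "WeightedGraph":
        g = cls(nodes)
        for u, v, w in edges:
            g.add_edge(u, v, w)
        return g

    # -- accessors --------------------------------------------------------

    def edge_key(self, u: str, v: str) -> tuple[str, str]:
        """Canonical (node-order) orientation of an edge."""
        return (u, v) if self.rank[u] < self.rank[v] else (v, u)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, {})

    def weight(self, u: str, v: str) -> float:
        return self._adj[u][v]

    def neighbors(self, u: str) -> dict[str, float]:
        return self._adj[u]

    def edges(self) -> list[tuple[str, str, float]]:
        """All edges in canonical orientation, ordered by node-order pair."""
        out = []
        for u in self.nodes:
            for v, w in self._adj[u].items():
                if self.rank[u] < self.rank[v]:
                    out.append((u, v, w))
        out.sort(key=lambda e: (self.rank[e[0]], self.rank[e[1]]))
        return out

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def strength(self, u: str) -> float:
        return float(sum(self._adj[u].values()))

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges())

    def connected_components(self) -> list[list[str]]:
        """Components as node lists, each in node order; components ordered
        by their first node."""
        seen: set[str] = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in self._adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            comps.append(sorted(comp, key=self.rank.get))
        return comps


# -- co-occurrence tables -------------------------------------------------

def cooccurrence_counts(m: OccurrenceMatrix) -> pd.DataFrame:
    """Symmetric table of joint study counts n_ij (diagonal zeroed, excluded)."""
    B = m.incidence
    C = B.T @ B
    np.fill_diagonal(C, 0)
    return pd.DataFrame(C, index=m.acupoints, columns=m.acupoints)


def cooccurrence_proportions(m: OccurrenceMatrix, mode: str = "global") -> pd.DataFrame:
    """Adjacency of co-occurrence proportions p_ij under the chosen mode."""
    if mode not in PROPORTION_MODES:
        raise ValidationError(f"unknown proportion mode {mode!r}; expected {PROPORTION_MODES}")
    C = cooccurrence_counts(m).to_numpy(dtype=float)
    f = m.frequencies.to_numpy(dtype=float)
    if mode == "global":
        P = C / m.n_studies
    elif mode == "jaccard":
        union = f[:, None] + f[None, :] - C
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(C > 0, C / union, 0.0)
    else:  # conditional-max
        denom = np.minimum(f[:, None], f[None, :])
        P = np.where(C > 0, C / denom, 0.0)
    np.fill_diagonal(P, 0.0)
    return pd.DataFrame(P, index=m.acupoints, columns=m.acupoints)


def build_graph(adj: pd.DataFrame, min_weight: float = 0.0,
                counts: pd.DataFrame | None = None) -> WeightedGraph:
    """Build a WeightedGraph from a symmetric proportion adjacency.

    Edges with p_ij > max(0, min_weight) are materialized; all nodes are
    retained even if isolated.  Node order follows the adjacency index.
    """
    A = adj.to_numpy(dtype=float)
    if adj.shape[0] != adj.shape[1] or list(adj.index) != list(adj.columns):
        raise ValidationError("adjacency must be square with matching index/columns")
    if not np.allclose(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 0.0):
        raise ValidationError("adjacency diagonal must be zero")
    g = WeightedGraph(list(adj.index))
    thresh = max(0.0, float(min_weight))
    nodes = g.nodes
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if A[i, j] > thresh:
                c = int(counts.iloc[i, j]) if counts is not None else None
                g.add_edge(nodes[i], nodes[j], float(A[i, j]), count=c)
    return g


def cooccurrence_graph(m: OccurrenceMatrix, mode: str = "global",
                       min_weight: float = 0.0) -> WeightedGraph:
    """Convenience: incidence matrix straight to weighted graph."""
    return build_graph(cooccurrence_proportions(m, mode),
                       min_weight=min_weight, counts=cooccurrence_counts(m))


# -- export / import ------------------------------------------------------

def export_graph(g: WeightedGraph, format: str, path: str | Path,
                 backbone=None) -> None:
    """Write the graph as ``graphml``, ``edge-list`` (TSV) or ``adjacency-csv``.

    The adjacency CSV follows the published convention: full-graph weights
    in the upper triangle and, when a spanning ``backbone`` is supplied,
    the surviving backbone weights in the lower triangle.
    """
    path = Path(path)
    try:
        if format == "graphml":
            _write_graphml(g, path)
        elif format == "edge-list":
            with open(path, "w", newline="") as fh:
                for u, v, w in sorted(g.edges()):
                    fh.write(f"{u}\t{v}\t{w:.12f}\n")
        elif format == "adjacency-csv":
            _write_adjacency(g, path, backbone)
        else:
            raise ValidationError(f"unknown export format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def _write_graphml(g: WeightedGraph, path: Path) -> None:
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    ET.SubElement(root, "key", id="w", **{"for": "edge", "attr.name": "weight",
                                          "attr.type": "double"})
    graph = ET.SubElement(root, "graph", id="G", edgedefault="undirected")
    for u in g.nodes:
        ET.SubElement(graph, "node", id=u)
    for u, v, w in g.edges():
        e = ET.SubElement(graph, "edge", source=u, target=v)
        d = ET.SubElement(e, "data", key="w")
        d.text = f"{w:.12f}"
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _write_adjacency(g: WeightedGraph, path: Path, backbone) -> None:
    n = g.n_nodes
    M = np.zeros((n, n))
    for u, v, w in g.edges():
        i, j = g.rank[u], g.rank[v]
        i, j = min(i, j), max(i, j)
        M[i, j] = w  # upper triangle: full graph
    if backbone is not None:
        for (u, v), w in backbone.edges.items():
            i, j = g.rank[u], g.rank[v]
            i, j = max(i, j), min(i, j)
            M[i, j] = w  # lower triangle: surviving backbone
    pd.DataFrame(M, index=g.nodes, columns=g.nodes).to_csv(path, float_format="%.6f")


def load_edge_list(path: str | Path, nodes: list[str] | None = None) -> WeightedGraph:
    """Read a TSV edge list written by :func:`export_graph`.

    Node set defaults to the labels occurring in the file, sorted; pass
    ``nodes`` to preserve isolated nodes and a specific order.
    """
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec:
                continue
            u, v, w = rec
            rows.append((u, v, float(w)))
    if nodes is None:
        nodes = sorted({u for u, _, _ in rows} | {v for _, v, _ in rows})
    g = WeightedGraph(list(nodes))
    for u, v, w in rows:
        g.add_edge(u, v, w)
    return g
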