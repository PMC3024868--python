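"""PPI network representation, I/O and topological metrics.

Networks are simple undirected :class:`networkx.Graph` objects over opaque,
case-sensitive protein identifier strings; self-loops and edge direction are
dropped on read.  The metrics here are the building blocks of the clustering
methods: node/edge clustering coefficients (triangle based), the
Czekanowski-Dice neighborhood similarity, shortest-path edge betweenness
normalized by its maximum, and the k x k fraction-matrix modularity Q.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "read_network",
    "write_network",
    "node_clustering_coefficient",
    "edge_clustering_coefficient",
    "neighborhood_similarity",
    "edge_betweenness",
    "modularity",
    "augment_network",
]

log = logging.getLogger(__name__)


def _clean(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    g = nx.Graph()
    n_self = n_dup = 0
    for a, b in edges:
        if a == b:
            n_self += 1
            g.add_node(a)
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_self or n_dup:
        log.info("dropped %d self-loops, collapsed %d duplicate edges", n_self, n_dup)
    return g


def read_network(path: str, fmt: str | None = None) -> nx.Graph:
    """Read an edge list (TSV: 2 columns, optional ignored weight) or SIF.

    SIF lines are ``a <relation> b``; format is sniffed from the ``.sif``
    extension unless ``fmt`` is given.  Self-loops are removed and duplicate
    edges collapsed.  An empty file yields an empty network with a warning;
    a malformed line raises with its line number.
    """
    if fmt is None:
        fmt = "sif" if str(path).endswith(".sif") else "tsv"
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "sif":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs 3 fields")
                edges.append((fields[0], fields[2]))
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                edges.append((fields[0], fields[1]))
    if not edges:
        warnings.warn(f"{path}: no edges read; empty network")
    return _clean(edges)


def write_network(net: nx.Graph, path: str) -> None:
    """Write a 2-column TSV edge list, endpoints sorted within and across rows."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\n")


def node_clustering_coefficient(net: nx.Graph, v: str) -> float:
    """Fraction of realized links among v's neighbors: 2 n_v / (k_v (k_v - 1)).

    ``n_v`` is the number of triangles through v; defined as 0 when k_v <= 1.
    """
    if v not in net:
        raise KeyError(f"unknown node {v!r}")
    k = net.degree(v)
    if k <= 1:
        return 0.0
    return nx.clustering(net, v)


def edge_clustering_coefficient(net: nx.Graph, i: str, j: str) -> float:
    """Triangles on edge (i, j) over the maximum possible, min(k_i-1, k_j-1).

    Zero when either endpoint has degree <= 1 or when no triangle exists.
    """
    if not net.has_edge(i, j):
        raise KeyError(f"({i!r}, {j!r}) is not an edge")
    ki, kj = net.degree(i), net.degree(j)
    if ki <= 1 or kj <= 1:
        return 0.0
    z = len(set(net[i]) & set(net[j]))
    if z == 0:
        return 0.0
    return z / min(ki - 1, kj - 1)


def neighborhood_similarity(net: nx.Graph, i: str, j: str) -> float:
    """Czekanowski-Dice similarity of closed neighborhoods.

    ``1 - |Int(i) XOR Int(j)| / (|Int(i)| + |Int(j)|)`` with Int the adjacency
    list including the node itself.  Non-adjacent nodes can score > 0 through
    shared neighbors; identical closed neighborhoods score 1.
    """
    for v in (i, j):
        if v not in net:
            raise KeyError(f"unknown node {v!r}")
    int_i = set(net[i]) | {i}
    int_j = set(net[j]) | {j}
    return 1.0 - len(int_i ^ int_j) / (len(int_i) + len(int_j))


def edge_betweenness(net: nx.Graph) -> dict[tuple[str, str], float]:
    """Shortest-path betweenness of every edge, normalized by the maximum.

    Each unordered node pair contributes once; ties among equal-length
    shortest paths are split fractionally (Brandes accounting).  At least one
    edge attains 1.  Edgeless networks yield an empty mapping.
    """
    if net.number_of_edges() == 0:
        return {}
    raw = nx.edge_betweenness_centrality(net, normalized=False)
    top = max(raw.values())
    return {tuple(sorted(e)): v / top for e, v in raw.items()}


def modularity(net: nx.Graph, partition: Sequence[Iterable[str]]) -> float:
    """Newman-Girvan modularity from the k x k edge-fraction matrix.

    ``d_ii`` is the fraction of edges inside cluster i; an edge between
    clusters i and j contributes half its fraction to ``d_ij`` and half to
    ``d_ji`` so the matrix sums to 1, making Q of the single-cluster
    partition exactly 0.  ``Q = sum_i (d_ii - a_i^2)`` with row sums a_i.
    Any partition of an edgeless network scores 0 by convention.
    """
    clusters = [set(c) for c in partition]
    seen: set[str] = set()
    for c in clusters:
        if c & seen:
            raise ValueError("partition clusters are not disjoint")
        seen |= c
    missing = set(net.nodes) - seen
    if missing:
        raise ValueError(f"nodes missing from partition: {sorted(missing)}")
    m = net.number_of_edges()
    if m == 0:
        return 0.0
    idx = {v: ci for ci, c in enumerate(clusters) for v in c}
    k = len(clusters)
    d = [[0.0] * k for _ in range(k)]
    for a, b in net.edges():
        ca, cb = idx[a], idx[b]
        if ca == cb:
            d[ca][ca] += 1.0 / m
        else:
            d[ca][cb] += 0.5 / m
            d[cb][ca] += 0.5 / m
    q = 0.0
    for i in range(k):
        a_i = sum(d[i])
        q += d[i][i] - a_i * a_i
    return q


def augment_network(net: nx.Graph, constraints) -> nx.Graph:
    """Union of PPI edges and constraint pairs, unweighted and deduplicated.

    Constraint endpoints absent from the network are added as new nodes.
    Idempotent; the count of genuinely new edges is logged.
    """
    out = net.copy()
    new = 0
    for a, b in constraints.pairs:
        if a == b:
            continue
        if not out.has_edge(a, b):
            out.add_edge(a, b)
            new += 1
    log.info("augmented network with %d new edges", new)
    return out
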