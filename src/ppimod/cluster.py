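"""Base functional-module identification algorithms.

Four detectors over a PPI network:

* ``hc_agnes`` — agglomerative hierarchical clustering on a topological
  similarity matrix (clustering-coefficient or neighborhood based), cut at
  ``k`` clusters;
* ``ng_divisive`` — Girvan-Newman divisive clustering: repeatedly remove the
  highest-betweenness edge for ``s`` steps, modules = connected components;
* ``mcl`` — Markov clustering: alternate expansion (matrix power) and
  inflation (entrywise power ``r``) of the column-stochastic flow matrix;
* ``mcode`` — molecular complex detection: k-core-based vertex weighting,
  seeded greedy expansion with a node-score cutoff ``t``, optional fluff.

All tie-breaks are lexicographic on sorted node identifiers, so every
algorithm is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import (
    edge_betweenness,
    edge_clustering_coefficient,
    neighborhood_similarity,
)

__all__ = [
    "ModuleSet",
    "similarity_matrix",
    "hc_agnes",
    "ng_divisive",
    "mcl",
    "mcode",
    "write_modules",
    "read_modules",
]


@dataclass
class ModuleSet:
    """Modules (node sets) with provenance.

    HC/NG/MCL outputs are disjoint and cover the assigned nodes; MCODE
    modules may overlap and need not cover the network (uncovered nodes go
    to ``residual``).
    """

    modules: list[frozenset[str]]
    method: str
    params: dict = field(default_factory=dict)
    overlapping: bool = False
    residual: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.modules = sorted(
            (frozenset(m) for m in self.modules), key=lambda m: sorted(m)
        )

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    @property
    def assigned(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return frozenset(out)

    def labels(self) -> dict[str, int]:
        """Node -> module index; overlapping membership resolved to the
        largest module (ties to the lexicographically smallest)."""
        out: dict[str, int] = {}
        order = sorted(
            range(len(self.modules)),
            key=lambda i: (-len(self.modules[i]), sorted(self.modules[i])),
        )
        for i in order:
            for v in self.modules[i]:
                out.setdefault(v, i)
        return out


def similarity_matrix(net: nx.Graph, metric: str = "cc"):
    """Pairwise topological similarity over sorted nodes.

    ``cc`` uses the edge clustering coefficient (0 for non-edges), ``nb``
    the Czekanowski-Dice neighborhood similarity (defined for every pair).
    Returns ``(nodes, matrix)`` with unit diagonal.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i], nodes[j]
            if metric == "cc":
                v = edge_clustering_coefficient(net, a, b) if net.has_edge(a, b) else 0.0
            elif metric == "nb":
                v = neighborhood_similarity(net, a, b)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            sim[i, j] = sim[j, i] = v
    return nodes, sim


def _agglomerate(
    nodes: list[str],
    sim: np.ndarray,
    initial: list[frozenset[str]],
    k: int,
    linkage: str,
) -> list[frozenset[str]]:
    """Greedy agglomeration of ``initial`` clusters down to ``k``.

    Cluster-cluster similarity is the mean (average linkage) or minimum
    (complete linkage) of the member-pair similarities; at each step the
    most similar pair merges, ties broken on the lexicographically smallest
    (representative_a, representative_b) pair.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    idx = {v: i for i, v in enumerate(nodes)}
    clusters = {ci: frozenset(c) for ci, c in enumerate(initial)}

    def link(a: frozenset[str], b: frozenset[str]) -> float:
        vals = [sim[idx[x], idx[y]] for x in a for y in b]
        return float(np.mean(vals)) if linkage == "average" else float(min(vals))

    def rep(c: frozenset[str]) -> str:
        return min(c)

    while len(clusters) > k:
        best = None
        for ca in clusters:
            for cb in clusters:
                if ca >= cb:
                    continue
                s = link(clusters[ca], clusters[cb])
                key = (-s, *sorted((rep(clusters[ca]), rep(clusters[cb]))))
                if best is None or key < best[0]:
                    best = (key, ca, cb)
        _, ca, cb = best
        clusters[ca] = clusters[ca] | clusters[cb]
        del clusters[cb]
    return sorted(clusters.values(), key=sorted)


def hc_agnes(
    nodes: list[str], sim: np.ndarray, k: int, linkage: str = "average"
) -> ModuleSet:
    """Agglomerative clustering of a similarity matrix cut at ``k`` clusters.

    Each node starts in its own cluster; pairs merge by decreasing linkage
    similarity until ``k`` clusters remain (``k = n`` returns singletons).
    """
    n = len(nodes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    initial = [frozenset([v]) for v in sorted(nodes)]
    mods = _agglomerate(list(nodes), sim, initial, k, linkage)
    return ModuleSet(mods, method="hc", params={"k": k, "linkage": linkage})


def ng_divisive(net: nx.Graph, s: int) -> ModuleSet:
    """Girvan-Newman divisive clustering with ``s`` edge removals.

    Each step recomputes shortest-path edge betweenness on the current graph
    and removes the single highest-betweenness edge (ties: lexicographically
    smallest edge).  Modules are the connected components; ``s = 0`` returns
    the components of the input.  Stops early with a warning if the graph
    runs out of edges.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    g = net.copy()
    for _ in range(s):
        if g.number_of_edges() == 0:
            import warnings

            warnings.warn("network became edgeless before s removals")
            break
        eb = edge_betweenness(g)
        top = max(eb.values())
        target = min(e for e, v in eb.items() if v == top)
        g.remove_edge(*target)
    mods = [frozenset(c) for c in nx.connected_components(g)]
    return ModuleSet(mods, method="ng", params={"s": s})


def mcl(
    net: nx.Graph,
    r: float = 1.4,
    expansion: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
    prune: float = 1e-8,
    self_loops: float = 1.0,
    on_iteration=None,
) -> ModuleSet:
    """Markov clustering of the network's flow matrix.

    Self-loops of weight ``self_loops`` are added, columns are normalized to
    a stochastic matrix, then expansion (power ``expansion``) and inflation
    (entrywise power ``r``, renormalize) alternate until the matrix changes
    by less than ``tol`` or ``max_iter`` is hit (warning on non-convergence).
    Clusters are read from attractor rows; a node attracted by several
    attractors joins the lexicographically smallest cluster.  Inflation
    controls granularity: larger ``r`` gives more, smaller clusters.
    """
    if r <= 1:
        raise ValueError("inflation r must be > 1")
    nodes = sorted(net.nodes)
    n = len(nodes)
    if n == 0:
        return ModuleSet([], method="mcl", params={"r": r})
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b in net.edges():
        if a == b:
            continue
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = 1.0
    np.fill_diagonal(m, self_loops)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, r)
        m[m < prune] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        if on_iteration is not None:
            on_iteration(m)
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("MCL did not converge within max_iter; using current matrix")
    # attractors: rows with positive diagonal mass
    attractors = [i for i in range(n) if m[i, i] > tol]
    clusters: dict[int, set[str]] = {a: set() for a in attractors}
    for j in range(n):
        owners = [a for a in attractors if m[a, j] > tol]
        if not owners:
            owners = [int(np.argmax(m[:, j]))]
            clusters.setdefault(owners[0], set())
        # overlap resolved to the lexicographically smallest cluster
        owner = min(owners, key=lambda a: nodes[a])
        clusters[owner].add(nodes[j])
    mods = [frozenset(c) for c in clusters.values() if c]
    return ModuleSet(
        mods, method="mcl", params={"r": r, "expansion": expansion, "tol": tol}
    )


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest non-empty k-core of ``g`` and its k."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_nums = nx.core_number(nx.Graph(g))
    k = max(core_nums.values())
    core = g.subgraph([v for v, c in core_nums.items() if c >= k])
    return k, core


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode(
    net: nx.Graph,
    t: float = 0.2,
    f: float | None = None,
) -> ModuleSet:
    """Molecular complex detection by local-density vertex weighting.

    Each vertex is weighted by the core-clustering coefficient: the density
    of the highest k-core of its closed neighborhood, multiplied by that
    core's k.  Complexes grow greedily from the highest-weight unvisited
    seed, admitting neighboring vertices whose weight exceeds
    ``seed_weight * (1 - t)``.  An optional fluff stage then adds boundary
    neighbors whose closed-neighborhood density exceeds ``f``, allowing
    modules to overlap.  Modules of size < 2 are discarded; unassigned
    nodes are reported in the residual set, never forced into modules.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must be in [0, 1]")
    if f is not None and not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    nodes = sorted(net.nodes)
    weight: dict[str, float] = {}
    for v in nodes:
        nbhd = net.subgraph(set(net[v]) | {v})
        k, core = _highest_kcore(nbhd)
        weight[v] = k * _density(core)
    visited: set[str] = set()
    raw_modules: list[set[str]] = []
    for seed in sorted(nodes, key=lambda v: (-weight[v], v)):
        if seed in visited or weight[seed] <= 0:
            continue
        cutoff = weight[seed] * (1.0 - t)
        module = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            u = frontier.pop()
            for w in sorted(net[u]):
                if w in visited or w in module:
                    continue
                if weight[w] > cutoff:
                    module.add(w)
                    visited.add(w)
                    frontier.append(w)
        if len(module) >= 2:
            raw_modules.append(module)
    if f is not None:
        fluffed = []
        for module in raw_modules:
            extra = set()
            for u in sorted(module):
                for w in sorted(net[u]):
                    if w in module:
                        continue
                    if _density(net.subgraph(set(net[w]) | {w})) > f:
                        extra.add(w)
            fluffed.append(module | extra)
        raw_modules = fluffed
    assigned = set().union(*raw_modules) if raw_modules else set()
    return ModuleSet(
        [frozenset(m) for m in raw_modules],
        method="mcode",
        params={"t": t, "f": f},
        overlapping=f is not None,
        residual=frozenset(set(nodes) - assigned),
    )


def write_modules(mods: ModuleSet, path: str) -> None:
    """Module TSV: one ``module_id  protein`` row per membership, with the
    method and parameters echoed in a header comment."""
    with open(path, "w") as fh:
        params = " ".join(f"{k}={v}" for k, v in sorted(mods.params.items()))
        fh.write(f"# method={mods.method} {params}\n")
        fh.write("module_id\tprotein\n")
        for i, m in enumerate(mods.modules):
            for v in sorted(m):
                fh.write(f"M{i + 1}\t{v}\n")


def read_modules(path: str) -> ModuleSet:
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("module_id"):
                continue
            mid, prot = line.split("\t")
            groups.setdefault(mid, set()).add(prot)
    return ModuleSet([frozenset(g) for g in groups.values()], method="file")
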