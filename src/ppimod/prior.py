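"""Semi-supervised module identification from must-link constraints.

High-confidence functional pairs (e.g. gene pairs with near-perfect GO
semantic similarity) act as must-link constraints: both proteins must end
up in the same module.  Two supervision strategies are provided:

* **ssHC** — the constraints' transitive closures (connected components of
  the constraint graph) become the initial clusters of agglomerative
  hierarchical clustering, so no must-link pair can ever be separated;
* **two-stage ssNG / ssMCL / ssMCODE** — the base algorithm is first run
  with deliberately over-splitting parameters, then sub-modules spanned by
  at least one constraint are merged (meta-graph connected components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cluster import ModuleSet, _agglomerate, mcl, mcode, ng_divisive

__all__ = [
    "ConstraintSet",
    "ClosureSet",
    "build_transitive_closures",
    "ss_hc",
    "ss_two_stage",
    "read_constraints",
    "write_constraints",
    "write_closures",
]


@dataclass(frozen=True)
class ConstraintSet:
    """Unordered must-link protein pairs, optionally with similarity values."""

    pairs: frozenset[tuple[str, str]]
    similarities: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float | None = None

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a!r}, {b!r}) not allowed")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"pair ({a!r}, {b!r}) must be sorted")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for pair in self.pairs for p in pair)


@dataclass(frozen=True)
class ClosureSet:
    """Transitive closures: disjoint protein sets, each with >= 2 members."""

    closures: tuple[frozenset[str], ...]
    pair_counts: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.closures)

    def __iter__(self):
        return iter(self.closures)


def build_transitive_closures(constraints: ConstraintSet) -> ClosureSet:
    """Connected components of the constraint graph.

    One graph node per protein appearing in a constraint, one edge per
    must-link pair; the components are the transitive closures.  Each
    closure reports its member count and the number of constraint pairs it
    contains.
    """
    g = nx.Graph()
    g.add_edges_from(constraints.pairs)
    closures = sorted((frozenset(c) for c in nx.connected_components(g)), key=sorted)
    counts = tuple(
        sum(1 for a, b in constraints.pairs if a in c and b in c) for c in closures
    )
    return ClosureSet(closures=tuple(closures), pair_counts=counts)


def ss_hc(
    nodes: list[str],
    sim: np.ndarray,
    closures: ClosureSet,
    k: int,
    linkage: str = "average",
) -> ModuleSet:
    """Closure-seeded agglomerative clustering.

    Initial clusters are the transitive closures plus singletons for every
    remaining node; merging proceeds until ``k`` clusters remain.  Because
    each closure starts (and stays) in one cluster, no must-link pair is
    ever separated.  With no closures this reduces exactly to plain
    agglomerative clustering.
    """
    node_set = set(nodes)
    for c in closures:
        missing = c - node_set
        if missing:
            raise ValueError(f"closure members absent from matrix: {sorted(missing)}")
    in_closure = set().union(*closures.closures) if len(closures) else set()
    initial = list(closures.closures) + [
        frozenset([v]) for v in sorted(node_set - in_closure)
    ]
    if k > len(initial):
        raise ValueError(
            f"k={k} exceeds the {len(initial)} initial clusters "
            f"(closures + free singletons); feasible maximum is {len(initial)}"
        )
    mods = _agglomerate(list(nodes), sim, initial, k, linkage)
    return ModuleSet(mods, method="ss_hc", params={"k": k, "linkage": linkage})


_BASE_METHODS = {
    "ng": lambda net, p: ng_divisive(net, **p),
    "mcl": lambda net, p: mcl(net, **p),
    "mcode": lambda net, p: mcode(net, **p),
}

#: Over-splitting stage-1 defaults for each base method.
STAGE1_DEFAULTS = {
    "ng": {"s": 6500},
    "mcl": {"r": 5.0},
    "mcode": {"t": 0.05},
}


def ss_two_stage(
    net: nx.Graph,
    base_method: str,
    constraints: ConstraintSet,
    base_params: dict | None = None,
) -> ModuleSet:
    """Over-split with the base method, then constraint-merge sub-modules.

    Stage 1 runs ``base_method`` (``ng``/``mcl``/``mcode``) with
    over-splitting parameters (defaults: s=6500, r=5, t=0.05).  Stage 2
    builds a meta-graph with one vertex per sub-module and an edge whenever
    >= 1 must-link pair spans two sub-modules; each meta connected component
    merges into one module.  Sub-modules touched by no constraint pass
    through unchanged, and for overlapping stage-1 output (MCODE) the
    overlap is preserved inside merged modules.
    """
    if base_method not in _BASE_METHODS:
        raise ValueError(f"unknown base method {base_method!r}")
    params = dict(STAGE1_DEFAULTS[base_method])
    if base_params:
        params.update(base_params)
    base = _BASE_METHODS[base_method](net, params)
    membership: dict[str, set[int]] = {}
    for i, m in enumerate(base.modules):
        for v in m:
            membership.setdefault(v, set()).add(i)
    meta = nx.Graph()
    meta.add_nodes_from(range(len(base.modules)))
    for a, b in constraints.pairs:
        for ia in membership.get(a, ()):
            for ib in membership.get(b, ()):
                if ia != ib:
                    meta.add_edge(ia, ib)
    merged = []
    for comp in nx.connected_components(meta):
        mod: set[str] = set()
        for i in comp:
            mod |= base.modules[i]
        merged.append(frozenset(mod))
    return ModuleSet(
        merged,
        method=f"ss_{base_method}",
        params=params,
        overlapping=base.overlapping,
        residual=base.residual,
    )


def read_constraints(path: str) -> ConstraintSet:
    """Constraint TSV: ``protein_a  protein_b  [similarity]`` per line.

    Cannot-link rows (a third token ``CL`` in a ``type`` column or negative
    similarity) are not part of this framework; lines whose similarity field
    is the literal ``CL`` are skipped with a warning.
    """
    pairs: set[tuple[str, str]] = set()
    sims: dict[tuple[str, str], float] = {}
    n_cl = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_a"):
                continue
            fields = line.split("\t")
            a, b = fields[0], fields[1]
            if len(fields) > 2 and fields[2] == "CL":
                n_cl += 1
                continue
            if a == b:
                continue
            pair = tuple(sorted((a, b)))
            pairs.add(pair)
            if len(fields) > 2:
                try:
                    sims[pair] = float(fields[2])
                except ValueError:
                    pass
    if n_cl:
        warnings.warn(f"ignored {n_cl} cannot-link constraints (must-links only)")
    return ConstraintSet(pairs=frozenset(pairs), similarities=sims)


def write_constraints(constraints: ConstraintSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tsimilarity\n")
        for a, b in sorted(constraints.pairs):
            s = constraints.similarities.get((a, b))
            fh.write(f"{a}\t{b}\t{'' if s is None else f'{s:.6g}'}\n")


def write_closures(closures: ClosureSet, path: str) -> None:
    """Closure report TSV: ``closure_id  size  n_pairs  members``."""
    with open(path, "w") as fh:
        fh.write("closure_id\tsize\tn_pairs\tmembers\n")
        for i, (c, np_) in enumerate(zip(closures.closures, closures.pair_counts)):
            fh.write(f"C{i + 1}\t{len(c)}\t{np_}\t{','.join(sorted(c))}\n")
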