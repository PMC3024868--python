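"""Ontology and annotation containers.

The Gene Ontology is three rooted directed acyclic vocabularies (biological
process, cellular component, molecular function).  Semantic-similarity
computations need, for every term, its reflexive set of ``is_a`` ancestors
and, from an annotation corpus, its direct occurrence count.  This module
parses OBO 1.2 files (via :mod:`obonet`) and GAF 2.x annotation files into
light-weight containers holding exactly that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "NAMESPACES",
    "OntologyDAG",
    "AnnotationTable",
    "parse_obo",
    "read_gaf",
]

#: Canonical short codes for the three GO namespaces.
NAMESPACES = ("BP", "CC", "MF")

_NS_LONG_TO_SHORT = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling links)."""


@dataclass
class OntologyDAG:
    """Rooted DAG of terms connected by ``is_a`` links, one root per namespace.

    Parameters
    ----------
    parents
        Mapping term -> set of direct ``is_a`` parents (empty for roots).
    namespace
        Mapping term -> namespace code (``BP``/``CC``/``MF``).
    """

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise OntologyError(
                        f"term {term!r} has dangling is_a target {p!r}"
                    )
                if self.namespace.get(p) != self.namespace.get(term):
                    raise OntologyError(
                        f"is_a link {term!r} -> {p!r} crosses namespaces"
                    )
        g = nx.DiGraph(
            (c, p) for c, ps in self.parents.items() for p in ps
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is_a cycle detected: {cycle}")
        # exactly one parentless term per populated namespace
        by_ns: dict[str, list[str]] = {}
        for term, ps in self.parents.items():
            if not ps:
                by_ns.setdefault(self.namespace[term], []).append(term)
        for ns in sorted({self.namespace[t] for t in self.parents}):
            tops = by_ns.get(ns, [])
            if len(tops) != 1:
                raise OntologyError(
                    f"namespace {ns} must have exactly one root, found {sorted(tops)}"
                )
            self.roots[ns] = tops[0]

    # -- queries --------------------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive ``is_a`` ancestors of ``term`` (includes itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(term)
        out: set[str] = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def terms_in_namespace(self, ns: str) -> frozenset[str]:
        return frozenset(t for t, n in self.namespace.items() if n == ns)


@dataclass
class AnnotationTable:
    """Direct gene -> term annotations plus per-term occurrence counts.

    ``occur`` counts one occurrence per distinct (gene, term) pair; duplicate
    annotation records for the same pair do not inflate a term's frequency.
    """

    annotations: dict[str, frozenset[str]]  # gene -> direct terms

    @property
    def genes(self) -> list[str]:
        return sorted(self.annotations)

    def terms_of(self, gene: str) -> frozenset[str]:
        if gene not in self.annotations:
            raise KeyError(f"unknown gene {gene!r}")
        return self.annotations[gene]

    def occur(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts

    def restricted_to(self, dag: OntologyDAG) -> "AnnotationTable":
        """Drop annotations to terms absent from ``dag`` (with a warning)."""
        known = dag.terms
        dropped = 0
        ann = {}
        for g, terms in self.annotations.items():
            keep = frozenset(t for t in terms if t in known)
            dropped += len(terms) - len(keep)
            ann[g] = keep
        if dropped:
            warnings.warn(f"dropped {dropped} annotations to unknown terms")
        return AnnotationTable(ann)


def parse_obo(path: str) -> OntologyDAG:
    """Parse an OBO 1.2 file into an :class:`OntologyDAG`.

    Obsolete terms are dropped; ``is_a`` is the only relation followed.
    Raises :class:`OntologyError` on cycles, dangling ``is_a`` targets or a
    namespace without a unique root.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    parents: dict[str, frozenset[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        if not data:
            # edge target never declared as a [Term] stanza
            children = sorted(c for c, p in graph.edges() if p == term)
            raise OntologyError(
                f"dangling is_a target {term!r} (referenced by {children})"
            )
        ns = data.get("namespace", "biological_process")
        namespace[term] = _NS_LONG_TO_SHORT.get(ns, ns)
    for term in graph.nodes:
        ps = frozenset(
            p
            for _, p, key in graph.out_edges(term, keys=True)
            if key == "is_a" and namespace.get(p) == namespace[term]
        )
        parents[term] = ps
    return OntologyDAG(parents=parents, namespace=namespace)


def read_gaf(path: str) -> AnnotationTable:
    """Read a GAF 2.x file: column 2 = gene symbol, 5 = GO id, 9 = aspect.

    Rows whose qualifier column contains ``NOT`` are skipped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="!",
        header=None,
        dtype=str,
        keep_default_na=False,
        usecols=range(15),
        names=[
            "db", "db_id", "symbol", "qualifier", "go_id", "reference",
            "evidence", "with_from", "aspect", "name", "synonym", "type",
            "taxon", "date", "assigned_by",
        ],
        engine="python",
    )
    df = df[~df["qualifier"].str.contains("NOT", na=False)]
    ann: dict[str, set[str]] = {}
    for sym, go in zip(df["symbol"], df["go_id"]):
        ann.setdefault(sym, set()).add(go)
    return AnnotationTable({g: frozenset(ts) for g, ts in ann.items()})
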