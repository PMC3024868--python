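"""Module-set evaluation against a reference complex catalog.

Detected modules are scored two ways: topologically, by Newman-Girvan
modularity, and biologically, by enrichment of known protein complexes.
Enrichment of a module for a complex is the one-sided hypergeometric tail
probability of drawing at least the observed overlap when the module's
annotated members are sampled from the annotated universe; a module's
enrichment score is minus the log (base 10 by default) of the geometric
mean of its enriched-complex p-values.  Coverage is the fraction of network
proteins contained in significantly annotated modules.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .cluster import ModuleSet

__all__ = [
    "ComplexCatalog",
    "EnrichmentResult",
    "hypergeom_enrichment",
    "enrichment_score",
    "coverage",
    "summarize",
    "read_catalog",
    "write_catalog",
]


@dataclass(frozen=True)
class ComplexCatalog:
    """Mapping complex identifier -> member protein set."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.complexes.values():
            out |= m
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class EnrichmentResult:
    """Per-complex enrichment of one module.

    ``table`` columns: complex_id, complex_size, hits, p_value — one row per
    complex overlapping the module, sorted by ascending p-value.
    """

    module_size: int
    n_annotated: int
    table: pd.DataFrame

    @property
    def best_p(self) -> float:
        return float(self.table["p_value"].min()) if len(self.table) else 1.0

    def top(self, n: int = 2) -> pd.DataFrame:
        return self.table.head(n)


def hypergeom_enrichment(
    module, catalog: ComplexCatalog, universe=None
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment of a module for each complex.

    With population the annotated universe (default: the catalog universe),
    successes the complex's annotated members and draws the module's
    annotated members, the p-value is P(X >= hits).  Complexes with zero
    hits are skipped.
    """
    module = set(module)
    universe = set(universe) if universe is not None else set(catalog.universe)
    if not universe:
        raise ValueError("empty universe")
    drawn = module & universe
    rows = []
    for cid in sorted(catalog.complexes):
        members = catalog.complexes[cid] & universe
        hits = len(members & drawn)
        if hits == 0:
            continue
        p = float(stats.hypergeom.sf(hits - 1, len(universe), len(members), len(drawn)))
        rows.append((cid, len(members), hits, min(1.0, max(p, 0.0))))
    table = pd.DataFrame(rows, columns=["complex_id", "complex_size", "hits", "p_value"])
    table = table.sort_values(["p_value", "complex_id"], ignore_index=True)
    return EnrichmentResult(
        module_size=len(module), n_annotated=len(drawn), table=table
    )


def enrichment_score(p_values, base: float = 10.0) -> float:
    """Minus log of the geometric mean of p-values.

    Equal to the arithmetic mean of the individual -log p values.  An empty
    list scores 0 (warning); p = 0 is clamped to the smallest positive
    normal float (warning).
    """
    p_values = list(p_values)
    if not p_values:
        warnings.warn("enrichment_score of empty p-value list is 0")
        return 0.0
    clamped = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            warnings.warn("p-value 0 clamped to smallest positive normal")
            p = sys.float_info.min
        clamped.append(p)
    return -sum(math.log(p, base) for p in clamped) / len(clamped)


def coverage(
    modules: ModuleSet,
    net: nx.Graph,
    catalog: ComplexCatalog,
    alpha: float = 0.05,
    universe=None,
) -> float:
    """Fraction of network proteins inside significantly annotated modules.

    A module counts as annotated when its best complex p-value is <= alpha.
    """
    if net.number_of_nodes() == 0:
        return 0.0
    covered: set[str] = set()
    for m in modules:
        res = hypergeom_enrichment(m, catalog, universe=universe)
        if len(res.table) and res.best_p <= alpha:
            covered |= set(m)
    return len(covered & set(net.nodes)) / net.number_of_nodes()


def summarize(
    modules: ModuleSet,
    net: nx.Graph,
    catalog: ComplexCatalog,
    alpha: float = 0.05,
    base: float = 10.0,
    universe=None,
    top_n: int = 2,
) -> dict:
    """Method-level summary plus per-module top-complex rows.

    Returns ``{"summary": DataFrame, "modules": DataFrame}``.  The summary
    row carries the annotated-module count, the average -log p of each
    annotated module's best complex, and the coverage; the module table
    lists each module's top ``top_n`` complexes (size, annotated members,
    complex id, hits, p-value), sorted by best p-value.
    """
    per_module = []
    best_ps = []
    covered: set[str] = set()
    for i, m in enumerate(modules):
        res = hypergeom_enrichment(m, catalog, universe=universe)
        if not len(res.table):
            continue
        if res.best_p <= alpha:
            best_ps.append(res.best_p)
            covered |= set(m)
            for _, row in res.top(top_n).iterrows():
                per_module.append(
                    (
                        f"M{i + 1}",
                        res.module_size,
                        res.n_annotated,
                        row["complex_id"],
                        int(row["hits"]),
                        row["p_value"],
                    )
                )
    mod_df = pd.DataFrame(
        per_module,
        columns=["module_id", "size", "n_annotated", "complex_id", "hits", "p_value"],
    )
    n_nodes = net.number_of_nodes()
    summary = pd.DataFrame(
        [
            {
                "method": modules.method,
                "n_modules": len(best_ps),
                "avg_neg_log_p": enrichment_score(best_ps, base=base)
                if best_ps
                else 0.0,
                "coverage": len(covered & set(net.nodes)) / n_nodes if n_nodes else 0.0,
            }
        ]
    )
    return {"summary": summary, "modules": mod_df}


def read_catalog(path: str) -> ComplexCatalog:
    """Catalog TSV: ``complex_id  protein`` rows."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("complex_id"):
                continue
            cid, prot = line.split("\t")
            groups.setdefault(cid, set()).add(prot)
    return ComplexCatalog({cid: frozenset(g) for cid, g in groups.items()})


def write_catalog(catalog: ComplexCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("complex_id\tprotein\n")
        for cid in sorted(catalog.complexes):
            for p in sorted(catalog.complexes[cid]):
                fh.write(f"{cid}\t{p}\n")
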