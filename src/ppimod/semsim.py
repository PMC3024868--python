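"""Information-content semantic similarity between GO terms and gene products.

A term's probability is its cumulative annotation frequency relative to the
namespace root::

    freq(c) = sum{ occur(c_i) : c in Ancestors(c_i) },   p(c) = freq(c) / freq(root)

The relevance similarity between two terms c1, c2 is the maximum over their
common ancestors c of::

    [ 2 ln p(c) / (ln p(c1) + ln p(c2)) ] * (1 - p(c))

The first factor is the shared-information ratio (Lin), the second discounts
shallow ancestors: an uninformative common ancestor (the root, p = 1) yields
zero.  Gene-product similarity aggregates term-level values by MAX over all
cross term pairs within a namespace, then MAX across the namespaces the two
genes share; a pair annotated in disjoint namespaces is UNDEFINED, which is
distinct from a similarity of zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .ontology import AnnotationTable, OntologyDAG

__all__ = [
    "UNDEFINED",
    "TermStats",
    "GenePairSimilarity",
    "compute_term_stats",
    "simrel",
    "gene_similarity",
    "all_pairs_similarity",
    "count_pairs",
    "extract_functional_pairs",
    "write_pairs",
    "read_pairs",
]


class _Undefined:
    """Sentinel for pairs whose similarity cannot be identified.

    Distinct from 0: genes annotated only in different namespaces have no
    comparable terms at all, whereas 0 means comparable terms sharing only
    the root.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class TermStats:
    """Cumulative term frequencies and probabilities, per namespace."""

    freq: dict[str, int]
    p: dict[str, float]

    def defined(self, term: str) -> bool:
        return term in self.p


@dataclass(frozen=True)
class GenePairSimilarity:
    gene_a: str
    gene_b: str
    value: object  # float in [0, 1] or UNDEFINED
    namespace: str | None  # namespace attaining the value, None if UNDEFINED


def compute_term_stats(dag: OntologyDAG, ann: AnnotationTable) -> TermStats:
    """Cumulative frequency and probability of every term, per namespace.

    freq(c) sums direct occurrences over all terms whose ancestor set
    contains c, so an ancestor's frequency is never below a descendant's.
    Terms with zero cumulative frequency get no probability and are excluded
    from similarity.  A namespace whose root frequency is zero has all
    probabilities undefined there (warning).
    """
    occur = ann.occur()
    unknown = sorted(t for t in occur if t not in dag.terms)
    if unknown:
        raise KeyError(f"annotated terms absent from ontology: {unknown}")
    freq: dict[str, int] = {t: 0 for t in dag.terms}
    for term, n in occur.items():
        for anc in dag.ancestors(term):
            freq[anc] += n
    p: dict[str, float] = {}
    for ns, root in dag.roots.items():
        root_freq = freq[root]
        if root_freq == 0:
            warnings.warn(
                f"namespace {ns} has no annotations; probabilities undefined"
            )
            continue
        for term in dag.terms_in_namespace(ns):
            if freq[term] > 0:
                p[term] = freq[term] / root_freq
    return TermStats(freq=freq, p=p)


def simrel(c1: str, c2: str, stats: TermStats, dag: OntologyDAG):
    """Relevance similarity between two terms; UNDEFINED across namespaces.

    The 0/0 case (both terms the root) is 0: the relevance factor
    ``1 - p(root)`` vanishes, forcing the limit.
    """
    if dag.namespace.get(c1) != dag.namespace.get(c2):
        return UNDEFINED
    if not (stats.defined(c1) and stats.defined(c2)):
        return UNDEFINED
    common = dag.ancestors(c1) & dag.ancestors(c2)
    denom = math.log(stats.p[c1]) + math.log(stats.p[c2])
    best = None
    for c in common:
        if not stats.defined(c):
            continue
        pc = stats.p[c]
        if denom == 0.0:
            # both terms at probability 1 (the root): value pinned to 0
            val = 0.0
        else:
            val = (2.0 * math.log(pc) / denom) * (1.0 - pc)
        if best is None or val > best:
            best = val
    if best is None:
        return UNDEFINED
    return min(1.0, max(0.0, best))


def gene_similarity(
    g1: str, g2: str, dag: OntologyDAG, stats: TermStats, ann: AnnotationTable
) -> GenePairSimilarity:
    """Semantic similarity between two gene products.

    Per shared namespace, the MAX of term-level relevance similarities over
    all cross term pairs; the overall value is the MAX across namespaces.
    UNDEFINED when no shared namespace yields a defined term-pair value
    (e.g. one gene annotated only in BP, the other only in MF).
    """
    a, b = sorted((g1, g2))
    t1 = ann.terms_of(g1)
    t2 = ann.terms_of(g2)
    best: float | None = None
    best_ns: str | None = None
    for ns in sorted(dag.roots):
        ts1 = [t for t in t1 if dag.namespace.get(t) == ns]
        ts2 = [t for t in t2 if dag.namespace.get(t) == ns]
        ns_best = None
        for c1, c2 in itertools.product(ts1, ts2):
            v = simrel(c1, c2, stats, dag)
            if v is UNDEFINED:
                continue
            if ns_best is None or v > ns_best:
                ns_best = v
        if ns_best is not None and (best is None or ns_best > best):
            best, best_ns = ns_best, ns
    if best is None:
        return GenePairSimilarity(a, b, UNDEFINED, None)
    return GenePairSimilarity(a, b, min(1.0, max(0.0, best)), best_ns)


def count_pairs(genes) -> int:
    """Number of unordered gene pairs, counted by streaming the enumeration."""
    n = 0
    for _ in itertools.combinations(sorted(genes), 2):
        n += 1
    return n


def all_pairs_similarity(
    genes, dag: OntologyDAG, stats: TermStats, ann: AnnotationTable
) -> pd.DataFrame:
    """Similarity records for every unordered pair, in sorted gene order.

    Returns a DataFrame with columns ``gene_a, gene_b, similarity, namespace``;
    UNDEFINED similarities are NaN with namespace ``NA``.  Exactly
    ``n*(n-1)/2`` rows for ``n`` genes.
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    rows = []
    for a, b in itertools.combinations(genes, 2):
        r = gene_similarity(a, b, dag, stats, ann)
        rows.append(
            (
                r.gene_a,
                r.gene_b,
                float("nan") if r.value is UNDEFINED else r.value,
                r.namespace or "NA",
            )
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity", "namespace"])


def extract_functional_pairs(pairs: pd.DataFrame, threshold: float):
    """Keep defined pairs with similarity >= threshold as must-link constraints.

    UNDEFINED (NaN) pairs never pass.  Returns a
    :class:`ppimod.prior.ConstraintSet` recording the threshold.
    """
    from .prior import ConstraintSet

    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = pairs[pairs["similarity"].notna() & (pairs["similarity"] >= threshold)]
    return ConstraintSet(
        pairs=frozenset(
            tuple(sorted((a, b))) for a, b in zip(kept["gene_a"], kept["gene_b"])
        ),
        similarities={
            tuple(sorted((a, b))): s
            for a, b, s in zip(kept["gene_a"], kept["gene_b"], kept["similarity"])
        },
        threshold=threshold,
    )


def write_pairs(pairs: pd.DataFrame, path: str) -> None:
    out = pairs.copy()
    out["similarity"] = out["similarity"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.6g}"
    )
    out.to_csv(path, sep="\t", index=False)


def read_pairs(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    df["similarity"] = pd.to_numeric(df["similarity"], errors="coerce")
    return df
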