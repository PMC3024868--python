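import networkx as nx
import pytest

from ppimod.ontology import AnnotationTable, OntologyDAG


def two_triangles_bridge() -> nx.Graph:
    """Two triangles joined by a single bridge edge: a-b-c-a, d-e-f-d, c-d."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    g.add_edges_from([("d", "e"), ("e", "f"), ("d", "f")])
    g.add_edge("c", "d")
    return g


@pytest.fixture
def bridge_graph():
    return two_triangles_bridge()


@pytest.fixture
def toy_dag():
    """Root R with children C1, C2; C1 has children L1, L2."""
    parents = {
        "R": frozenset(),
        "C1": frozenset(["R"]),
        "C2": frozenset(["R"]),
        "L1": frozenset(["C1"]),
        "L2": frozenset(["C1"]),
    }
    ns = {t: "BP" for t in parents}
    return OntologyDAG(parents=parents, namespace=ns)


@pytest.fixture
def toy_ann():
    return AnnotationTable(
        {
            "g1": frozenset(["L1"]),
            "g2": frozenset(["L1"]),
            "g3": frozenset(["L2"]),
            "g4": frozenset(["C2"]),
            "g5": frozenset(),
        }
    )
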