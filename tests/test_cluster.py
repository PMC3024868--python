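"""Base module-identification algorithms: HC, NG, MCL, MCODE."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ppimod.cluster import (
    hc_agnes,
    mcl,
    mcode,
    ng_divisive,
    read_modules,
    similarity_matrix,
    write_modules,
)
from ppimod.synthetic import generate_benchmark


def partition_of(mods):
    return {frozenset(m) for m in mods.modules}


class TestHC:
    def test_block_diagonal_two_blocks(self):
        nodes = list("abcdef")
        sim = np.eye(6)
        for i, j in itertools.combinations(range(3), 2):
            sim[i, j] = sim[j, i] = 0.9
        for i, j in itertools.combinations(range(3, 6), 2):
            sim[i, j] = sim[j, i] = 0.9
        mods = hc_agnes(nodes, sim, k=2)
        assert partition_of(mods) == {frozenset("abc"), frozenset("def")}

    def test_k_equals_n_singletons(self):
        nodes = list("abcd")
        mods = hc_agnes(nodes, np.eye(4), k=4)
        assert partition_of(mods) == {frozenset(x) for x in "abcd"}

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            hc_agnes(list("ab"), np.eye(2), k=3)

    def test_matches_exhaustive_two_partition_search(self):
        """On a well-separated 6-node matrix with one noisy entry, the greedy
        agglomeration at k=2 finds the 2-partition maximizing average
        within-cluster (equivalently minimizing inter-cluster) similarity,
        verified by enumerating all 2-partitions."""
        nodes = list("abcdef")
        rng = np.random.default_rng(4)
        sim = np.eye(6)
        for i, j in itertools.combinations(range(6), 2):
            same = (i < 3) == (j < 3)
            v = 0.8 + 0.1 * rng.random() if same else 0.1 * rng.random()
            sim[i, j] = sim[j, i] = v
        sim[2, 3] = sim[3, 2] = 0.55  # noisy cross-block entry

        def avg_inter(groups):
            a, b = groups
            return np.mean([sim[i, j] for i in a for j in b])

        best = None
        for bits in range(1, 2**5):  # node 0 fixed in group A
            a = [0] + [i for i in range(1, 6) if bits >> (i - 1) & 1]
            b = [i for i in range(1, 6) if i not in a]
            if not b:
                continue
            cand = (avg_inter((a, b)), frozenset(a))
            if best is None or cand[0] < best[0]:
                best = cand
        expected = {
            frozenset(nodes[i] for i in best[1]),
            frozenset(n for i, n in enumerate(nodes) if i not in best[1]),
        }
        mods = hc_agnes(nodes, sim, k=2, linkage="average")
        assert partition_of(mods) == expected

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scipy_hierarchy(self, linkage, seed):
        """Independent route: scipy's agglomerative linkage on distance
        1 - similarity produces the same k-partition on tie-free matrices."""
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(seed)
        n = 8
        sim = np.eye(n)
        vals = 0.2 + 0.6 * rng.random(n * (n - 1) // 2)  # generic: no tied merges
        k = 0
        for i, j in itertools.combinations(range(n), 2):
            sim[i, j] = sim[j, i] = vals[k]
            k += 1
        nodes = [f"n{i}" for i in range(n)]
        for kk in (2, 3, 4):
            z = scipy_linkage(squareform(1 - sim, checks=False), method=linkage)
            labels = fcluster(z, t=kk, criterion="maxclust")
            expected = {
                frozenset(nodes[i] for i in range(n) if labels[i] == c)
                for c in set(labels)
            }
            got = partition_of(hc_agnes(nodes, sim, k=kk, linkage=linkage))
            assert got == expected


class TestNG:
    def test_bridge_removed_first(self, bridge_graph):
        mods = ng_divisive(bridge_graph, s=1)
        assert partition_of(mods) == {frozenset("abc"), frozenset("def")}

    def test_s_zero_is_components(self, bridge_graph):
        mods = ng_divisive(bridge_graph, s=0)
        assert partition_of(mods) == {frozenset("abcdef")}

    def test_all_edges_removed_singletons(self, bridge_graph):
        m = bridge_graph.number_of_edges()
        mods = ng_divisive(bridge_graph, s=m)
        assert all(len(x) == 1 for x in mods.modules)

    def test_s_beyond_edges_warns(self, bridge_graph):
        with pytest.warns(UserWarning, match="edgeless"):
            ng_divisive(bridge_graph, s=bridge_graph.number_of_edges() + 5)

    @pytest.mark.parametrize("seed", range(3))
    def test_successive_steps_refine(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        prev = ng_divisive(g, s=0)
        for s in range(1, 6):
            cur = ng_divisive(g, s=s)
            # every current module is contained in some previous module
            for m in cur.modules:
                assert any(m <= p for p in prev.modules)
            prev = cur


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        mods = mcl(g, r=2.0)
        assert partition_of(mods) == {frozenset("abc"), frozenset("xyz")}

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("a")
        mods = mcl(g, r=2.0)
        assert partition_of(mods) == {frozenset("a")}

    def test_partition_covers_nodes(self):
        b = generate_benchmark(seed=3)
        mods = mcl(b.network, r=2.0)
        assert mods.assigned == frozenset(b.network.nodes)
        counts = sum(len(m) for m in mods.modules)
        assert counts == b.network.number_of_nodes()  # disjoint cover

    @pytest.mark.parametrize("seed", range(3))
    def test_cluster_count_nondecreasing_in_inflation(self, seed):
        b = generate_benchmark(seed=seed)
        counts = [len(mcl(b.network, r=r)) for r in (1.4, 2.0, 5.0)]
        assert counts == sorted(counts)

    def test_columns_stay_stochastic(self):
        b = generate_benchmark(seed=0)
        devs = []
        mcl(
            b.network,
            r=2.0,
            on_iteration=lambda m: devs.append(abs(m.sum(axis=0) - 1.0).max()),
        )
        assert devs and max(devs) < 1e-9

    def test_invalid_inflation(self):
        with pytest.raises(ValueError):
            mcl(nx.complete_graph(3), r=1.0)


class TestMCODE:
    def test_k5_with_pendant_path(self):
        """The K5 dominates the vertex weighting and is recovered as a pure
        module; pendant-path vertices (low weight) never join it."""
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"k{i}" for i in g.nodes})
        g.add_edges_from([("k0", "p1"), ("p1", "p2"), ("p2", "p3")])
        k5 = frozenset({"k0", "k1", "k2", "k3", "k4"})
        mods = mcode(g, t=0.2)
        assert k5 in partition_of(mods)
        assert all(m == k5 or not (m & k5) for m in mods.modules)

    def test_edgeless_graph_empty(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        mods = mcode(g, t=0.2)
        assert len(mods) == 0
        assert mods.residual == frozenset("abc")

    @pytest.mark.parametrize("seed", range(3))
    def test_smaller_cutoff_smaller_modules(self, seed):
        b = generate_benchmark(seed=seed)
        sizes = []
        for t in (0.05, 0.2, 0.5):
            mods = mcode(b.network, t=t)
            sizes.append(max((len(m) for m in mods.modules), default=0))
        assert sizes == sorted(sizes)

    def test_fluff_allows_overlap(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"a{i}" for i in g.nodes})
        h = nx.complete_graph(4)
        h = nx.relabel_nodes(h, {i: f"b{i}" for i in h.nodes})
        g.update(h)
        g.add_edge("a0", "b0")
        mods = mcode(g, t=0.9, f=0.1)
        assert mods.overlapping


@pytest.mark.parametrize("method", ["hc", "ng", "mcl", "mcode"])
def test_relabeling_invariance(method):
    g = nx.gnp_random_graph(10, 0.4, seed=5)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    rng = np.random.default_rng(1)
    perm = list(g.nodes)
    rng.shuffle(perm)
    mapping = dict(zip(sorted(g.nodes), perm))
    h = nx.relabel_nodes(g, mapping)

    def run(net):
        if method == "hc":
            nodes, sim = similarity_matrix(net, "nb")
            return hc_agnes(nodes, sim, k=3)
        if method == "ng":
            return ng_divisive(net, s=3)
        if method == "mcl":
            return mcl(net, r=2.0)
        return mcode(net, t=0.2)

    a = {frozenset(mapping[v] for v in m) for m in run(g).modules}
    b = {frozenset(m) for m in run(h).modules}
    assert a == b


def test_modules_round_trip(tmp_path, bridge_graph):
    mods = ng_divisive(bridge_graph, s=1)
    p = tmp_path / "mods.tsv"
    write_modules(mods, str(p))
    back = read_modules(str(p))
    assert partition_of(back) == partition_of(mods)
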