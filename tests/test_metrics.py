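import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import traitnet as tn
from traitnet.metrics import best_partition_exhaustive

from conftest import make_network


def q_oracle(adj: np.ndarray, labels: dict[int, int]) -> float:
    """Independent Newman–Girvan Q: (1/2m) sum_ij (A_ij - k_i k_j / 2m)
    over same-community pairs."""
    a = np.asarray(adj, dtype=float)
    m2 = a.sum()
    if m2 == 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


def path_graph(n):
    adj = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


class TestDegreeAndDensity:
    def test_empty_sixteen(self):
        net = make_network(np.zeros((16, 16), dtype=int))
        assert tn.edge_density(net) == 0.0
        assert np.all(tn.degree(net) == 0)

    def test_complete_sixteen(self):
        adj = np.ones((16, 16), dtype=int) - np.eye(16, dtype=int)
        net = make_network(adj)
        assert tn.edge_density(net) == 1.0
        assert np.all(tn.degree(net) == 15)

    def test_path_degrees(self):
        net = make_network(path_graph(3))
        np.testing.assert_array_equal(tn.degree(net), [1, 2, 1])

    def test_density_fraction(self):
        # 41 edges over 16 nodes -> 41/120
        rng = np.random.default_rng(0)
        g = nx.gnm_random_graph(16, 41, seed=4)
        adj = nx.to_numpy_array(g, dtype=int)
        assert tn.edge_density(make_network(adj)) == pytest.approx(41 / 120)

    def test_density_needs_two_nodes(self):
        with pytest.raises(ValueError):
            tn.edge_density(make_network(np.zeros((1, 1), dtype=int)))

    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    def test_handshake_lemma(self, n, seed):
        rng = np.random.default_rng(seed)
        adj = np.triu((rng.random((n, n)) < 0.4).astype(int), 1)
        adj = adj + adj.T
        net = make_network(adj)
        assert tn.degree(net).sum() == 2 * net.n_edges


class TestModularity:
    def test_two_disjoint_triangles(self):
        adj = np.zeros((6, 6), dtype=int)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        partition, q = tn.detect_modules(make_network(adj))
        assert q == pytest.approx(0.5)
        assert len(set(partition.values())) == 2

    def test_complete_single_module_q_zero(self):
        adj = np.ones((16, 16), dtype=int) - np.eye(16, dtype=int)
        q = tn.modularity_q(adj, [set(range(16))])
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_empty_network_convention(self):
        net = make_network(np.zeros((5, 5), dtype=int))
        partition, q = tn.detect_modules(net)
        assert q == 0.0
        assert sorted(partition.values()) == [0, 1, 2, 3, 4]

    def test_isolated_nodes_are_singletons(self):
        adj = np.zeros((5, 5), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        partition, q = tn.detect_modules(make_network(adj))
        labs = [partition[f"n{i:02d}"] for i in range(5)]
        assert labs[0] == labs[1]
        assert len(set(labs)) == 4  # the pair plus three singletons

    def test_greedy_is_reproducible(self, planted_matrix):
        net = tn.build_network(planted_matrix)
        p1, q1 = tn.detect_modules(net)
        p2, q2 = tn.detect_modules(net)
        assert p1 == p2 and q1 == q2

    def test_louvain_seeded(self, planted_matrix):
        net = tn.build_network(planted_matrix)
        p1, q1 = tn.detect_modules(net, method="louvain", seed=11)
        p2, q2 = tn.detect_modules(net, method="louvain", seed=11)
        assert p1 == p2 and q1 == q2
        with pytest.raises(ValueError):
            tn.detect_modules(net, method="louvain")

    def test_q_matches_oracle_on_random_graphs(self):
        for seed in range(30):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            adj = nx.to_numpy_array(g, dtype=int)
            net = make_network(adj)
            partition, q = tn.detect_modules(net)
            labels = {i: partition[f"n{i:02d}"] for i in range(12)}
            assert q == pytest.approx(q_oracle(adj, labels), abs=1e-12)

    def test_q_matches_igraph(self):
        igraph = pytest.importorskip("igraph")
        for seed in range(10):
            g = nx.gnp_random_graph(16, 0.3, seed=seed)
            adj = nx.to_numpy_array(g, dtype=int)
            partition, q = tn.detect_modules(make_network(adj))
            ig = igraph.Graph.Adjacency(adj.tolist(), mode="undirected")
            membership = [partition[f"n{i:02d}"] for i in range(16)]
            assert q == pytest.approx(ig.modularity(membership), abs=1e-12)

    def test_greedy_not_better_than_exhaustive(self):
        # on every connected graph with <= 6 nodes, the greedy Q never
        # exceeds the exhaustive optimum, and both Q evaluations agree
        atlas = [g for g in nx.graph_atlas_g()[1:209]
                 if g.number_of_nodes() >= 2 and nx.is_connected(g)]
        assert len(atlas) > 100
        for g in atlas:
            adj = nx.to_numpy_array(g, dtype=int)
            net = make_network(adj)
            partition, q_greedy = tn.detect_modules(net)
            _, q_best = best_partition_exhaustive(adj)
            assert q_greedy <= q_best + 1e-12
            labels = {i: partition[f"n{i:02d}"]
                      for i in range(g.number_of_nodes())}
            assert q_greedy == pytest.approx(
                q_oracle(adj, labels), abs=1e-12)


class TestHubsAndImportance:
    def test_tie_break_lexicographic(self):
        net = make_network(np.zeros((4, 4), dtype=int))
        met = tn.compute_metrics(net)
        assert [t for t, _ in tn.hub_traits(met, 4)] == \
            ["n00", "n01", "n02", "n03"]

    def test_path_top_hub(self):
        met = tn.compute_metrics(make_network(path_graph(3)))
        assert tn.hub_traits(met, 1)[0] == ("n01", 2)

    def test_planted_hub_ranks_first(self):
        cfg = tn.SyntheticConfig(
            n_records=400, blocks=tn.default_blocks(rho_in=0.9), rho_out=0.0,
            hub_trait="SPC", hub_rho=0.4, seed=3)
        m = tn.log_transform(tn.generate(cfg))
        met = tn.compute_metrics(tn.build_network(m))
        assert tn.hub_traits(met, 1)[0][0] == "SPC"

    def test_importance_complete_graph(self):
        adj = np.ones((16, 16), dtype=int) - np.eye(16, dtype=int)
        net = tn.TraitNetwork(adjacency=adj, trait_names=list(tn.DEFAULT_TRAITS),
                              alpha=0.05)
        met = tn.compute_metrics(net)
        imp = tn.importance(met, tn.default_categories())
        assert all(v == 15.0 for v in imp.absolute.values())
        assert all(v == pytest.approx(15 / 240) for v in imp.relative.values())

    def test_importance_empty_network(self):
        net = tn.TraitNetwork(
            adjacency=np.zeros((16, 16), dtype=int),
            trait_names=list(tn.DEFAULT_TRAITS), alpha=0.05)
        imp = tn.importance(tn.compute_metrics(net), tn.default_categories())
        assert all(v == 0.0 for v in imp.absolute.values())
        assert all(v == 0.0 for v in imp.relative.values())

    def test_importance_hand_case(self):
        # economic degrees all 2, chemical all 0, structural all 1
        cats = tn.default_categories()
        adj = np.zeros((16, 16), dtype=int)
        names = list(tn.DEFAULT_TRAITS)
        econ = [names.index(t) for t in cats[0].members]
        struct = [names.index(t) for t in cats[2].members]
        for i, j in zip(econ, econ[1:] + econ[:1]):       # 6-cycle: degree 2
            adj[i, j] = adj[j, i] = 1
        adj[struct[0], struct[1]] = adj[struct[1], struct[0]] = 1
        adj[struct[2], struct[3]] = adj[struct[3], struct[2]] = 1
        net = tn.TraitNetwork(adjacency=adj, trait_names=names, alpha=0.05)
        imp = tn.importance(tn.compute_metrics(net), cats)
        assert imp.absolute == {"economic": 2.0, "chemical": 0.0,
                                "structural": 1.0}
        assert imp.relative["economic"] == pytest.approx(2 / 16)
        assert imp.relative["structural"] == pytest.approx(1 / 16)

    def test_importance_invariant(self, planted_matrix):
        # sum over categories of absolute * size equals the total degree
        met = tn.compute_metrics(tn.build_network(planted_matrix))
        imp = tn.importance(met, tn.default_categories())
        total = sum(imp.absolute[c.name] * len(c.members)
                    for c in tn.default_categories())
        assert total == pytest.approx(met.degree.sum())

    def test_unknown_trait_rejected(self):
        met = tn.compute_metrics(make_network(np.zeros((2, 2), dtype=int)))
        with pytest.raises(ValueError):
            tn.importance(met, (tn.TraitCategory("x", ("nope",)),))
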