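"""Signed modularity, the Louvain optimizer, and consensus clustering."""

import numpy as np
import pytest

from coopnet.community import (
    Partition,
    consensus_cluster,
    expected_weights,
    louvain_signed,
    signed_modularity,
)
from coopnet.cooccurrence import SignedNetwork
from coopnet.datatypes import ValidationError


def modularity_double_loop(net: SignedNetwork, partition: Partition) -> float:
    """Brute-force oracle: explicit double loop over ordered node pairs.

    Q = 1/(2(v+ + v-)) * sum_ij [(w+ - s+_i s+_j / 2v+) - (w- - s-_i s-_j / 2v-)] δ
    """
    sp, sm = net.strengths()
    vp, vm = net.v_plus, net.v_minus
    if vp + vm == 0:
        return 0.0
    w = {}
    for (u, v), weight in net.edges.items():
        w[(u, v)] = w[(v, u)] = weight
    q = 0.0
    for i in net.nodes:
        for j in net.nodes:
            if partition.membership[i] != partition.membership[j]:
                continue
            wij = w.get((i, j), 0.0) if i != j else 0.0
            wp_ij, wm_ij = max(wij, 0.0), max(-wij, 0.0)
            term = wp_ij - wm_ij
            if vp > 0:
                term -= sp[i] * sp[j] / (2 * vp)
            if vm > 0:
                term += sm[i] * sm[j] / (2 * vm)
            q += term
    return q / (2 * (vp + vm))


def unit_triangle() -> SignedNetwork:
    return SignedNetwork(
        nodes=("a", "b", "c"),
        frequencies={"a": 1, "b": 1, "c": 1},
        edges={("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0},
    )


def random_network(rng, n_max=30, p=0.35, signed=False) -> SignedNetwork:
    n = int(rng.integers(4, n_max + 1))
    nodes = tuple(f"n{i:02d}" for i in range(n))
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.1, 4.0))
                if signed and rng.random() < 0.4:
                    w = -w
                edges[(nodes[i], nodes[j])] = w
    return SignedNetwork(nodes=nodes, frequencies={x: 1 for x in nodes}, edges=edges)


def two_signed_cliques(size=5) -> SignedNetwork:
    """Two positive cliques joined by all-negative edges."""
    nodes = tuple(f"n{i}" for i in range(2 * size))
    edges = {}
    for off in (0, size):
        for i in range(size):
            for j in range(i + 1, size):
                edges[(f"n{off + i}", f"n{off + j}")] = 1.0
    for i in range(size):
        for j in range(size):
            a, b = sorted((f"n{i}", f"n{size + j}"))
            edges[(a, b)] = -1.0
    return SignedNetwork(nodes=nodes, frequencies={x: 1 for x in nodes}, edges=edges)


class TestExpectedWeights:
    def test_triangle_value(self):
        net = unit_triangle()
        for i, j in (("a", "b"), ("a", "c"), ("b", "c")):
            assert expected_weights(net, i, j, "+") == pytest.approx(2 / 3)

    def test_empty_negative_layer_gives_zero(self):
        assert expected_weights(unit_triangle(), "a", "b", "-") == 0.0

    def test_null_model_conserves_total_weight(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, signed=True)
        for sign, total in (("+", net.v_plus), ("-", net.v_minus)):
            s = sum(
                expected_weights(net, i, j, sign)
                for i in net.nodes
                for j in net.nodes
            )
            assert s == pytest.approx(2 * total, rel=1e-9)


class TestSignedModularity:
    def test_all_in_one_is_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_network(rng, signed=True)
            part = Partition({n: 0 for n in net.nodes})
            assert signed_modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_singletons(self):
        part = Partition({"a": 0, "b": 1, "c": 2})
        assert signed_modularity(unit_triangle(), part) == pytest.approx(-1 / 3)

    def test_matches_double_loop_oracle_on_signed_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = random_network(rng, signed=True)
            labels = rng.integers(0, 4, size=net.n_nodes)
            part = Partition.from_labels(net.nodes, labels)
            assert signed_modularity(net, part) == pytest.approx(
                modularity_double_loop(net, part), abs=1e-12
            )

    def test_equals_newman_on_positive_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        for _ in range(10):
            net = random_network(rng, signed=False)
            labels = rng.integers(0, 3, size=net.n_nodes)
            part = Partition.from_labels(net.nodes, labels)
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            for (u, v), w in net.edges.items():
                g.add_edge(u, v, weight=w)
            communities = [
                set(members) for members in part.module_members().values()
            ]
            q_nx = nx.community.modularity(g, communities, weight="weight")
            assert signed_modularity(net, part) == pytest.approx(q_nx, abs=1e-12)

    def test_uncovered_node_rejected(self):
        with pytest.raises(ValidationError, match="cover"):
            signed_modularity(unit_triangle(), Partition({"a": 0, "b": 0}))


class TestLouvain:
    def test_recovers_planted_signed_cliques(self):
        res = louvain_signed(two_signed_cliques(), seed=1)
        groups = res.partition.module_members()
        assert len(groups) == 2
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"n{i}" for i in range(5)),
            frozenset(f"n{i}" for i in range(5, 10)),
        }

    def test_edgeless_network_stays_singleton(self):
        nodes = tuple("abcd")
        net = SignedNetwork(nodes=nodes, frequencies={n: 1 for n in nodes}, edges={})
        res = louvain_signed(net, seed=0)
        assert res.partition.n_modules == 4
        assert res.modularity == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, signed=True)
        a = louvain_signed(net, seed=99)
        b = louvain_signed(net, seed=99)
        assert a.partition.membership == b.partition.membership
        assert a.phase_modularity == b.phase_modularity

    def test_q_non_decreasing_across_phases(self):
        rng = np.random.default_rng(31)
        for seed in range(5):
            net = random_network(rng, signed=True)
            res = louvain_signed(net, seed=seed)
            diffs = np.diff(res.phase_modularity)
            assert np.all(diffs >= -1e-12)

    def test_beats_random_partitions(self):
        rng = np.random.default_rng(41)
        net = random_network(rng, signed=True)
        for seed in (0, 1, 2):
            q_opt = louvain_signed(net, seed=seed).modularity
            for _ in range(100):
                k = int(rng.integers(1, net.n_nodes + 1))
                labels = rng.integers(0, k, size=net.n_nodes)
                part = Partition.from_labels(net.nodes, labels)
                assert q_opt >= signed_modularity(net, part) - 1e-12

    def test_negative_clique_is_split_not_merged(self):
        # all-negative clique: grouping any two nodes costs modularity
        nodes = tuple(f"n{i}" for i in range(5))
        edges = {
            (nodes[i], nodes[j]): -1.0
            for i in range(5)
            for j in range(i + 1, 5)
        }
        net = SignedNetwork(nodes=nodes, frequencies={n: 1 for n in nodes}, edges=edges)
        res = louvain_signed(net, seed=7)
        assert res.partition.n_modules == 5
        # while the positively signed mirror collapses into one module
        pos = SignedNetwork(
            nodes=nodes,
            frequencies={n: 1 for n in nodes},
            edges={k: 1.0 for k in edges},
        )
        assert louvain_signed(pos, seed=7).partition.n_modules == 1


class TestConsensus:
    def test_unambiguous_network_converges_in_one_round(self):
        net = two_signed_cliques()
        res = consensus_cluster(net, runs=10, threshold=0.4, seed=0)
        assert res.converged and res.iterations == 1
        vals = np.unique(res.co_classification)
        assert set(np.round(vals, 12)).issubset({0.0, 1.0})
        assert res.final_partition.n_modules == 2

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        net = random_network(rng, signed=True)
        res = consensus_cluster(net, runs=8, threshold=0.4, seed=3)
        c = res.co_classification
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert c.min() >= 0.0 and c.max() <= 1.0

    def test_idempotent_on_converged_result(self):
        net = two_signed_cliques()
        res = consensus_cluster(net, runs=10, threshold=0.4, seed=0)
        # feed the 0/1 co-classification graph back in
        from coopnet.community import _consensus_graph

        again = consensus_cluster(
            _consensus_graph(res.co_classification, 0.4, net.nodes),
            runs=10,
            threshold=0.4,
            seed=1,
        )
        assert again.final_partition.canonical() == res.final_partition.canonical()

    def test_determinism(self):
        rng = np.random.default_rng(13)
        net = random_network(rng, signed=True)
        a = consensus_cluster(net, runs=12, threshold=0.4, seed=5)
        b = consensus_cluster(net, runs=12, threshold=0.4, seed=5)
        assert a.final_partition.membership == b.final_partition.membership
        assert np.array_equal(a.co_classification, b.co_classification)

    def test_parameter_validation(self):
        net = two_signed_cliques()
        with pytest.raises(ValidationError):
            consensus_cluster(net, runs=1, threshold=0.4)
        with pytest.raises(ValidationError):
            consensus_cluster(net, runs=5, threshold=1.0)
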