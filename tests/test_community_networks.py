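"""Network construction, Girvan–Newman communities and difference analysis."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcnatools.community_networks import (
    CommunityPartition,
    ContactNetwork,
    build_network,
    community_delta,
    consensus_network,
    difference_network,
    girvan_newman,
    modularity,
    top_changed_residues,
)
from dcnatools.contact_dynamics import ContactProbabilityMatrix, CorrelationMatrix
from dcnatools.errors import NetworkError

from helpers import make_node_table, nx_modularity, random_connected_graph


def cpm(P, chain_size=1, state="s"):
    P = np.asarray(P, dtype=float)
    return ContactProbabilityMatrix(
        P=P, cutoff=4.5, exclusion=1, state_label=state,
        node_table=make_node_table(P.shape[0], chain_size),
    )


def graph_network(G):
    return ContactNetwork(
        graph=G, node_table=make_node_table(G.number_of_nodes(), 1), mode="dcna", state_label="g"
    )


def two_triangles(bridge: bool) -> nx.Graph:
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    if bridge:
        G.add_edge(2, 3)
    return G


class TestBuildNetwork:
    def test_covariance_weights(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.9
        P[1, 2] = P[2, 1] = 0.8
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 1.0
        c[1, 2] = c[2, 1] = -0.5
        net = build_network(cpm(P), CorrelationMatrix(np.clip(c, -1, 1)), mode="covariance")
        assert net.graph[0][1]["weight"] == pytest.approx(0.0)
        assert net.graph[1][2]["weight"] == pytest.approx(np.log(2), abs=1e-12)

    def test_covariance_threshold_excludes_weak_contacts(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.6
        c = np.eye(3); c[0, 1] = c[1, 0] = 0.9
        net = build_network(cpm(P), CorrelationMatrix(c), mode="covariance")
        assert not net.graph.has_edge(0, 1)

    def test_zero_correlation_on_edge_rejected(self):
        P = np.zeros((2, 2)); P[0, 1] = P[1, 0] = 0.9
        c = np.eye(2)
        with pytest.raises(NetworkError, match="A:1"):
            build_network(cpm(P), CorrelationMatrix(c), mode="covariance")

    def test_dcna_keeps_any_nonzero_occupancy(self):
        P = np.zeros((3, 3))
        P[0, 2] = P[2, 0] = 0.05
        net = build_network(cpm(P))
        assert net.graph[0][2]["weight"] == 0.05
        assert net.graph.number_of_edges() == 1


class TestConsensus:
    def _matrices(self, probs_by_state):
        out = []
        for label, p in probs_by_state.items():
            P = np.zeros((4, 4))
            P[0, 2] = P[2, 0] = p
            P[1, 3] = P[3, 1] = 0.9
            out.append(cpm(P, state=label))
        return out

    def test_edge_kept_when_stable_everywhere(self):
        cons = consensus_network(self._matrices({"a": 0.9, "b": 0.8, "c": 0.95}), 0.75)
        assert cons.graph.has_edge(0, 2) and cons.graph.has_edge(1, 3)
        assert cons.graph[0][2]["p_b"] == 0.8

    def test_edge_dropped_when_unstable_in_one_state(self):
        cons = consensus_network(self._matrices({"a": 0.9, "b": 0.2, "c": 0.95}), 0.75)
        assert not cons.graph.has_edge(0, 2)
        assert cons.graph.has_edge(1, 3)

    def test_three_state_consensus_equals_pairwise_intersection(self, rng):
        mats = []
        for label in "abc":
            P = np.zeros((6, 6))
            iu = np.triu_indices(6, k=2)
            vals = rng.random(len(iu[0]))
            P[iu] = vals
            P = P + P.T
            mats.append(cpm(P, state=label))
        full = consensus_network(mats, 0.5)
        pairwise = [
            set(map(tuple, map(sorted, consensus_network([a, b], 0.5).graph.edges())))
            for a, b in [(mats[0], mats[1]), (mats[1], mats[2]), (mats[0], mats[2])]
        ]
        expected = set.intersection(*pairwise)
        got = set(map(tuple, map(sorted, full.graph.edges())))
        assert got == expected

    def test_per_state_probabilities_respect_threshold(self):
        cons = consensus_network(self._matrices({"a": 0.9, "b": 0.8, "c": 0.95}), 0.75)
        for _, _, d in cons.graph.edges(data=True):
            for s in cons.states:
                assert d[f"p_{s}"] >= cons.stability_min_probability


class TestModularity:
    def test_two_disconnected_triangles(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity(two_triangles(False), labels) == pytest.approx(0.5, abs=1e-15)

    def test_two_triangles_plus_bridge(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity(two_triangles(True), labels) == pytest.approx(5 / 14, abs=1e-15)

    def test_single_community_is_zero(self):
        assert modularity(two_triangles(True), np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_edgeless_graph_rejected(self):
        G = nx.empty_graph(3)
        with pytest.raises(NetworkError):
            modularity(G, np.zeros(3, dtype=int))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 8))
    def test_matches_networkx_on_random_partitions(self, seed, n):
        G = random_connected_graph(n, seed)
        labels = np.random.default_rng(seed).integers(0, 3, size=n)
        assert modularity(G, labels) == pytest.approx(nx_modularity(G, labels), abs=1e-12)


class TestGirvanNewman:
    def test_bridge_removed_first_recovers_triangles(self):
        part = girvan_newman(graph_network(two_triangles(True)))
        assert part.n_communities == 2
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1
        assert part.modularity == pytest.approx(5 / 14)

    def test_disconnected_triangles_initial_partition_final(self):
        part = girvan_newman(graph_network(two_triangles(False)))
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(0.5)

    def test_single_clique_stays_whole(self):
        part = girvan_newman(graph_network(nx.complete_graph(4)))
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0)

    def test_deterministic(self):
        G = random_connected_graph(8, 5)
        p1 = girvan_newman(graph_network(G))
        p2 = girvan_newman(graph_network(G.copy()))
        assert np.array_equal(p1.labels, p2.labels)

    def test_stopping_rule_matches_best_q_when_improvements_large(self):
        # planted two-clique graph: all recorded improvements >= 0.001
        part = girvan_newman(graph_network(two_triangles(True)))
        best_q = max(q for _, q in part.trace)
        assert part.modularity == best_q


class TestDifferenceNetwork:
    def _consensus(self):
        P_apo = np.zeros((4, 4))
        P_apo[0, 2] = P_apo[2, 0] = 0.9
        P_apo[1, 3] = P_apo[3, 1] = 0.8
        P_ner = np.zeros((4, 4))
        P_ner[0, 2] = P_ner[2, 0] = 0.2
        P_ner[1, 3] = P_ner[3, 1] = 0.95
        return consensus_network(
            [cpm(P_apo, state="apo"), cpm(P_ner, state="NER")], 0.1
        )

    def test_subtraction(self):
        diff = difference_network(self._consensus(), "apo", "NER")
        assert diff.graph[0][2]["delta"] == pytest.approx(-0.7)

    def test_identity_transition_is_zero(self):
        diff = difference_network(self._consensus(), "apo", "apo")
        assert all(d["delta"] == 0 for _, _, d in diff.graph.edges(data=True))

    def test_antisymmetry(self):
        cons = self._consensus()
        fwd = difference_network(cons, "apo", "NER")
        rev = difference_network(cons, "NER", "apo")
        for u, v, d in fwd.graph.edges(data=True):
            assert d["delta"] == pytest.approx(-rev.graph[u][v]["delta"])

    def test_unknown_state_rejected(self):
        with pytest.raises(NetworkError):
            difference_network(self._consensus(), "apo", "PIC")


class TestCommunityDelta:
    def _diff_and_partition(self, rng, n=12):
        P_a = np.zeros((n, n))
        iu = np.triu_indices(n, k=2)
        P_a[iu] = rng.random(len(iu[0]))
        P_a = P_a + P_a.T
        P_b = np.zeros((n, n))
        P_b[iu] = rng.random(len(iu[0]))
        P_b = P_b + P_b.T
        cons = consensus_network([cpm(P_a, state="a"), cpm(P_b, state="b")], 0.05)
        diff = difference_network(cons, "a", "b")
        labels = rng.integers(0, 3, size=n)
        return diff, CommunityPartition(labels=labels, modularity=0.0)

    def test_simple_sum(self):
        P_a = np.zeros((4, 4)); P_b = np.zeros((4, 4))
        for (i, j), (pa, pb) in {(0, 2): (0.5, 0.8), (1, 3): (0.6, 0.5)}.items():
            P_a[i, j] = P_a[j, i] = pa
            P_b[i, j] = P_b[j, i] = pb
        cons = consensus_network([cpm(P_a, state="a"), cpm(P_b, state="b")], 0.1)
        diff = difference_network(cons, "a", "b")
        part = CommunityPartition(labels=np.array([0, 0, 1, 1]), modularity=0.0)
        delta = community_delta(diff, part)
        assert delta.delta[0, 1] == pytest.approx(0.3 - 0.1)

    def test_matches_brute_force_accumulation(self, rng):
        diff, part = self._diff_and_partition(rng)
        delta = community_delta(diff, part)
        K = len(delta.community_ids)
        expected = np.zeros((K, K))
        for u, v, d in diff.graph.edges(data=True):
            a, b = sorted((part.labels[u], part.labels[v]))
            if a == b:
                expected[a, a] += d["delta"]
            else:
                expected[a, b] += d["delta"]
                expected[b, a] += d["delta"]
        assert np.allclose(delta.delta, expected)

    def test_grand_total_conservation(self, rng):
        diff, part = self._diff_and_partition(rng)
        delta = community_delta(diff, part)
        total_edges = sum(d["delta"] for _, _, d in diff.graph.edges(data=True))
        total_matrix = np.triu(delta.delta).sum()
        assert total_matrix == pytest.approx(total_edges)

    def test_antisymmetric_in_transition(self, rng):
        diff, part = self._diff_and_partition(rng)
        fwd = community_delta(diff, part).delta
        Grev = nx.Graph()
        Grev.add_nodes_from(range(diff.graph.number_of_nodes()))
        for u, v, d in diff.graph.edges(data=True):
            Grev.add_edge(u, v, delta=-d["delta"])
        from dcnatools.community_networks import DifferenceNetwork

        rev_diff = DifferenceNetwork(
            graph=Grev, node_table=diff.node_table, state_a="b", state_b="a"
        )
        assert np.allclose(community_delta(rev_diff, part).delta, -fwd)


class TestTopChangedResidues:
    def _diff(self, edge_deltas, n=5):
        import networkx as nx

        from dcnatools.community_networks import DifferenceNetwork

        G = nx.Graph()
        G.add_nodes_from(range(n))
        for (u, v), d in edge_deltas.items():
            G.add_edge(u, v, delta=d)
        return DifferenceNetwork(
            graph=G, node_table=make_node_table(n, 1), state_a="a", state_b="b"
        )

    def test_ranking_by_aggregate_magnitude(self):
        diff = self._diff({(0, 1): 0.5, (0, 2): 0.4, (3, 4): 0.3})
        top = top_changed_residues(diff)
        assert top.iloc[0]["node_index"] == 0
        assert top.iloc[0]["aggregate_delta_p"] == pytest.approx(0.9)
        assert top.iloc[0]["direction"] == "gain"

    def test_cancellation_ranks_last(self):
        diff = self._diff({(0, 1): 0.5, (0, 2): -0.5, (3, 4): 0.1})
        top = top_changed_residues(diff)
        assert top.iloc[-1]["node_index"] == 0

    def test_ties_broken_by_chain_and_residue(self):
        diff = self._diff({(2, 4): 0.3, (1, 3): 0.3})
        top = top_changed_residues(diff)
        # all four touched nodes tie at |0.3|; order by residue number
        touched = top[top["aggregate_delta_p"].abs() > 0]["node_index"].tolist()
        assert touched == sorted(touched)
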