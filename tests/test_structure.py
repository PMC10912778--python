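"""Community detection, reaching centrality, and signed interconnection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import grntrace as gt
from conftest import random_digraph


def brute_force_reachability(g: nx.DiGraph) -> dict:
    """Independent oracle: boolean transitive closure by matrix powers."""
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in g.edges:
        adj[idx[a], idx[b]] = True
    closure = adj.copy()
    for _ in range(n):
        new = closure | (closure @ adj)
        if (new == closure).all():
            break
        closure = new
    np.fill_diagonal(closure, False)
    return {node: closure[idx[node]].sum() for node in nodes}


class TestLocalReachingCentrality:
    def test_chain(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        lrc = gt.local_reaching_centrality(g)["local_reaching_centrality"]
        assert lrc["a"] == pytest.approx(1.0)
        assert lrc["b"] == pytest.approx(0.5)
        assert lrc["c"] == pytest.approx(0.0)

    def test_star_hub_reaches_everything(self):
        g = nx.DiGraph([("hub", f"leaf{i}") for i in range(7)])
        lrc = gt.local_reaching_centrality(g)["local_reaching_centrality"]
        assert lrc["hub"] == pytest.approx(1.0)
        assert (lrc.drop("hub") == 0.0).all()

    def test_matches_brute_force_on_random_digraphs(self):
        """Exact agreement with a matrix-closure oracle, 100 random graphs."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            g = random_digraph(rng, 20, rng.uniform(0.05, 0.3))
            expected = brute_force_reachability(g)
            lrc = gt.local_reaching_centrality(g)["local_reaching_centrality"]
            for node, count in expected.items():
                assert lrc[node] == pytest.approx(count / 19)


class TestDetectCommunities:
    def test_two_components_found_exactly(self):
        g = nx.DiGraph()
        for i in range(4):
            g.add_edge(f"a{i}", f"a{i + 1}", importance=1.0)
            g.add_edge(f"b{i}", f"b{i + 1}", importance=1.0)
        part = gt.detect_communities(g, seed=0)
        assert len(part.communities) == 2
        assert {frozenset(c) for c in part.communities} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_single_node(self):
        g = nx.DiGraph()
        g.add_node("only")
        part = gt.detect_communities(g, seed=0)
        assert part.labels == {"only": "I"}
        assert part.modularity == 0.0

    def test_seeded_determinism_and_order_invariance(self, inferred_network):
        g = inferred_network.to_networkx()
        part_a = gt.detect_communities(g, seed=5)
        shuffled = nx.DiGraph()
        for node in reversed(sorted(g.nodes)):
            shuffled.add_node(node)
        shuffled.add_edges_from(g.edges(data=True))
        part_b = gt.detect_communities(shuffled, seed=5)
        assert part_a.labels == part_b.labels

    def test_labels_ordered_by_size(self, inferred_network):
        part = gt.detect_communities(inferred_network, seed=1)
        sizes = [len(c) for c in part.communities]
        assert sizes == sorted(sizes, reverse=True)
        assert part.label_order[0] == "I"


class TestRankRegulators:
    def test_master_regulator_rank_one(self):
        g = nx.DiGraph([("m", "x"), ("x", "y"), ("m", "z")])
        part = gt.SubnetworkPartition(
            labels={n: "I" for n in g.nodes}, modularity=0.0,
            communities=[frozenset(g.nodes)],
        )
        ranks = gt.rank_regulators(g, part)
        assert ranks.loc["m", "hierarchy_rank"] == 1
        assert ranks.loc["m", "local_reaching_centrality"] == pytest.approx(1.0)

    def test_lrc_tie_broken_by_id(self):
        g = nx.DiGraph([("a", "s1"), ("a", "s2"), ("b", "s1"), ("b", "s2")])
        part = gt.SubnetworkPartition(
            labels={n: "I" for n in g.nodes}, modularity=0.0,
            communities=[frozenset(g.nodes)],
        )
        ranks = gt.rank_regulators(g, part)
        # a and b tie on LRC (2/3) and out-degree (2); id breaks the tie
        assert ranks.loc["a", "hierarchy_rank"] == 1
        assert ranks.loc["b", "hierarchy_rank"] == 2

    def test_ranks_are_permutation_within_subnetwork(self, inferred_network):
        part = gt.detect_communities(inferred_network, seed=1)
        ranks = gt.rank_regulators(inferred_network, part)
        for label, block in ranks.groupby("subnetwork"):
            assert sorted(block["hierarchy_rank"]) == list(range(1, len(block) + 1))


class TestPearsonResidualTest:
    def test_worked_example(self):
        table = pd.DataFrame([[10, 20], [30, 40]])
        chi2, p, dof, expected, resid, low = gt.pearson_residual_test(table)
        assert chi2 == pytest.approx(0.7936507936, abs=1e-6)
        assert resid.iloc[0, 0] == pytest.approx(-2 / np.sqrt(12), abs=1e-9)
        np.testing.assert_allclose(
            expected.to_numpy(), [[12.0, 18.0], [28.0, 42.0]]
        )

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = pd.DataFrame(rng.integers(1, 50, size=(3, 4)))
            chi2, p, dof, *_ = gt.pearson_residual_test(table)
            ref = chi2_contingency(table.to_numpy(), correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_residual_squares_sum_to_statistic(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = pd.DataFrame(rng.integers(0, 40, size=(3, 3)))
            chi2, _, _, _, resid, _ = gt.pearson_residual_test(table)
            assert (resid.to_numpy() ** 2).sum() == pytest.approx(chi2, abs=1e-9)

    def test_uniform_table_nothing_enriched(self):
        chi2, p, dof, _, resid, _ = gt.pearson_residual_test(
            pd.DataFrame([[10, 10], [10, 10]])
        )
        assert chi2 == 0.0
        assert (resid.to_numpy() == 0).all()

    def test_low_expected_cells_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            gt.pearson_residual_test(pd.DataFrame([[1, 0], [0, 30]]))


class TestInterconnectionAnalysis:
    def _network(self):
        g = nx.DiGraph()
        rng = np.random.default_rng(3)
        labels = {}
        for i in range(6):
            labels[f"a{i}"] = "I"
            labels[f"b{i}"] = "II"
        # I represses II heavily; II activates I sparsely
        for i in range(6):
            for j in range(6):
                if rng.random() < 0.7:
                    g.add_edge(f"a{i}", f"b{j}", sign=-1)
                if rng.random() < 0.1:
                    g.add_edge(f"b{i}", f"a{j}", sign=1)
        part = gt.SubnetworkPartition(
            labels=labels, modularity=0.0,
            communities=[frozenset(labels) for _ in range(2)],
        )
        return g, part

    def test_counts_cover_inter_edges_only(self):
        g, part = self._network()
        res = gt.interconnection_analysis(g, part, residual_threshold=1.0)
        n_inter = sum(
            1 for a, b in g.edges if part.labels[a] != part.labels[b]
        )
        assert res.observed.to_numpy().sum() == n_inter

    def test_sign_specific_relations_rendered(self):
        # I represses II (20 negative edges), II activates I (20 positive):
        # both cells deviate from the pooled sign margins
        g = nx.DiGraph()
        labels = {}
        for i in range(20):
            g.add_edge(f"a{i}", f"b{i}", sign=-1)
            g.add_edge(f"b{i}", f"a{(i + 1) % 20}", sign=1)
        for i in range(20):
            labels[f"a{i}"] = "I"
            labels[f"b{i}"] = "II"
        part = gt.SubnetworkPartition(
            labels=labels, modularity=0.0,
            communities=[frozenset(labels) for _ in range(2)],
        )
        res = gt.interconnection_analysis(g, part, residual_threshold=2.0)
        relations = set(res.enriched["relation"])
        assert "I -| II" in relations
        assert "II -> I" in relations

    def test_requires_two_subnetworks(self):
        g = nx.DiGraph([("a", "b", {"sign": 1})])
        part = gt.SubnetworkPartition(
            labels={"a": "I", "b": "I"}, modularity=0.0,
            communities=[frozenset({"a", "b"})],
        )
        with pytest.raises(ValueError, match="2 subnetworks"):
            gt.interconnection_analysis(g, part)
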