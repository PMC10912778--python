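"""Upstream regulons, control fractions, dependency tests, target filter."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import grntrace as gt
from grntrace.synth import PROFILE_ACTIVATOR, PROFILE_NONE


class TestUpstreamRegulon:
    def test_chain_orders(self):
        g = nx.DiGraph([("TF3", "TF2"), ("TF2", "TF1"), ("TF1", "g")])
        orders = gt.upstream_regulon(g, "g", max_order=3)
        assert orders == [{"TF1"}, {"TF1", "TF2"}, {"TF1", "TF2", "TF3"}]

    def test_two_cycle_excludes_self(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        assert gt.upstream_regulon(g, "a", max_order=3) == [{"b"}, {"b"}, {"b"}]

    def test_orphan_gene_empty(self):
        g = nx.DiGraph()
        g.add_node("lonely")
        assert gt.upstream_regulon(g, "lonely") == [set(), set(), set()]

    def test_absent_gene_raises(self):
        g = nx.DiGraph([("a", "b")])
        with pytest.raises(KeyError):
            gt.upstream_regulon(g, "ghost")

    def test_orders_are_nested(self, true_graph, truth):
        for gene in truth.target_ids[:20]:
            o1, o2, o3 = gt.upstream_regulon(true_graph, gene)
            assert o1 <= o2 <= o3


class TestControlFractions:
    def test_one_of_three_direct(self):
        frac = gt.regulon_control_fractions(
            {"t1", "t2", "t3"},
            {"t1": True},
            {},
        )
        assert frac["pct_direct"] == pytest.approx(1 / 3)

    def test_all_misregulated(self):
        frac = gt.regulon_control_fractions(
            {"t1", "t2"}, {}, {"t1": PROFILE_ACTIVATOR, "t2": PROFILE_ACTIVATOR}
        )
        assert frac["pct_indirect"] == 1.0

    def test_empty_regulon_flagged(self):
        frac = gt.regulon_control_fractions(set(), {}, {})
        assert not frac["defined"]
        assert np.isnan(frac["pct_direct"])

    def test_either_bounds_both(self, true_graph, truth, profiles):
        flags = dict(truth.tf_cleavage_status)
        table = gt.build_regulon_table(
            true_graph, truth.target_ids, flags, dict(profiles["profile"])
        )
        defined = table[table["defined"]]
        assert (
            defined["pct_either"]
            >= defined[["pct_direct", "pct_indirect"]].max(axis=1) - 1e-12
        ).all()


class TestMisregulationDependency:
    def test_collinear_input_exact_fit(self):
        idx = [f"g{i}" for i in range(20)]
        fractions = pd.DataFrame(
            {"pct_direct": np.linspace(0, 1, 20),
             "pct_indirect": np.linspace(0, 1, 20),
             "pct_either": np.linspace(0, 1, 20),
             "defined": True},
            index=idx,
        )
        scores = pd.Series(2 * np.linspace(0, 1, 20), index=idx)
        dep = gt.misregulation_dependency(fractions, scores)
        assert dep.loc["pct_direct", "slope"] == pytest.approx(2.0)
        assert dep.loc["pct_direct", "pearson_r"] == pytest.approx(1.0)

    def test_independent_input_near_zero_tau(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(500)]
        fractions = pd.DataFrame(
            {"pct_direct": rng.uniform(size=500),
             "pct_indirect": rng.uniform(size=500),
             "pct_either": rng.uniform(size=500),
             "defined": True},
            index=idx,
        )
        scores = pd.Series(rng.uniform(size=500), index=idx)
        dep = gt.misregulation_dependency(fractions, scores)
        assert abs(dep.loc["pct_direct", "kendall_tau"]) < 0.1

    def test_zero_variance_predictor_flagged(self):
        idx = [f"g{i}" for i in range(12)]
        fractions = pd.DataFrame(
            {"pct_direct": 0.5, "pct_indirect": np.linspace(0, 1, 12),
             "pct_either": np.linspace(0, 1, 12), "defined": True},
            index=idx,
        )
        scores = pd.Series(np.arange(12.0), index=idx)
        dep = gt.misregulation_dependency(fractions, scores)
        assert bool(dep.loc["pct_direct", "flagged"])
        assert np.isnan(dep.loc["pct_direct", "slope"])

    def test_planted_positive_dependency(self, true_graph, truth, profiles):
        flags = dict(truth.tf_cleavage_status)
        table = gt.build_regulon_table(
            true_graph, truth.target_ids, flags, dict(profiles["profile"])
        )
        dep = gt.misregulation_dependency(table, profiles["cumulative_effect"])
        assert dep.loc["pct_direct", "kendall_tau"] > 0
        assert dep.loc["pct_direct", "kendall_p"] < 0.01

    def test_too_few_genes_rejected(self):
        fractions = pd.DataFrame(
            {"pct_direct": [0.1, 0.2], "pct_indirect": [0.1, 0.2],
             "pct_either": [0.1, 0.2], "defined": True},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="10 genes"):
            gt.misregulation_dependency(fractions, pd.Series([1.0, 2.0], index=["a", "b"]))


class TestCrosstabRegulonStatus:
    def test_independent_strata_residuals_zero(self):
        idx = [f"g{i}" for i in range(40)]
        fractions = pd.DataFrame(
            {"pct_direct": ([0.5] * 20 + [0.0] * 20),
             "pct_indirect": [0.5, 0.0] * 20,
             "defined": True},
            index=idx,
        )
        # equal misregulation proportion in every stratum -> O == E
        mis = {g: ((i // 2) % 2 == 0) for i, g in enumerate(idx)}
        out = gt.crosstab_regulon_status(fractions, mis)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_concentration_in_double_positive_cell(
        self, true_graph, truth, profiles
    ):
        flags = dict(truth.tf_cleavage_status)
        table = gt.build_regulon_table(
            true_graph, truth.target_ids, flags, dict(profiles["profile"])
        )
        mis = {
            g: profiles.loc[g, "profile"] != PROFILE_NONE for g in table.index
        }
        out = gt.crosstab_regulon_status(table, mis)
        assert out["p"] < 0.01
        direct_rows = [s for s in out["table"].index if "direct=y" in s]
        assert out["residuals"].loc[direct_rows, "misregulated"].max() > 2


class TestFilterProteaseTargets:
    def _net(self):
        g = nx.DiGraph([("A", "t1"), ("B", "t2"), ("A", "t3")])
        return g

    def test_filter_contract(self):
        flags = {"A": True, "B": False}
        profs = {"t1": PROFILE_ACTIVATOR, "t2": PROFILE_ACTIVATOR, "t3": PROFILE_NONE}
        calls = gt.filter_protease_targets(self._net(), flags, profs)
        kept = calls.edges[calls.edges["keep"]]
        assert list(zip(kept["regulator"], kept["target"])) == [("A", "t1")]
        assert calls.direct_targets == {"A"}
        assert calls.indirect_targets == {"t1"}

    def test_tf_in_both_categories(self):
        g = nx.DiGraph([("A", "B"), ("B", "t")])
        flags = {"A": True, "B": True}
        profs = {"B": PROFILE_ACTIVATOR, "t": PROFILE_ACTIVATOR}
        calls = gt.filter_protease_targets(g, flags, profs)
        assert "B" in calls.direct_targets
        assert "B" in calls.indirect_targets
        assert calls.both == {"B"}

    def test_empty_network(self):
        calls = gt.filter_protease_targets(nx.DiGraph(), {}, {})
        assert calls.direct_targets == set()
        assert len(calls.edges) == 0

    def test_recovery_on_benchmark(self, inferred_network, truth, profiles, cleavage_table):
        flags = dict(cleavage_table["nerd_like"])
        calls = gt.filter_protease_targets(
            inferred_network, flags, dict(profiles["profile"])
        )
        cleaved = truth.cleaved_tfs()
        planted_mis = {
            g for g, p in truth.planted_profile.items() if p != PROFILE_NONE
        }
        recoverable = {
            tf for tf in cleaved
            if any(
                (truth.true_edges["regulator"] == tf)
                & truth.true_edges["target"].isin(planted_mis)
            )
        }
        assert len(calls.direct_targets & recoverable) >= 0.9 * len(recoverable)
        false_calls = calls.direct_targets - cleaved
        assert len(false_calls) <= 0.1 * max(len(calls.direct_targets), 1)


class TestExtendRegulon:
    def test_shared_hub_connects_everything(self):
        g = nx.DiGraph([("hub", f"g{i}") for i in range(5)])
        cent = pd.DataFrame(
            {"local_reaching_centrality": [1.0] + [0.0] * 5},
            index=["hub"] + [f"g{i}" for i in range(5)],
        )
        sub, stats = gt.extend_regulon(
            [f"g{i}" for i in range(5)], g, cent, {"hub": True}
        )
        assert stats["frac_genes_in_largest_component"] == 1.0
        assert "hub" in sub

    def test_no_qualifying_tfs_returns_input_only(self):
        g = nx.DiGraph([("tf", "g0")])
        cent = pd.DataFrame(
            {"local_reaching_centrality": [0.5, 0.0]}, index=["tf", "g0"]
        )
        sub, _ = gt.extend_regulon(["g0"], g, cent, {"tf": False})
        assert set(sub.nodes) == {"g0"}

    def test_max_tfs_respected(self, true_graph, truth):
        cent = gt.local_reaching_centrality(true_graph)
        flags = {tf: True for tf in truth.tf_ids}
        sub, _ = gt.extend_regulon(
            truth.target_ids[:1], true_graph, cent, flags, max_tfs=2
        )
        assert len(set(sub.nodes) - {truth.target_ids[0]}) <= 2


class TestUpstreamUnchangedTFs:
    def test_unchanged_tf_with_misregulated_targets_included(self):
        g = nx.DiGraph([("tf", "m1"), ("tf", "m2")])
        out = gt.upstream_unchanged_tfs(g, {"m1", "m2"}, {"tf": PROFILE_NONE})
        assert out == {"tf"}

    def test_misregulated_tf_excluded(self):
        g = nx.DiGraph([("tf", "m1")])
        out = gt.upstream_unchanged_tfs(g, {"m1"}, {"tf": PROFILE_ACTIVATOR})
        assert out == set()

    def test_tf_without_misregulated_targets_excluded(self):
        g = nx.DiGraph([("tf", "quiet")])
        out = gt.upstream_unchanged_tfs(g, set(), {"tf": PROFILE_NONE})
        assert out == set()
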