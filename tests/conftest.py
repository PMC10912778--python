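"""Shared fixtures: one default-scale benchmark run reused across tests.

The heavy artifacts (tree-ensemble inference at the 20-TF/300-target desk
scale) are session-scoped so the suite pays for them once.
"""

import warnings

import networkx as nx
import numpy as np
import pytest

import grntrace as gt

BENCH_SEED = 1
N_TREES = 100  # desk-scale ensemble size used throughout the suite


@pytest.fixture(scope="session")
def default_config():
    return gt.SimConfig(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def truth(default_config):
    return gt.simulate_grn(default_config)


@pytest.fixture(scope="session")
def expr(truth):
    return gt.simulate_expression(truth)


@pytest.fixture(scope="session")
def inferred_network(truth, expr):
    edges = gt.rank_edges(expr, truth.tf_ids, n_trees=N_TREES, seed=BENCH_SEED)
    edges = gt.assign_edge_signs(expr, edges)
    net = gt.select_top_k(edges, k=10)
    net.candidate_edges = edges  # full ranking, for recovery metrics
    return net


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free generator run plus its inferred network."""
    cfg = gt.SimConfig(seed=BENCH_SEED, noise_sd=0.0)
    tr = gt.simulate_grn(cfg)
    ex = gt.simulate_expression(tr)
    edges = gt.rank_edges(ex, tr.tf_ids, n_trees=N_TREES, seed=BENCH_SEED)
    edges = gt.assign_edge_signs(ex, edges)
    net = gt.select_top_k(edges, k=10)
    return cfg, tr, ex, net


@pytest.fixture(scope="session")
def dge_trio(expr):
    d_ko = gt.timecourse_dge(expr, ("WT", "dek1"))
    d_oe = gt.timecourse_dge(expr, ("WT", "oex1"))
    d_ko_oe = gt.timecourse_dge(expr, ("oex1", "dek1"))
    return d_ko, d_oe, d_ko_oe


@pytest.fixture(scope="session")
def profiles(dge_trio):
    return gt.classify_profiles(*dge_trio)


@pytest.fixture(scope="session")
def proteome(truth):
    return gt.simulate_proteome(truth)


@pytest.fixture(scope="session")
def cleavage_table(truth, proteome):
    sequences, sites = proteome
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = gt.protein_profiles(sites, sequences)
        table["slc"] = gt.slc_categories(table, seed=BENCH_SEED)
        clusters = gt.cluster_cleavage_patterns(table, seed=BENCH_SEED)
    return table.join(clusters)


@pytest.fixture(scope="session")
def true_graph(truth):
    g = nx.DiGraph()
    g.add_nodes_from(truth.genes)
    for _, e in truth.true_edges.iterrows():
        g.add_edge(
            e["regulator"], e["target"],
            sign=int(e["sign"]), importance=float(e["weight"]),
        )
    return g


def random_digraph(rng: np.random.Generator, n_nodes: int, p: float) -> nx.DiGraph:
    """Erdos-Renyi style random digraph without self-loops."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for a in range(n_nodes):
        for b in range(n_nodes):
            if a != b and rng.random() < p:
                g.add_edge(a, b)
    return g
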