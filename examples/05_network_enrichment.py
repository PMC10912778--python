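"""NEAT: are two gene sets connected by more edges than chance predicts?

Under the null, the edges leaving set A hit target endpoints drawn
without replacement from all edge endpoints, so the A->B edge count is
hypergeometric. The worked example below has 10 edges, 4 leaving A, 5
entering B, and all 4 of A's edges land in B.
"""

import networkx as nx

import grntrace as gt
from grntrace.synth import PROFILE_NONE

g = nx.DiGraph([
    ("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2"),
    ("x1", "b1"), ("x1", "x2"), ("x2", "x3"), ("x3", "x4"),
    ("x4", "x5"), ("x5", "x1"),
])
res = gt.neat_test(g, {"a1", "a2"}, {"b1", "b2"}, alternative="greater")
print(f"worked example: n_obs={res.n_obs}, n_exp={res.n_exp}, "
      f"one-sided p={res.p:.4f} (exactly 5/210)")

# batch mode: misregulated gene sets against inferred subnetworks
cfg = gt.SimConfig(seed=1)
truth = gt.simulate_grn(cfg)
expr = gt.simulate_expression(truth)
edges = gt.assign_edge_signs(expr, gt.rank_edges(expr, truth.tf_ids, n_trees=100, seed=1))
network = gt.select_top_k(edges, k=10)
partition = gt.detect_communities(network, seed=1)

d_ko = gt.timecourse_dge(expr, ("WT", "dek1"))
d_oe = gt.timecourse_dge(expr, ("WT", "oex1"))
d_ko_oe = gt.timecourse_dge(expr, ("oex1", "dek1"))
profiles = gt.classify_profiles(d_ko, d_oe, d_ko_oe)
sets = {
    prof: set(profiles.index[profiles["profile"] == prof])
    for prof in profiles["profile"].unique() if prof != PROFILE_NONE
}
batch = gt.neat_batch(network, sets, partition, fdr=0.01)
print("\nset x subnetwork calls (+ enriched / - depleted at FDR 0.01):")
print(batch[["gene_set", "subnetwork", "n_obs", "n_exp", "q", "call"]]
      .to_string(index=False, float_format="%.3g"))
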