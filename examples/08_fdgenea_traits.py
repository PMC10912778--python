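"""FDGENEA: map a binary phenotype trait onto the regulatory network.

The trait (here 'overbudding', TRUE in the two protease-null genotypes)
is tested per gene with the shared time-course LRT; associated genes are
projected onto the network to find enriched subnetworks and isolated
subgraphs with their common upstream regulators, and every node gets
cumulative signed effect sizes (cb = sum of sign(b)*LRT downstream,
cab = sum of absolute values).
"""

import grntrace as gt

cfg = gt.SimConfig(seed=1)
truth = gt.simulate_grn(cfg)
expr = gt.simulate_expression(truth)
traits = gt.simulate_traits(cfg)
edges = gt.assign_edge_signs(expr, gt.rank_edges(expr, truth.tf_ids, n_trees=100, seed=1))
network = gt.select_top_k(edges, k=10)
partition = gt.detect_communities(network, seed=1)

assoc = gt.trait_dge(expr, traits["overbudding"], q_max=0.01)
print("direction calls:", assoc["direction"].value_counts().to_dict())

components = gt.isolate_components(network, assoc, q_max=0.01)
print(f"{len(components)} trait-associated components")
main = components[0]
print(f"largest: {len(main.nodes)} nodes, "
      f"{len(main.significant_genes)} significant genes, "
      f"{len(main.common_upstream)} common upstream regulators")
cleaved = truth.cleaved_tfs()
common = set().union(*[c.common_upstream for c in components])
print(f"planted cleaved TFs among common upstream: {len(common & cleaved)}/{len(cleaved)}")

stats = gt.node_stats(main, assoc)
top = stats.sort_values("cab_total", ascending=False).head(3)
print("\ntop nodes by total absolute downstream effect (cab_total):")
print(top[["s", "cb_first", "cab_first", "cb_total", "cab_total"]]
      .to_string(float_format="%.0f"))
# Upstream regulators accumulate the largest cab_total: they sit above
# many trait-associated genes even when not trait-associated themselves.
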