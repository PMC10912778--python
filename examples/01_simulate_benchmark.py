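"""Generate the synthetic benchmark: a signed GRN, a five-genotype time
course, a proteome with planted cleavage sites, and binary traits.

Every output is a deterministic function of the seed, and the ground truth
(planted edges, cleavage status, misregulation profiles) is kept alongside
the observable data so downstream stages can be scored.
"""

from collections import Counter

import grntrace as gt

cfg = gt.SimConfig(seed=1)
truth = gt.simulate_grn(cfg)
expr = gt.simulate_expression(truth)
sequences, sites = gt.simulate_proteome(truth)
traits = gt.simulate_traits(cfg)

print(f"network: {len(truth.true_edges)} true edges, "
      f"{len(truth.tf_ids)} TFs over {len(truth.target_ids)} targets")
print(f"cleaved TFs (N-degron routed): {sorted(truth.cleaved_tfs())}")
print("planted misregulation profiles:",
      dict(Counter(truth.planted_profile.values())))
print(f"expression: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples "
      f"({len(cfg.genotypes)} genotypes x {len(cfg.days)} days x {cfg.replicates} reps)")
print(f"proteome: {len(sequences)} proteins, {len(sites)} predicted cleavage sites")
print(f"traits: {traits.shape[1]} binary phenotype columns")
# The profile counts split roughly half/half between activator and repressor
# targets of cleaved TFs; 'none' genes are controlled by uncleaved TFs only.
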