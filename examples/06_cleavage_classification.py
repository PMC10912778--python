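"""Classify predicted cleavage sites by the N-degron fate of the fragment.

A protease cut exposes a new N-terminus (the P1' residue). Destabilizing
residues (R, K, H, F, W, Y, L, I, D, E, N, Q by default) route the
fragment to N-degron degradation; Nt-acetylation substrates and Met/Pro
leave it stable. Proteins are profiled by length-scaled class
frequencies, binned into site-abundance categories (SLC 1-5) and
clustered with a BIC-selected Gaussian mixture; NERD-rich clusters are
flagged ``nerd_like``.
"""

import warnings

import grntrace as gt

cfg = gt.SimConfig(seed=1)
truth = gt.simulate_grn(cfg)
sequences, sites = gt.simulate_proteome(truth)

site = gt.CleavageSite(sites.iloc[0]["protein"], int(sites.iloc[0]["position"]))
cls = gt.classify_nterminus(site, sequences[site.protein])
print(f"first site: {site.protein} pos {site.position} -> class {cls}")

profiles = gt.protein_profiles(sites, sequences)
profiles["slc"] = gt.slc_categories(profiles, k=5, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    clusters = gt.cluster_cleavage_patterns(profiles, seed=1)
profiles = profiles.join(clusters)

print(f"{len(profiles)} proteins, "
      f"{int(profiles['n_sites'].sum())} sites, "
      f"{clusters.attrs['n_components']} mixture components")
flagged = set(profiles.index[profiles["nerd_like"]])
cleaved = truth.cleaved_tfs()
print(f"nerd_like proteins: {len(flagged)}; "
      f"planted cleaved TFs recovered: {len(flagged & cleaved)}/{len(cleaved)}; "
      f"false flags: {len(flagged - cleaved)}")
# Exact recovery means the mixture isolates the planted NERD-site-bearing
# TFs purely from their site-class frequency profiles.
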