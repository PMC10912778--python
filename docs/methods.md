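# Methods

## Generative model of the synthetic benchmark

The generator emulates a post-translationally gated regulatory system
sampled as a factorial study: five genotypes spanning a calpain-activity
gradient (null alleles a = 0, a partial allele a = 0.5, wild type a = 1,
an overexpressor a = 2), five sampling days (3, 5, 9, 12, 14) and three
replicates — 75 samples.

**Network.** TFs occupy `layers` hierarchy levels (default 3); layer-0
TFs have no parents, every other node (deeper TFs and all target genes)
draws `edges_per_target` parents from shallower layers. Edge weights are
U(0.5, 1); signs are repressive with probability
`sign_fraction_negative` (default 0.5). `edges_per_target` defaults to 1:
with only five timepoints the regulator curve space has at most four
effective dimensions after centering, so multi-parent targets make the
marginal Pearson sign of an edge structurally ambiguous (collinear
parents' cross-covariances can flip it). One regulator per gene keeps the
planted sign identifiable from the data the sign-assignment step actually
uses; multi-parent generation is fully supported through the parameter.

**Expression.** TF mRNA is a smooth positive curve of day, identical
across genotypes — the protease acts purely post-translationally.
Layer-0 programs are random centered unit-norm day-vectors,
rejection-sampled so no two exceed |r| = 0.9: five-point curve spaces
otherwise produce duplicate regulators that no inference method can
separate, which would make the benchmark test nothing. A non-root TF's
program is the signed weighted sum of its parents' programs plus a
*private input* (regulation from outside the modeled TF set), drawn
orthogonal to the parents so the planted parent-edge correlation signs
stay exact, and scaled to half the parent signal.

A cleaved TF retains protein activity exp(−κ·a_g) in genotype g
(κ default 1); uncleaved TFs keep full activity. A target's expected
log2 expression is `baseline + Σ sign·weight·protein` over its parents.
Sampling reads this literally: a sample's TF protein derives from that
sample's *realized* mRNA, so a node's deviation from expectation
propagates downstream exactly like the mean does
(dev(v) = own noise + Σ sign·weight·m·dev(parent), in layer order). This
shared biological fluctuation is what lets inference distinguish a true
parent from a merely collinear regulator. Observation noise is Gaussian
on the log scale (`noise_sd`, default 0.05); negative-binomial counts
(gamma–Poisson, `nb_dispersion`) are available instead, in which case the
pipeline first normalizes (median-library scaling, log2(x+1)).

**Planted truth.** A target's profile is *activator-target* /
*repressor-target* when the net signed, mRNA-weighted influence of its
**direct** cleaved parents is positive / negative, else *none*. Because
TF mRNA is genotype-invariant by construction, genotype effects do not
propagate through intermediate TFs, and upstream TFs are never
misregulated themselves (their `pct_indirect` is identically zero on
generator data; the tracing code handles nonzero values, exercised with
constructed inputs). Cleaved TFs receive 2–4 planted sites whose P1′
residue is destabilizing; uncleaved proteins receive at most one
stabilizing site. Trait truth is computed exactly: a gene is responsive
to a trait when its expected expression differs between the trait's
genotype groups.

What the generator does **not** emulate: read-level count overdispersion
structure, batch effects, unmodeled confounders, regulators outside the
TF list, post-transcriptional regulation beyond the single attenuation
mechanism, or realistic protein biophysics. Passing recovery tests shows
the chain is correct and identifiable under its own assumptions, not that
real-data error rates will match.

## Network inference

GENIE3-style: each gene's profile is regressed on all regulator profiles
(never its own), importances normalized to sum to one per target. The
ensemble is the extremely-randomized-trees flavour with √p feature
subsampling and a minimum leaf size of 5 (default 1000 trees). The leaf
floor departs from the fully-grown-trees convention deliberately: at
n = 75 samples, fully grown forests spend most impurity reduction on
per-sample noise splits, diluting importance across collinear regulators;
the floor roughly doubles the measured AUPR ratio. Determinism comes from
per-gene child seeds derived from the stage seed, independent of gene
order.

Signs: Pearson r per configured column set (default: all samples, and the
WT+knockout time course); the sign is sign(r_timecourse) with fallback to
r_global below 10⁻¹²; undefined correlations (zero variance) are recorded
as 0 and flagged. Top-k selection keeps the k highest-importance inbound
edges per target (k = 10), ties broken by |r_timecourse| then regulator
id; zero-importance candidates are never kept.

## Structure, DGE, enrichment

**Louvain** runs on the weighted undirected projection (summed
importances), nodes inserted in sorted order so the partition depends
only on the seed, labels Roman numerals by size. **LRC** uses the N−1
denominator (self excluded) on whatever graph is passed; hierarchy ranks
sort by (LRC, out-degree, id) within each subnetwork.

**DGE** fits, per gene, a null model spanning intercept plus a degree-3
orthogonal polynomial of scaled day (the df = 3 smooth-trend space; with
five timepoints this is equivalent to any cubic-spline basis of the same
dimension and no extrapolation occurs) and a full model adding the group
indicator. The reported statistic is n·log(RSS₀/RSS₁); p-values use the
exact finite-sample F distribution of the same nested comparison — a
monotone transform of the LRT that is exactly calibrated under the
Gaussian model, where the χ²₁ approximation is measurably inflated at
n = 30. b is the indicator coefficient, positive when the second group of
the contrast is higher. Calibration is verified under the
model-consistent null (cubic day trend + iid noise); with arbitrary
five-point day profiles the df = 3 basis leaves lack-of-fit that makes
the test *conservative* (both RSS terms inflate equally), never
anticonservative — the generator-null check asserts the FDR side.

**NEAT** uses the directed hypergeometric null
n_obs ~ Hypergeom(D, d_B, o_A), two-sided p by doubling the smaller tail
(capped at 1), one-sided available. Batch mode defaults to counting edges
from the subnetwork into the gene set (`block_to_set`): candidate sets
are target-gene sets whose regulatory attachment runs through incoming
edges; `set_to_block` serves regulator sets. BH within each batch,
calls at q < 0.01.

## Cleavage classification

The default N-terminal class table encodes the canonical N-end-rule
fates of the P1′ residue — destabilizing {R K H F W Y L I D E N Q} →
NERD; Nt-acetylation substrates {A S T C G V} → other; {M P} →
unchanged — and is user-replaceable. Frequencies are per-class site
counts over protein length. SLC bins come from 1-D k-means (k = 5) on
log(freq + ε), ε half the smallest nonzero frequency, labels ordered by
centroid. Pattern clustering standardizes the class-frequency features,
projects on up to 10 principal components and selects a full-covariance
Gaussian mixture (1–9 components) by BIC (reg_covar 10⁻⁶, 10
initializations). The SLC one-hot block is available as a feature option
but off by default: the discrete axes violate the Gaussian assumption and
in practice blur the continuous pattern space. A cluster is `nerd_like`
when its mean NERD-site frequency exceeds the global mean — a stated
proxy for "NERD-type cleavage pattern".

## Tracing and FDGENEA

Regulons are breadth-first along reversed edges, a TF counted once at its
minimal order, self excluded, cumulative to order 3. Control fractions
are simple fractions over the order-3 set; empty regulons are flagged
undefined. The dependency analysis (linear slope, Kendall τ, Pearson r)
and the status cross-table run on whatever network they are given; at
desk scale (20 TFs, top-10 selection) an *inferred* network's order-3
regulons saturate — nearly every TF is upstream of every gene — so the
benchmark exercises these two analyses on the planted topology, where
regulon composition varies. The final target filter keeps edges whose
source is `nerd_like` and whose target is misregulated (profile ≠ none at
q < 0.1); direct targets are the kept sources, indirect targets the kept
targets.

FDGENEA tests each usable (non-constant) binary trait with the shared
LRT, significance q < 0.01. Components are weakly connected subgraphs of
the significant genes plus their direct upstream regulators (attached
even when not significant, which can merge otherwise separate groups —
accepted, as it reflects shared control); common upstream regulators are
nodes with ≥ 2 significant targets in the component. Node effects use
s = sign(b)·LRT (0 when not significant) — the signed summand is what
makes the cb/cab distinction informative — with first-order and
total-downstream scopes inside the component. The permutation null
shuffles trait values across *samples*, severing the genotype linkage;
shuffling at the genotype level would often produce partially
calpain-aligned groupings in a five-genotype design and is not a null.

## Problem sizes and determinism

The benchmark default is 20 TFs over 300 targets; tests and the
acceptance script run the inference ensemble at 100 trees (200 for the
single-regulator dominance check), sizes at which every recovery
property holds with wide margin. The pipeline fans one global seed out to
per-stage child seeds (stage-name CRC mixed into a SeedSequence), so any
stage can be rerun in isolation and reproduce the full run; manifests
record output hashes per stage. Known limitations: desk-scale defaults
are far below genome scale (35k genes), the Gaussian stand-in ignores
count-level mean–variance structure, and the `nerd_like` flag depends on
the mixture granularity selected by BIC rather than a calibrated error
rate.
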