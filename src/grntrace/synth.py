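"""Ground-truth synthetic benchmark generator.

Emulates the study design the downstream pipeline was built for: a layered
signed GRN of TFs over target genes, a multi-genotype developmental time
course in which calpain activity post-translationally attenuates cleaved
TFs, a proteome with planted cleavage sites, and genotype-linked binary
traits. All outputs are a deterministic function of ``SimConfig.seed``.

Generative model
----------------
TF mRNA is a smooth positive curve of day, identical across genotypes
(control is purely post-translational). A cleaved TF's *protein* activity
in genotype ``g`` is its mRNA scaled by ``exp(-kappa * a_g)``; uncleaved
TFs keep full activity. A target gene's expected log expression is

    baseline + sum_j sign_j * weight_j * protein_j(day, g)

over its direct TF parents. Observations add Gaussian noise on the log
scale, or negative-binomial counts when a dispersion is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .datasets import ExpressionDataset, make_sample_sheet

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Destabilizing neo-N-terminal residues routed to N-degron degradation.
NERD_RESIDUES = "RKHFWYLIDENQ"
#: Residues yielding a stable (acetylated or unchanged) neo-N-terminus.
STABLE_RESIDUES = "ASTCGVMP"

PROFILE_ACTIVATOR = "activator-target"
PROFILE_REPRESSOR = "repressor-target"
PROFILE_NONE = "none"

_WINDOW_FLANK = 10  # residues on each side of the scissile bond


@dataclass
class GroundTruth:
    """Planted truth for one simulated study.

    ``true_edges`` is the signed regulator->target graph;
    ``tf_cleavage_status`` marks TFs routed to N-degron degradation after
    calpain cleavage; ``planted_profile`` records the noise-free mutant
    misregulation class of every gene; ``trait_truth`` lists genes whose
    expected expression separates each trait's genotype groups.
    """

    config: SimConfig
    true_edges: pd.DataFrame  # regulator, target, weight, sign
    tf_ids: List[str]
    target_ids: List[str]
    tf_layer: Dict[str, int]
    tf_cleavage_status: Dict[str, bool]
    planted_profile: Dict[str, str]
    trait_truth: Dict[str, Set[str]] = field(default_factory=dict)
    tf_mrna: pd.DataFrame = None  # TFs x days, genotype-invariant curves

    @property
    def genes(self) -> List[str]:
        return self.tf_ids + self.target_ids

    def cleaved_tfs(self) -> Set[str]:
        return {g for g, c in self.tf_cleavage_status.items() if c}

    def parents_of(self, gene: str) -> pd.DataFrame:
        e = self.true_edges
        return e[e["target"] == gene]

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "true_edges": self.true_edges.to_dict(orient="records"),
            "tf_ids": self.tf_ids,
            "target_ids": self.target_ids,
            "tf_layer": self.tf_layer,
            "tf_cleavage_status": self.tf_cleavage_status,
            "planted_profile": self.planted_profile,
            "trait_truth": {t: sorted(s) for t, s in self.trait_truth.items()},
            "tf_mrna": self.tf_mrna.to_dict(orient="index"),
        }


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _curve_shape(rng: np.random.Generator, n_days: int) -> np.ndarray:
    """Random centered, unit-norm expression program over the day grid."""
    raw = rng.normal(size=n_days)
    raw = raw - raw.mean()
    norm = np.linalg.norm(raw)
    if norm < 1e-12:
        raw = np.linspace(-1.0, 1.0, n_days)
        norm = np.linalg.norm(raw)
    return raw / norm


def _smooth_curve(
    rng: np.random.Generator,
    u: np.ndarray,
    existing: list = None,
    max_abs_r: float = 0.9,
    max_tries: int = 100,
) -> np.ndarray:
    """Random positive curve over the day grid, rejection-sampled to stay
    distinguishable (pairwise |r| <= ``max_abs_r``) from ``existing``
    curves — with five timepoints, undistinguishable duplicate regulators
    would otherwise be common and no inference method could separate them."""
    existing = existing or []
    best, best_r = None, np.inf
    for _ in range(max_tries):
        shape = _curve_shape(rng, len(u))
        worst = max(
            (abs(float(np.dot(shape, e))) for e in existing), default=0.0
        )
        if worst < best_r:
            best, best_r = shape, worst
        if worst <= max_abs_r:
            break
    shape = best
    lo = rng.uniform(1.5, 2.5)
    span = rng.uniform(1.0, 3.0)
    rng_range = shape.max() - shape.min()
    return lo + span * (shape - shape.min()) / rng_range


def _rescale(raw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = rng.uniform(1.5, 2.5)
    span = rng.uniform(1.0, 3.0)
    rng_range = raw.max() - raw.min()
    if rng_range < 1e-12:
        return np.full_like(raw, lo)
    return lo + span * (raw - raw.min()) / rng_range


def simulate_grn(config: SimConfig) -> GroundTruth:
    """Build the layered signed ground-truth network.

    Layer-0 TFs have no parents; deeper TFs and all target genes draw
    ``edges_per_target`` parents from strictly shallower layers (targets
    may use any TF). Edge signs are repressive with probability
    ``sign_fraction_negative``; weights are U(0.5, 1).
    """
    rng = _rng(config, 0)
    n_tf, n_targets = config.n_tf, config.n_targets
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tf)]
    target_ids = [f"G{i + 1:04d}" for i in range(n_targets)]

    # assign TFs to layers as evenly as possible, layer 0 first
    layers = min(config.layers, n_tf)
    tf_layer: Dict[str, int] = {}
    for i, tf in enumerate(tf_ids):
        tf_layer[tf] = i % layers
    layer_members: Dict[int, List[str]] = {
        l: [tf for tf in tf_ids if tf_layer[tf] == l] for l in range(layers)
    }

    edges = []

    def draw_parents(pool: List[str], k: int) -> List[str]:
        if k > len(pool):
            raise ValueError(
                f"insufficient regulators: need {k}, have {len(pool)}"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    for l in range(1, layers):
        pool = [tf for tf in tf_ids if tf_layer[tf] < l]
        for tf in layer_members[l]:
            for parent in draw_parents(pool, config.edges_per_target):
                edges.append((parent, tf))
    for tgt in target_ids:
        for parent in draw_parents(tf_ids, config.edges_per_target):
            edges.append((parent, tgt))

    weights = rng.uniform(0.5, 1.0, size=len(edges))
    signs = np.where(
        rng.random(len(edges)) < config.sign_fraction_negative, -1, 1
    )
    edge_df = pd.DataFrame(
        {
            "regulator": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "weight": weights,
            "sign": signs.astype(int),
        }
    )

    # cleavage status: a fixed fraction of TFs is routed to degradation
    n_cleaved = int(round(config.frac_tf_cleaved * n_tf))
    cleaved_idx = rng.choice(n_tf, size=n_cleaved, replace=False)
    cleavage = {tf: False for tf in tf_ids}
    for i in cleaved_idx:
        cleavage[tf_ids[i]] = True

    # genotype-invariant TF mRNA curves (layered: deeper TFs are affine
    # combinations of their parents' mRNA, so true TF->TF edges leave a
    # correlation footprint)
    u = np.asarray(config.days, dtype=float)
    u = (u - u.min()) / max(u.max() - u.min(), 1e-12)
    mrna: Dict[str, np.ndarray] = {}
    shapes: list = []

    def _register(curve: np.ndarray) -> None:
        c = curve - curve.mean()
        n = np.linalg.norm(c)
        if n > 1e-12:
            shapes.append(c / n)

    for tf in layer_members[0]:
        mrna[tf] = _smooth_curve(rng, u, existing=shapes)
        _register(mrna[tf])
    for l in range(1, layers):
        for tf in layer_members[l]:
            rows = edge_df[edge_df["target"] == tf]
            raw = np.zeros_like(u)
            basis = []
            for _, r in rows.iterrows():
                raw = raw + r["sign"] * r["weight"] * mrna[r["regulator"]]
                basis.append(mrna[r["regulator"]])
            # private regulatory input (inputs outside the modeled TF set),
            # orthogonalized against the parents so it cannot flip the
            # planted correlation sign of any parent edge
            private = _curve_shape(rng, len(u))
            basis_mat = np.column_stack(
                [np.ones_like(u)] + [b - b.mean() for b in basis]
            )
            q, _ = np.linalg.qr(basis_mat)
            private = private - q @ (q.T @ private)
            p_norm = np.linalg.norm(private)
            raw_scale = np.linalg.norm(raw - raw.mean())
            if p_norm > 1e-12 and raw_scale > 1e-12:
                private = private / p_norm * 0.5 * raw_scale
                raw = raw + private
            mrna[tf] = _rescale(raw, rng)
            _register(mrna[tf])
    tf_mrna = pd.DataFrame(
        {tf: mrna[tf] for tf in tf_ids}, index=list(config.days)
    ).T
    tf_mrna.index.name = "gene"

    # planted profiles: net signed weight of *cleaved* direct parents,
    # weighted by the parent's mean mRNA level (always positive)
    profile: Dict[str, str] = {tf: PROFILE_NONE for tf in tf_ids}
    mean_mrna = {tf: float(tf_mrna.loc[tf].mean()) for tf in tf_ids}
    for tgt in target_ids:
        rows = edge_df[edge_df["target"] == tgt]
        net = 0.0
        for _, r in rows.iterrows():
            if cleavage[r["regulator"]]:
                net += r["sign"] * r["weight"] * mean_mrna[r["regulator"]]
        if net > 1e-9:
            profile[tgt] = PROFILE_ACTIVATOR
        elif net < -1e-9:
            profile[tgt] = PROFILE_REPRESSOR
        else:
            profile[tgt] = PROFILE_NONE

    truth = GroundTruth(
        config=config,
        true_edges=edge_df,
        tf_ids=tf_ids,
        target_ids=target_ids,
        tf_layer=tf_layer,
        tf_cleavage_status=cleavage,
        planted_profile=profile,
        tf_mrna=tf_mrna,
    )
    truth.trait_truth = _trait_truth(truth)
    return truth


def expected_log_expression(truth: GroundTruth) -> Dict[str, pd.DataFrame]:
    """Noise-free expected log expression per genotype (genes x days)."""
    config = truth.config
    days = list(config.days)
    activity = config.genotype_activity
    # deterministic per-gene baselines drawn from a dedicated stream
    rng = _rng(config, 3)
    baselines = {
        g: rng.uniform(0.5, 1.5) for g in truth.genes
    }
    out: Dict[str, pd.DataFrame] = {}
    mrna = truth.tf_mrna
    for g_name, a_g in activity.items():
        mat = pd.DataFrame(0.0, index=truth.genes, columns=days)
        for tf in truth.tf_ids:
            mat.loc[tf] = mrna.loc[tf].values
        for tgt in truth.target_ids:
            rows = truth.true_edges[truth.true_edges["target"] == tgt]
            val = np.full(len(days), baselines[tgt])
            for _, r in rows.iterrows():
                m = (
                    np.exp(-config.kappa * a_g)
                    if truth.tf_cleavage_status[r["regulator"]]
                    else 1.0
                )
                val = val + r["sign"] * r["weight"] * m * mrna.loc[r["regulator"]].values
            mat.loc[tgt] = val
        out[g_name] = mat
    return out


def _trait_truth(truth: GroundTruth) -> Dict[str, Set[str]]:
    """Genes whose expected expression separates a trait's genotype groups."""
    config = truth.config
    expected = expected_log_expression(truth)
    names = [g for g, _ in config.genotypes]
    out: Dict[str, Set[str]] = {}
    for trait, true_set in config.trait_genotype_map.items():
        in_group = [g for g in names if g in true_set]
        out_group = [g for g in names if g not in true_set]
        if not in_group or not out_group:
            out[trait] = set()
            continue
        mean_in = sum(expected[g] for g in in_group) / len(in_group)
        mean_out = sum(expected[g] for g in out_group) / len(out_group)
        delta = (mean_in - mean_out).abs().mean(axis=1)
        out[trait] = set(delta.index[delta > 1e-9])
    return out


def simulate_expression(truth: GroundTruth, config: SimConfig = None) -> ExpressionDataset:
    """Sample the observed expression matrix for the full design.

    TF rows carry the genotype-invariant mRNA curves; target rows carry the
    calpain-modulated expectations. Noise is Gaussian on the log scale, or
    negative-binomial counts when ``nb_dispersion`` is set.
    """
    config = config or truth.config
    if config.genotypes != truth.config.genotypes or config.days != truth.config.days:
        raise ValueError("config design is inconsistent with the ground truth")
    for _, a in config.genotypes:
        if a < 0:
            raise ValueError("negative calpain activity")
    rng = _rng(config, 1)
    names = [g for g, _ in config.genotypes]
    sheet = make_sample_sheet(names, config.days, config.replicates)
    expected = expected_log_expression(truth)

    genes = truth.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    mat = np.empty((len(genes), len(sheet)))
    day_index = {d: i for i, d in enumerate(config.days)}
    activity = config.genotype_activity
    sample_m_cleaved = np.array(
        [np.exp(-config.kappa * activity[g]) for g in sheet["genotype"]]
    )
    for j, (sid, row) in enumerate(sheet.iterrows()):
        col = expected[row["genotype"]].iloc[:, day_index[row["day"]]]
        mat[:, j] = col.values
    if config.nb_dispersion is not None:
        mu = np.power(2.0, mat)
        # gamma-poisson mixture: var = mu + phi * mu^2
        phi = config.nb_dispersion
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        mat = rng.poisson(lam).astype(float)
    elif config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=mat.shape)
        # a sample's TF protein derives from that sample's *realized* mRNA,
        # so fluctuations propagate downstream exactly like the mean does:
        # dev(v) = own noise + sum_parents sign * weight * m * dev(parent),
        # evaluated in topological (layer) order
        dev = np.zeros_like(mat)
        is_tf = set(truth.tf_ids)
        order = sorted(
            truth.genes,
            key=lambda g: truth.tf_layer.get(g, len(truth.tf_layer) + 1),
        )
        edges_by_target: Dict[str, list] = {}
        for _, e in truth.true_edges.iterrows():
            edges_by_target.setdefault(e["target"], []).append(e)
        for gene in order:
            gi = gene_pos[gene]
            d = noise[gi].copy()
            for e in edges_by_target.get(gene, []):
                pi = gene_pos[e["regulator"]]
                m = (
                    sample_m_cleaved
                    if (
                        truth.tf_cleavage_status[e["regulator"]]
                        and gene not in is_tf
                    )
                    else 1.0
                )
                d += e["sign"] * e["weight"] * m * dev[pi]
            dev[gi] = d
        mat = mat + dev
    values = pd.DataFrame(mat, index=genes, columns=sheet.index)
    values.index.name = "gene"
    return ExpressionDataset(values, sheet)


def simulate_proteome(
    truth: GroundTruth, config: SimConfig = None
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random protein sequences with planted cleavage sites.

    Every cleaved TF receives 2-4 sites whose P1' residue (first residue of
    the C-terminal fragment) is destabilizing, so the fragment is routed to
    N-degron degradation. Uncleaved proteins receive no site or one site
    with a stabilizing P1' residue.

    Returns ``(sequences, site_table)`` where the site table has columns
    protein, position (1-based P1 index; the cut is between P1 and P1'),
    window (20-mer spanning the cut) and score.
    """
    config = config or truth.config
    lo, hi = config.protein_length_range
    if lo < 2 * _WINDOW_FLANK + 1:
        raise ValueError(
            f"protein shorter than window: min length {lo} < {2 * _WINDOW_FLANK + 1}"
        )
    rng = _rng(config, 2)
    sequences: Dict[str, str] = {}
    rows = []
    aa = np.array(list(AA_ALPHABET))
    for gene in truth.genes:
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aa, size=length)
        cleaved = truth.tf_cleavage_status.get(gene, False)
        if cleaved:
            n_sites = int(rng.integers(2, 5))
            positions = _draw_positions(rng, length, n_sites)
            for pos in positions:
                seq[pos] = rng.choice(list(NERD_RESIDUES))  # P1' residue
        else:
            n_sites = int(rng.integers(0, 2))
            positions = _draw_positions(rng, length, n_sites)
            for pos in positions:
                seq[pos] = rng.choice(list(STABLE_RESIDUES))
        seq_str = "".join(seq)
        sequences[gene] = seq_str
        for pos in positions:
            # pos is the 0-based index of P1'; P1 is pos-1 (0-based)
            p1_1based = pos
            window = seq_str[pos - _WINDOW_FLANK : pos + _WINDOW_FLANK]
            rows.append(
                (gene, p1_1based, window, float(np.round(rng.uniform(0.5, 1.0), 4)))
            )
    sites = pd.DataFrame(rows, columns=["protein", "position", "window", "score"])
    return sequences, sites


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> List[int]:
    """0-based P1' indices, spaced so full 20-mer windows fit."""
    if n == 0:
        return []
    usable = np.arange(_WINDOW_FLANK, length - _WINDOW_FLANK)
    n = min(n, len(usable))
    pos = rng.choice(usable, size=n, replace=False)
    return sorted(int(p) for p in pos)


def simulate_traits(config: SimConfig) -> pd.DataFrame:
    """Sample-level binary trait table from the genotype->trait map."""
    names = [g for g, _ in config.genotypes]
    known = set(names)
    for trait, gs in config.trait_genotype_map.items():
        unknown = set(gs) - known
        if unknown:
            raise ValueError(
                f"trait {trait!r} references unknown genotypes {sorted(unknown)}"
            )
    sheet = make_sample_sheet(names, config.days, config.replicates)
    table = pd.DataFrame(index=sheet.index)
    for trait, gs in config.trait_genotype_map.items():
        table[trait] = sheet["genotype"].isin(set(gs))
    return table
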