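"""End-to-end pipeline orchestration from a single configuration.

Stages run in order: simulate (or load) -> normalize -> GRN inference ->
network structure -> DGE/profiles -> NEAT -> cleavage classification ->
target tracing -> FDGENEA. Every stage writes its tables under one run
directory and appends a manifest entry (stage, output hashes, child seed,
runtime), so identical configs and seeds produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cleavage import cluster_cleavage_patterns, protein_profiles, slc_categories
from .config import SimConfig, stage_seed
from .datasets import ExpressionDataset
from .dge import (
    classify_profiles,
    cluster_phases,
    cumulative_misregulation,
    normalize,
    timecourse_dge,
)
from .fdgenea import (
    encode_traits,
    isolate_components,
    node_stats,
    trait_dge,
    trait_network_enrichment,
)
from .inference import assign_edge_signs, default_column_sets, rank_edges, select_top_k
from .neat import neat_batch
from .structure import detect_communities, interconnection_analysis, rank_regulators
from .synth import (
    PROFILE_NONE,
    simulate_expression,
    simulate_grn,
    simulate_proteome,
    simulate_traits,
)
from .tracing import build_regulon_table, extend_regulon, filter_protease_targets

log = logging.getLogger("grntrace")


@dataclass
class PipelineConfig:
    """One config drives the whole run.

    Exactly one of ``synthetic`` (a SimConfig) or ``paths`` (expression,
    samples, regulators, fasta, sites, traits TSV/FASTA files) must be
    set. Stage parameters default to the analysis conventions: top-10
    edges per target, misregulation FDR 0.1, trait/NEAT FDR 0.01, five
    SLC bins, ten principal components, residual threshold 4.
    """

    seed: int = 0
    outdir: str = "grntrace_run"
    synthetic: Optional[SimConfig] = None
    paths: Optional[Dict[str, str]] = None
    raw_counts: bool = False
    k: int = 10
    n_trees: int = 1000
    spline_df: int = 3
    q_profiles: float = 0.1
    q_traits: float = 0.01
    neat_fdr: float = 0.01
    slc_k: int = 5
    n_pcs: int = 10
    residual_threshold: float = 4.0
    phase_k: int = 3
    knockout: str = "dek1"
    overexpression: str = "oex1"
    reference: str = "WT"
    run_fdgenea: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError("exactly one of synthetic/paths must be set")
        for name in ("q_profiles", "q_traits", "neat_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.run_fdgenea and self.paths is not None and "traits" not in self.paths:
            raise ValueError("FDGENEA enabled but no traits table configured")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("synthetic") is not None:
            d["synthetic"] = SimConfig.from_dict(d["synthetic"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.path = outdir / "manifest.json"
        self.entries = []
        self.seed = seed

    def record(self, stage: str, outputs, child_seed: int, runtime: float) -> None:
        self.entries.append(
            {
                "stage": stage,
                "seed": child_seed,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "runtime_s": round(runtime, 3),
            }
        )
        self.path.write_text(
            json.dumps(
                {"global_seed": self.seed, "stages": self.entries}, indent=2
            )
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir, manifest)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise RuntimeError(f"stage failure: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path, manifest: _Manifest) -> Path:
    truth = None
    t0 = time.time()
    if config.synthetic is not None:
        sim = config.synthetic
        truth = simulate_grn(sim)
        expr_raw = simulate_expression(truth, sim)
        sequences, sites = simulate_proteome(truth, sim)
        traits = simulate_traits(sim)
        regulator_classes = {tf: "TF" for tf in truth.tf_ids}
        gio.write_expression(
            expr_raw, outdir / "expression.tsv", outdir / "samples.tsv"
        )
        gio.write_regulators(regulator_classes, outdir / "regulators.tsv")
        gio.write_fasta(sequences, outdir / "proteome.fasta")
        gio.write_table(sites, outdir / "cleavage_sites.tsv", index_label="row")
        gio.write_table(traits, outdir / "traits.tsv", index_label="sample")
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=1)
        )
        cfg_path = outdir / "config.yaml"
        config.to_yaml(cfg_path)
        manifest.record(
            "simulate",
            [
                outdir / f
                for f in (
                    "expression.tsv", "samples.tsv", "regulators.tsv",
                    "proteome.fasta", "cleavage_sites.tsv", "traits.tsv",
                    "ground_truth.json", "config.yaml",
                )
            ],
            sim.seed,
            time.time() - t0,
        )
        raw_counts = sim.nb_dispersion is not None
    else:
        p = config.paths
        expr_raw = gio.read_expression(p["expression"], p["samples"])
        regulator_classes = gio.read_regulators(p["regulators"])
        sequences = gio.read_fasta(p["fasta"]) if "fasta" in p else {}
        sites = gio.read_table(p["sites"]) if "sites" in p else pd.DataFrame(
            columns=["protein", "position", "window", "score"]
        )
        traits = (
            gio.read_table(p["traits"], index_col="sample")
            if "traits" in p
            else pd.DataFrame(index=expr_raw.samples.index)
        )
        raw_counts = config.raw_counts

    # normalize ------------------------------------------------------------
    t0 = time.time()
    if raw_counts:
        expr = normalize(expr_raw.values, expr_raw.samples)
    else:
        expr = expr_raw  # generator output is already log scale
    gio.write_table(expr.values, outdir / "normalized.tsv", index_label="gene")
    manifest.record("normalize", [outdir / "normalized.tsv"], config.seed, time.time() - t0)

    # GRN inference --------------------------------------------------------
    t0 = time.time()
    grn_seed = stage_seed(config.seed, "grn")
    regulators = sorted(regulator_classes)
    candidates = rank_edges(expr, regulators, n_trees=config.n_trees, seed=grn_seed)
    column_sets = default_column_sets(
        expr, timecourse_genotypes=(config.reference, config.knockout)
    )
    candidates = assign_edge_signs(expr, candidates, column_sets)
    network = select_top_k(candidates, k=config.k)
    network.regulator_classes = regulator_classes
    gio.write_table(network.edges, outdir / "edges.tsv", index_label="row")
    gio.write_graphml(network.to_networkx(), outdir / "network.graphml")
    manifest.record(
        "grn",
        [outdir / "edges.tsv", outdir / "network.graphml"],
        grn_seed,
        time.time() - t0,
    )
    log.info("network: %d edges over %d nodes", len(network.edges), len(network.nodes))

    # structure ------------------------------------------------------------
    t0 = time.time()
    struct_seed = stage_seed(config.seed, "structure")
    partition = detect_communities(network, seed=struct_seed)
    centrality = rank_regulators(network, partition)
    try:
        inter = interconnection_analysis(
            network, partition, residual_threshold=config.residual_threshold
        )
        inter_observed, inter_resid = inter.observed, inter.residuals
    except ValueError:
        log.info("interconnection analysis skipped (single subnetwork)")
        inter_observed = pd.DataFrame(columns=["positive", "negative"])
        inter_resid = inter_observed.copy()
    gio.write_table(partition.to_frame(), outdir / "partition.tsv", index_label="gene")
    gio.write_table(centrality, outdir / "centrality.tsv", index_label="gene")
    inter_frame = inter_observed.copy()
    inter_frame.columns = [f"observed_{c}" for c in inter_frame.columns]
    for c in inter_resid.columns:
        inter_frame[f"residual_{c}"] = inter_resid[c]
    gio.write_table(inter_frame.reset_index(), outdir / "interconnection.tsv")
    manifest.record(
        "structure",
        [outdir / "partition.tsv", outdir / "centrality.tsv", outdir / "interconnection.tsv"],
        struct_seed,
        time.time() - t0,
    )

    # DGE + misregulation profiles ------------------------------------------
    t0 = time.time()
    dge_seed = stage_seed(config.seed, "dge")
    ko, oe, wt = config.knockout, config.overexpression, config.reference
    contrasts = {
        "ko_wt": (wt, ko),
        "oe_wt": (wt, oe),
        "ko_oe": (oe, ko),
    }
    dge_results = {}
    dge_files = []
    for name, pair in contrasts.items():
        res = timecourse_dge(expr, pair, spline_df=config.spline_df)
        dge_results[name] = res
        path = outdir / f"dge_{pair[1]}_vs_{pair[0]}.tsv"
        gio.write_table(res, path, index_label="gene")
        dge_files.append(path)
    profiles = classify_profiles(
        dge_results["ko_wt"],
        dge_results["oe_wt"],
        dge_results["ko_oe"],
        q_max=config.q_profiles,
        knockout=ko,
        overexpression=oe,
        reference=wt,
    )
    for prof_name in profiles["profile"].unique():
        if prof_name == PROFILE_NONE:
            continue
        genes = list(profiles.index[profiles["profile"] == prof_name])
        if len(genes) >= config.phase_k:
            phases = cluster_phases(
                expr, genes, genotype=wt, k=config.phase_k, seed=dge_seed
            )
            profiles.loc[phases.index, "phase"] = phases
    gio.write_table(profiles, outdir / "profiles.tsv", index_label="gene")
    manifest.record(
        "dge", dge_files + [outdir / "profiles.tsv"], dge_seed, time.time() - t0
    )

    # NEAT ------------------------------------------------------------------
    t0 = time.time()
    profile_map = dict(profiles["profile"])
    misregulated = {g for g, pr in profile_map.items() if pr != PROFILE_NONE}
    from .tracing import upstream_unchanged_tfs

    gene_sets = {}
    for prof_name in sorted(set(profile_map.values()) - {PROFILE_NONE}):
        gene_sets[prof_name] = {
            g for g, pr in profile_map.items() if pr == prof_name
        }
    gene_sets["upstream_tfs_unchanged"] = upstream_unchanged_tfs(
        network, misregulated, profile_map
    )
    neat_frame = neat_batch(network, gene_sets, partition, fdr=config.neat_fdr)
    gio.write_table(neat_frame, outdir / "neat.tsv", index_label="row")
    manifest.record("neat", [outdir / "neat.tsv"], config.seed, time.time() - t0)

    # cleavage --------------------------------------------------------------
    t0 = time.time()
    cleave_seed = stage_seed(config.seed, "cleavage")
    cleavage_profiles = protein_profiles(sites, sequences)
    cleavage_profiles["slc"] = slc_categories(
        cleavage_profiles, k=config.slc_k, seed=cleave_seed
    )
    clusters = cluster_cleavage_patterns(
        cleavage_profiles, n_pcs=config.n_pcs, seed=cleave_seed
    )
    cleavage_profiles = cleavage_profiles.join(clusters)
    gio.write_table(cleavage_profiles, outdir / "cleavage_profiles.tsv", index_label="protein")
    manifest.record(
        "cleavage", [outdir / "cleavage_profiles.tsv"], cleave_seed, time.time() - t0
    )

    # target tracing --------------------------------------------------------
    t0 = time.time()
    nerd_like = dict(cleavage_profiles["nerd_like"])
    calls = filter_protease_targets(network, nerd_like, profile_map)
    regulon = build_regulon_table(
        network, sorted(network.nodes), nerd_like, profile_map
    )
    gio.write_table(calls.edges, outdir / "target_calls.tsv", index_label="row")
    gio.write_table(regulon, outdir / "regulons.tsv", index_label="gene")
    ext_graph, ext_stats = extend_regulon(
        sorted(misregulated), network, centrality, nerd_like
    )
    gio.write_graphml(ext_graph, outdir / "extended_regulon.graphml")
    (outdir / "target_summary.json").write_text(
        json.dumps(
            {
                "n_direct": len(calls.direct_targets),
                "n_indirect": len(calls.indirect_targets),
                "n_both": len(calls.both),
                "extended": ext_stats,
            },
            indent=1,
        )
    )
    manifest.record(
        "targets",
        [
            outdir / "target_calls.tsv", outdir / "regulons.tsv",
            outdir / "extended_regulon.graphml", outdir / "target_summary.json",
        ],
        config.seed,
        time.time() - t0,
    )

    # FDGENEA ---------------------------------------------------------------
    if config.run_fdgenea and traits.shape[1]:
        t0 = time.time()
        matrix, usable = encode_traits(
            _traits_to_map(traits, expr.samples), expr.samples
        )
        fdg_dir = outdir / "fdgenea"
        fdg_dir.mkdir(exist_ok=True)
        files = []
        for trait in matrix.columns:
            if not usable[trait]:
                log.info("trait %s skipped (constant)", trait)
                continue
            assoc = trait_dge(
                expr, matrix[trait], spline_df=config.spline_df, q_max=config.q_traits
            )
            runs = trait_network_enrichment(
                assoc, partition, network, fdr=config.neat_fdr
            )
            comps = isolate_components(network, assoc, q_max=config.q_traits)
            stats_frames = []
            for comp in comps:
                st = node_stats(
                    comp, assoc, regulators=set(regulator_classes), q_max=config.q_traits
                )
                st["component"] = comp.component_id
                stats_frames.append(st)
            a_path = fdg_dir / f"{trait}_association.tsv"
            gio.write_table(assoc, a_path, index_label="gene")
            n_path = fdg_dir / f"{trait}_neat.tsv"
            gio.write_table(runs["annotation"], n_path, index_label="subnetwork")
            files += [a_path, n_path]
            if stats_frames:
                s_path = fdg_dir / f"{trait}_components.tsv"
                gio.write_table(pd.concat(stats_frames), s_path, index_label="node")
                files.append(s_path)
        manifest.record("fdgenea", files, config.seed, time.time() - t0)

    return outdir


def _traits_to_map(traits: pd.DataFrame, samples: pd.DataFrame) -> Dict[str, set]:
    """Recover the genotype-level trait map from a sample-level table."""
    out = {}
    geno = samples["genotype"]
    for trait in traits.columns:
        col = traits[trait].astype(bool).reindex(samples.index)
        out[trait] = set(geno[col.fillna(False)])
    return out
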