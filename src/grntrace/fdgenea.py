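"""FDGENEA: factorial differential gene expression network enrichment.

Each binary phenotype trait is mapped onto the expression design through
the genotype it segregates with, tested gene-by-gene with the shared
time-course LRT (trait indicator over a smooth day trend), and the
resulting associated gene sets are projected onto the regulatory network:
NEAT enrichment per subnetwork, isolation of weakly connected subgraphs
of associated genes plus their direct upstream regulators, and per-node
cumulative signed effect sizes (``_cb``: sum of sign(b) * LRT over
downstream genes; ``_cab``: sum of absolute values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .dge import _lrt_shift, bh_adjust
from .neat import neat_batch
from .tracing import _as_graph

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"


def encode_traits(
    trait_genotype_map: Mapping[str, Iterable[str]],
    samples: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Expand genotype-level trait definitions to sample-level booleans.

    Returns ``(matrix, usable)``: constant columns (all TRUE or all FALSE
    across samples) are flagged unusable because they carry no contrast.
    Unknown genotypes raise.
    """
    known = set(samples["genotype"])
    matrix = pd.DataFrame(index=samples.index)
    usable = {}
    for trait, gs in trait_genotype_map.items():
        gs = set(gs)
        unknown = gs - known
        if unknown:
            raise ValueError(
                f"trait {trait!r} references unknown genotypes {sorted(unknown)}"
            )
        col = samples["genotype"].isin(gs)
        matrix[trait] = col
        usable[trait] = 0 < col.sum() < len(col)
    return matrix, pd.Series(usable, name="usable")


def trait_dge(
    expr: ExpressionDataset,
    trait: pd.Series,
    spline_df: int = 3,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Per-gene association with one binary trait.

    Same linear model as the genotype contrasts with the trait indicator
    in place of genotype; ``b > 0`` means higher expression in the TRUE
    group. Adds a direction call (up/down/ns) at ``q < q_max``.
    """
    trait = trait.reindex(expr.sample_ids)
    if trait.isna().any():
        raise ValueError("trait column does not cover all samples")
    z = trait.to_numpy(dtype=bool)
    if z.all() or not z.any():
        raise ValueError("constant trait column (no contrast)")
    if z.sum() < 2 or (~z).sum() < 2:
        raise ValueError("need >= 2 samples per trait level")
    res = _lrt_shift(
        expr.values.to_numpy(dtype=float),
        expr.samples["day"].to_numpy(),
        z,
        spline_df,
    )
    res.index = expr.values.index
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = DIRECTION_NS
    res.loc[(res["q"] < q_max) & (res["b"] > 0), "direction"] = DIRECTION_UP
    res.loc[(res["q"] < q_max) & (res["b"] < 0), "direction"] = DIRECTION_DOWN
    res.attrs["trait"] = trait.name
    res.attrs["q_max"] = q_max
    return res[["lrt_stat", "p", "q", "b", "direction"]]


def trait_network_enrichment(
    associations: pd.DataFrame,
    partition,
    network,
    fdr: float = 0.01,
    alternative: str = "two-sided",
) -> Dict[str, pd.DataFrame]:
    """NEAT runs for the up, down and combined associated gene sets.

    BH correction is applied within each run. The merged annotation marks
    a subnetwork "+" when the up-set is enriched, "-" when the down-set
    is, and "+-" when both are.
    """
    up = set(associations.index[associations["direction"] == DIRECTION_UP])
    down = set(associations.index[associations["direction"] == DIRECTION_DOWN])
    runs: Dict[str, pd.DataFrame] = {}
    for name, members in (("up", up), ("down", down), ("combined", up | down)):
        runs[name] = neat_batch(
            network, {name: members}, partition, fdr=fdr, alternative=alternative
        )
    blocks = (
        partition.label_order
        if hasattr(partition, "label_order")
        else sorted(partition)
    )
    ann = []
    for block in blocks:
        mark = ""
        for name, sym in (("up", "+"), ("down", "-")):
            row = runs[name][runs[name]["subnetwork"] == block]
            if len(row) and row.iloc[0]["call"] == "+":
                mark += sym
        combined = runs["combined"][runs["combined"]["subnetwork"] == block]
        ann.append(
            {
                "subnetwork": block,
                "annotation": mark or "ns",
                "combined_call": combined.iloc[0]["call"] if len(combined) else "ns",
                "combined_ratio": combined.iloc[0]["ratio"] if len(combined) else np.nan,
            }
        )
    runs["annotation"] = pd.DataFrame(ann).set_index("subnetwork")
    return runs


@dataclass
class FDGENEAComponent:
    """One weakly connected subgraph of trait-associated genes plus their
    direct upstream regulators (attached even when not significant)."""

    component_id: int
    nodes: Set[str]
    significant_genes: Set[str]
    attached_regulators: Set[str]
    common_upstream: Set[str] = field(default_factory=set)
    subgraph: nx.DiGraph = None


def isolate_components(
    network,
    associations: pd.DataFrame,
    q_max: float = 0.01,
) -> List[FDGENEAComponent]:
    """Trait-associated subgraphs with shared upstream regulators.

    The induced graph contains all significant genes and every direct
    predecessor of a significant gene; weakly connected components are
    returned largest-first, each listing the regulators that control at
    least two significant genes in the component.
    """
    g = _as_graph(network)
    sig = {
        gene
        for gene in associations.index[associations["q"] < q_max]
        if gene in g
    }
    if not sig:
        return []
    regulators: Set[str] = set()
    for gene in sig:
        regulators |= set(g.predecessors(gene))
    nodes = sig | regulators
    sub = g.subgraph(nodes).copy()
    comps = sorted(nx.weakly_connected_components(sub), key=len, reverse=True)
    out = []
    for i, comp in enumerate(comps):
        comp_sig = comp & sig
        comp_reg = comp - sig
        comp_graph = sub.subgraph(comp).copy()
        common = {
            node
            for node in comp
            if len(set(comp_graph.successors(node)) & comp_sig) >= 2
        }
        out.append(
            FDGENEAComponent(
                component_id=i + 1,
                nodes=set(comp),
                significant_genes=comp_sig,
                attached_regulators=comp_reg,
                common_upstream=common,
                subgraph=comp_graph,
            )
        )
    return out


def node_stats(
    component: FDGENEAComponent,
    associations: pd.DataFrame,
    regulators: Optional[Set[str]] = None,
    tfs: Optional[Set[str]] = None,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Cumulative signed effect sizes per component node.

    Node effect s = sign(b) * lrt_stat for significant nodes, else 0.
    ``cb_first``/``cab_first`` sum s (resp. |s|) over direct targets in
    the component; ``cb_total``/``cab_total`` over all reachable
    downstream nodes (focal excluded). Regulator/TF counts follow the
    same first-order vs total scopes.
    """
    g = component.subgraph
    if regulators is None:
        regulators = {n for n in g.nodes if g.out_degree(n) > 0}
    if tfs is None:
        tfs = regulators

    def effect(node: str) -> float:
        if node not in associations.index:
            return 0.0
        row = associations.loc[node]
        if row["q"] >= q_max:
            return 0.0
        return float(np.sign(row["b"]) * row["lrt_stat"])

    s = {n: effect(n) for n in g.nodes}
    rows = []
    for node in sorted(g.nodes):
        first = set(g.successors(node))
        total = nx.descendants(g, node)
        rows.append(
            {
                "node": node,
                "s": s[node],
                "cb_first": sum(s[x] for x in first),
                "cab_first": sum(abs(s[x]) for x in first),
                "cb_total": sum(s[x] for x in total),
                "cab_total": sum(abs(s[x]) for x in total),
                "n_downstream_regulators_first": len(first & regulators),
                "n_downstream_regulators_total": len(total & regulators),
                "n_downstream_tfs_first": len(first & tfs),
                "n_downstream_tfs_total": len(total & tfs),
            }
        )
    return pd.DataFrame(rows).set_index("node")
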