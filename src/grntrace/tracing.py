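"""Upstream-regulon tracing and direct/indirect protease-target calls.

Combines three layers of evidence: network topology (which TFs sit up to
three regulatory steps above a gene), cleavage classification (which TFs
carry an N-degron-creating cleavage pattern, i.e. are *direct* protease
targets), and misregulation profiles (which genes respond in the mutants,
i.e. are *indirect* targets). The final target filter keeps edges whose
source TF is nerd_like and whose target is misregulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .structure import pearson_residual_test
from .synth import PROFILE_NONE


def _as_graph(network) -> nx.DiGraph:
    return network.to_networkx() if hasattr(network, "to_networkx") else network


def upstream_regulon(
    network, gene: str, max_order: int = 3, regulators: Optional[Set[str]] = None
) -> List[Set[str]]:
    """Cumulative upstream regulator sets at orders 1..max_order.

    Breadth-first traversal along reversed edges, restricted to regulator
    nodes when ``regulators`` is given; the focal gene is excluded and a
    node is counted once at its minimal order (cycles cannot revisit).
    """
    g = _as_graph(network)
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    seen: Set[str] = set()
    frontier = {gene}
    orders: List[Set[str]] = []
    for _ in range(max_order):
        nxt = set()
        for node in frontier:
            for pred in g.predecessors(node):
                if pred == gene or pred in seen:
                    continue
                if regulators is not None and pred not in regulators:
                    continue
                nxt.add(pred)
        seen |= nxt
        orders.append(set(seen))
        frontier = nxt
        if not frontier:
            # pad remaining orders with the closure reached so far
            while len(orders) < max_order:
                orders.append(set(seen))
            break
    return orders


def regulon_control_fractions(
    regulon: Set[str],
    nerd_like: Mapping[str, bool],
    profiles: Mapping[str, str],
) -> Dict[str, float]:
    """Fractions of upstream TFs under direct / indirect protease control.

    direct = nerd_like cleavage pattern; indirect = misregulated profile;
    either = at least one of the two. Empty regulons are flagged undefined
    (NaN fractions).
    """
    if not regulon:
        return {
            "pct_direct": np.nan,
            "pct_indirect": np.nan,
            "pct_either": np.nan,
            "defined": False,
        }
    n = len(regulon)
    direct = sum(bool(nerd_like.get(tf, False)) for tf in regulon)
    indirect = sum(profiles.get(tf, PROFILE_NONE) != PROFILE_NONE for tf in regulon)
    either = sum(
        bool(nerd_like.get(tf, False))
        or profiles.get(tf, PROFILE_NONE) != PROFILE_NONE
        for tf in regulon
    )
    return {
        "pct_direct": direct / n,
        "pct_indirect": indirect / n,
        "pct_either": either / n,
        "defined": True,
    }


def build_regulon_table(
    network,
    genes: Iterable[str],
    nerd_like: Mapping[str, bool],
    profiles: Mapping[str, str],
    max_order: int = 3,
    regulators: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Per-gene regulon sizes and control fractions (order-``max_order``)."""
    g = _as_graph(network)
    rows = []
    for gene in genes:
        if gene not in g:
            continue
        orders = upstream_regulon(g, gene, max_order, regulators)
        frac = regulon_control_fractions(orders[-1], nerd_like, profiles)
        row = {"gene": gene}
        for i, o in enumerate(orders, start=1):
            row[f"order{i}_size"] = len(o)
        row.update(frac)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def misregulation_dependency(
    fractions: pd.DataFrame,
    scores: pd.Series,
    predictors: Sequence[str] = ("pct_direct", "pct_indirect", "pct_either"),
) -> pd.DataFrame:
    """Does misregulation grow with protease-controlled upstream fraction?

    Linear regression slope plus Kendall tau and Pearson r (with p-values)
    of the cumulative misregulation score on each regulon fraction, over
    genes with defined fractions. Requires >= 10 such genes.
    """
    joined = fractions.join(scores.rename("score"), how="inner")
    if "defined" in joined.columns:
        joined = joined[joined["defined"].astype(bool)]
    joined = joined.dropna(subset=["score"])
    if len(joined) < 10:
        raise ValueError("need at least 10 genes with defined fractions")
    rows = []
    y = joined["score"].to_numpy(dtype=float)
    for pred in predictors:
        x = joined[pred].to_numpy(dtype=float)
        if np.std(x) <= 0:
            rows.append(
                {
                    "predictor": pred, "slope": np.nan, "intercept": np.nan,
                    "pearson_r": np.nan, "pearson_p": np.nan,
                    "kendall_tau": np.nan, "kendall_p": np.nan,
                    "n": len(x), "flagged": True,
                }
            )
            continue
        lr = sstats.linregress(x, y)
        tau = sstats.kendalltau(x, y)
        rows.append(
            {
                "predictor": pred,
                "slope": lr.slope,
                "intercept": lr.intercept,
                "pearson_r": lr.rvalue,
                "pearson_p": lr.pvalue,
                "kendall_tau": tau.statistic,
                "kendall_p": tau.pvalue,
                "n": len(x),
                "flagged": False,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def crosstab_regulon_status(
    fractions: pd.DataFrame, misregulated: Mapping[str, bool]
):
    """Chi-square cross-table of binary regulon statuses vs misregulation.

    Strata are the four combinations of (any direct upstream control,
    any indirect upstream control); columns are the target's own
    misregulation status. Shares the Pearson-residual machinery with the
    inter-subnetwork analysis. Empty strata are flagged.
    """
    f = fractions[fractions.get("defined", True).astype(bool)]
    direct = f["pct_direct"] > 0
    indirect = f["pct_indirect"] > 0
    mis = pd.Series({g: bool(misregulated.get(g, False)) for g in f.index})
    strata = pd.Series(
        [
            f"direct={'y' if d else 'n'},indirect={'y' if i else 'n'}"
            for d, i in zip(direct, indirect)
        ],
        index=f.index,
    )
    table = pd.crosstab(strata, mis.rename("misregulated"))
    table = table.reindex(columns=[False, True], fill_value=0)
    table.columns = ["not_misregulated", "misregulated"]
    chi2, p, dof, expected, resid, low = pearson_residual_test(table)
    empty = [s for s in table.index if table.loc[s].sum() == 0]
    return {
        "table": table,
        "chi2": chi2,
        "p": p,
        "dof": dof,
        "expected": expected,
        "residuals": resid,
        "low_expected": low,
        "empty_strata": empty,
        "proportion_misregulated": (
            table["misregulated"] / table.sum(axis=1).replace(0, np.nan)
        ),
    }


@dataclass
class TargetCallTable:
    """Final direct/indirect protease-target calls.

    ``edges`` carries a per-edge ``keep`` flag; ``direct_targets`` are
    nerd_like TFs with at least one kept (misregulated) target;
    ``indirect_targets`` are the misregulated targets of those TFs;
    ``both`` are genes in both sets.
    """

    edges: pd.DataFrame
    direct_targets: Set[str] = field(default_factory=set)
    indirect_targets: Set[str] = field(default_factory=set)
    both: Set[str] = field(default_factory=set)

    def composition(self, partition) -> pd.DataFrame:
        """Per-subnetwork counts of kept edges and target classes."""
        labels = partition.labels if hasattr(partition, "labels") else partition
        kept = self.edges[self.edges["keep"]]
        rows = []
        for label in sorted(set(labels.values())):
            members = {g for g, l in labels.items() if l == label}
            rows.append(
                {
                    "subnetwork": label,
                    "kept_edges": int(
                        (kept["target"].isin(members)).sum()
                    ),
                    "direct": len(self.direct_targets & members),
                    "indirect": len(self.indirect_targets & members),
                }
            )
        return pd.DataFrame(rows).set_index("subnetwork")


def filter_protease_targets(
    network,
    nerd_like: Mapping[str, bool],
    profiles: Mapping[str, str],
) -> TargetCallTable:
    """Keep edges with a nerd_like source TF and a misregulated target.

    The direct-target set is the kept edges' sources (TFs whose protein is
    predicted to be cleaved and degraded); the indirect-target set is the
    kept edges' targets (genes misregulated through such a TF).
    """
    if hasattr(network, "edges") and isinstance(network.edges, pd.DataFrame):
        edges = network.edges.copy()
    else:
        g = _as_graph(network)
        edges = pd.DataFrame(
            [(a, b) for a, b in g.edges()], columns=["regulator", "target"]
        )
    if len(edges) == 0:
        return TargetCallTable(edges.assign(keep=pd.Series(dtype=bool)))
    src_ok = edges["regulator"].map(lambda r: bool(nerd_like.get(r, False)))
    tgt_ok = edges["target"].map(
        lambda t: profiles.get(t, PROFILE_NONE) != PROFILE_NONE
    )
    edges["keep"] = src_ok & tgt_ok
    kept = edges[edges["keep"]]
    direct = set(kept["regulator"])
    indirect = set(kept["target"])
    return TargetCallTable(
        edges=edges,
        direct_targets=direct,
        indirect_targets=indirect,
        both=direct & indirect,
    )


def extend_regulon(
    genes: Iterable[str],
    network,
    centrality: pd.DataFrame,
    nerd_like: Mapping[str, bool],
    max_tfs: int = 5,
    max_order: int = 3,
):
    """Attach each gene's best-ranked protease-controlled upstream TFs.

    For every input gene, up to ``max_tfs`` nerd_like TFs from its
    order-``max_order`` upstream regulon are added, choosing the highest
    local reaching centrality (ties by id). Returns the induced subgraph
    and connectivity statistics.
    """
    g = _as_graph(network)
    genes = [x for x in genes if x in g]
    lrc = centrality["local_reaching_centrality"]
    selected: Set[str] = set(genes)
    for gene in genes:
        orders = upstream_regulon(g, gene, max_order)
        candidates = [tf for tf in orders[-1] if nerd_like.get(tf, False)]
        candidates.sort(key=lambda tf: (-float(lrc.get(tf, 0.0)), tf))
        selected |= set(candidates[:max_tfs])
    sub = g.subgraph(selected).copy()
    stats = {"n_nodes": sub.number_of_nodes(), "n_edges": sub.number_of_edges()}
    if genes and sub.number_of_nodes():
        comps = list(nx.weakly_connected_components(sub))
        largest = max(comps, key=len) if comps else set()
        stats["n_components"] = len(comps)
        stats["frac_genes_in_largest_component"] = (
            len(set(genes) & largest) / len(genes)
        )
    else:
        stats["n_components"] = 0
        stats["frac_genes_in_largest_component"] = 0.0
    return sub, stats


def upstream_unchanged_tfs(
    network, misregulated: Iterable[str], profiles: Mapping[str, str]
) -> Set[str]:
    """TFs with >= 1 misregulated direct target but unchanged expression.

    These are candidate direct cleavage targets invisible to differential
    expression: their mRNA is unaltered while their protein is removed.
    """
    g = _as_graph(network)
    mis = set(misregulated)
    out = set()
    for node in g.nodes:
        if profiles.get(node, PROFILE_NONE) != PROFILE_NONE:
            continue
        if any(t in mis for t in g.successors(node)):
            out.add(node)
    return out
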