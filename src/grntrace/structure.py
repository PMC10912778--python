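"""Subnetwork partitioning, regulator hierarchy, and inter-subnetwork tests.

Communities come from Louvain modularity maximization on the weighted
undirected projection of the regulatory graph. The regulator hierarchy
within each subnetwork is ranked by local reaching centrality (LRC): the
fraction of the subnetwork a node can reach along directed edges. Signed
inter-subnetwork connection patterns are tested with a chi-square test and
Pearson residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class SubnetworkPartition:
    """Gene -> subnetwork label (Roman numerals, largest first)."""

    labels: Dict[str, str]
    modularity: float
    communities: List[frozenset] = field(default_factory=list)

    def members(self, label: str) -> frozenset:
        return frozenset(g for g, l in self.labels.items() if l == label)

    @property
    def label_order(self) -> List[str]:
        return [roman(i + 1) for i in range(len(self.communities))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["gene", "subnetwork"]
        ).set_index("gene")


def _undirected_projection(g: nx.DiGraph) -> nx.Graph:
    """Sum directed importance weights into an undirected weighted graph,
    with nodes and edges inserted in sorted order so the partition does not
    depend on input order."""
    u = nx.Graph()
    u.add_nodes_from(sorted(g.nodes))
    acc: Dict[Tuple[str, str], float] = {}
    for a, b, data in g.edges(data=True):
        key = (a, b) if a <= b else (b, a)
        acc[key] = acc.get(key, 0.0) + float(data.get("importance", 1.0))
    for (a, b), w in sorted(acc.items()):
        u.add_edge(a, b, weight=w)
    return u


def detect_communities(network, seed: int = 0) -> SubnetworkPartition:
    """Louvain partition of the undirected weighted projection.

    Deterministic under ``seed``; community labels are Roman numerals
    ordered by descending size (ties by smallest member id).
    """
    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    u = _undirected_projection(g)
    if u.number_of_edges() == 0:
        comms = [frozenset({n}) for n in sorted(u.nodes)]
        mod = 0.0
    else:
        comms = nx.community.louvain_communities(u, weight="weight", seed=int(seed))
        comms = [frozenset(c) for c in comms]
        mod = nx.community.modularity(u, comms, weight="weight")
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = {}
    for i, c in enumerate(comms):
        for gene in c:
            labels[gene] = roman(i + 1)
    return SubnetworkPartition(labels=labels, modularity=float(mod), communities=comms)


def local_reaching_centrality(network) -> pd.DataFrame:
    """LRC(v) = |{u != v reachable from v}| / (N - 1), with degrees.

    Computed on the graph as given; pass a subnetwork-induced subgraph to
    get the within-subnetwork fraction.
    """
    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    n = g.number_of_nodes()
    rows = []
    for v in sorted(g.nodes):
        reach = len(nx.descendants(g, v))
        lrc = reach / (n - 1) if n > 1 else 0.0
        rows.append((v, lrc, g.out_degree(v), g.in_degree(v)))
    return pd.DataFrame(
        rows, columns=["gene", "local_reaching_centrality", "out_degree", "in_degree"]
    ).set_index("gene")


def rank_regulators(network, partition: SubnetworkPartition) -> pd.DataFrame:
    """Hierarchy ranks within each subnetwork.

    LRC is computed on the subnetwork-induced subgraph; nodes sort by
    (LRC desc, out-degree desc, id asc) and rank 1 is the subnetwork's
    master regulator.
    """
    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    frames = []
    for label in partition.label_order:
        members = sorted(partition.members(label) & set(g.nodes))
        if not members:
            continue
        sub = g.subgraph(members)
        cent = local_reaching_centrality(sub).reset_index()
        cent["subnetwork"] = label
        cent = cent.sort_values(
            ["local_reaching_centrality", "out_degree", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        cent["hierarchy_rank"] = np.arange(1, len(cent) + 1)
        frames.append(cent.set_index("gene"))
    if not frames:
        return pd.DataFrame(
            columns=[
                "local_reaching_centrality", "out_degree", "in_degree",
                "subnetwork", "hierarchy_rank",
            ]
        )
    return pd.concat(frames)


def pearson_residual_test(table: pd.DataFrame):
    """Chi-square independence test without continuity correction, plus the
    per-cell Pearson residuals (O - E) / sqrt(E).

    Returns ``(chi2, p, dof, expected, residuals, low_expected_cells)``.
    Degenerate tables (fewer than 2 informative rows or columns) yield a
    zero statistic. Cells with expected count < 1 are flagged and reported
    with a warning rather than an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.sum() <= 0 or min(obs.shape) < 2:
        expected = obs.copy()
        resid = np.zeros_like(obs)
        return 0.0, 1.0, 0, _like(table, expected), _like(table, resid), []
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(expected > 0, (obs - expected) / np.sqrt(expected), 0.0)
    chi2 = float((resid**2).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    # rows/cols with zero totals carry no information
    informative = (row[:, 0] > 0).sum() >= 2 and (col[0] > 0).sum() >= 2
    if not informative or dof == 0:
        return 0.0, 1.0, 0, _like(table, expected), _like(table, resid), []
    p = float(stats.chi2.sf(chi2, dof))
    low = [
        tuple(idx)
        for idx in np.argwhere((expected < 1) & (expected > 0) | (expected == 0))
    ]
    if low:
        warnings.warn(
            f"{len(low)} contingency cells have expected count < 1; "
            "chi-square approximation is unreliable there",
            stacklevel=2,
        )
    return chi2, p, dof, _like(table, expected), _like(table, resid), low


def _like(table, arr):
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(arr, index=table.index, columns=table.columns)
    return arr


@dataclass
class InterconnectionResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame
    chi2: float
    p: float
    dof: int
    enriched: pd.DataFrame
    low_expected: list


def interconnection_analysis(
    network,
    partition: SubnetworkPartition,
    residual_threshold: float = 4.0,
) -> InterconnectionResult:
    """Test whether signed inter-subnetwork edges deviate from independence.

    Counts directed edges between distinct subnetworks in a
    (source->target pair) x (sign) table, runs the chi-square test and
    reports cells with Pearson residual above ``residual_threshold`` as
    enriched connections (rendered ``A -> B`` for activating, ``A -| B``
    for repressing).
    """
    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    if len(set(partition.labels.values())) < 2:
        raise ValueError("need at least 2 subnetworks")
    counts: Dict[Tuple[str, str], List[int]] = {}
    for a, b, data in g.edges(data=True):
        la, lb = partition.labels.get(a), partition.labels.get(b)
        if la is None or lb is None or la == lb:
            continue
        key = (la, lb)
        counts.setdefault(key, [0, 0])
        if int(data.get("sign", 1)) >= 0:
            counts[key][0] += 1
        else:
            counts[key][1] += 1
    if not counts:
        empty = pd.DataFrame(columns=["positive", "negative"])
        return InterconnectionResult(
            empty, empty, empty, 0.0, 1.0, 0, pd.DataFrame(), []
        )
    idx = pd.MultiIndex.from_tuples(sorted(counts), names=["source", "target"])
    table = pd.DataFrame(
        [counts[k] for k in sorted(counts)],
        index=idx,
        columns=["positive", "negative"],
    )
    chi2, p, dof, expected, resid, low = pearson_residual_test(table)
    hits = []
    for (src, tgt) in table.index:
        for sign_col, arrow in (("positive", "->"), ("negative", "-|")):
            r = float(resid.loc[(src, tgt), sign_col])
            if r > residual_threshold:
                hits.append((src, tgt, sign_col, r, f"{src} {arrow} {tgt}"))
    enriched = pd.DataFrame(
        hits, columns=["source", "target", "sign", "residual", "relation"]
    )
    return InterconnectionResult(table, expected, resid, chi2, p, dof, enriched, low)
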