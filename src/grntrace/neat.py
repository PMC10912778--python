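"""Network enrichment analysis test (NEAT) for directed graphs.

Are there more (or fewer) directed edges from gene set A to gene set B
than expected by chance? Under the null the ``o_A`` edges leaving A hit
target endpoints drawn without replacement from the network's ``D`` edge
endpoints, of which ``d_B`` point into B, so the observed A->B edge count
is hypergeometric with mean ``o_A * d_B / D``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust


@dataclass
class NEATResult:
    set_a: str
    set_b: str
    n_obs: int
    o_a: int
    d_b: int
    d_total: int
    n_exp: float
    p: float
    direction: str  # "+", "-" or "0"
    q: Optional[float] = None
    call: str = "ns"
    flagged: bool = False

    @property
    def ratio(self) -> float:
        return self.n_obs / self.n_exp if self.n_exp > 0 else np.nan


def _edge_arrays(network):
    if hasattr(network, "edges") and isinstance(network.edges, pd.DataFrame):
        e = network.edges
        return e["regulator"].to_numpy(), e["target"].to_numpy()
    # networkx graph
    src, tgt = zip(*network.edges()) if network.number_of_edges() else ((), ())
    return np.asarray(src, dtype=object), np.asarray(tgt, dtype=object)


def neat_test(
    network,
    set_a: Iterable[str],
    set_b: Iterable[str],
    alternative: str = "two-sided",
    name_a: str = "A",
    name_b: str = "B",
) -> NEATResult:
    """Hypergeometric test of the directed A->B edge count.

    Two-sided p doubles the smaller tail probability (capped at 1);
    ``alternative`` may also be ``"greater"`` or ``"less"``. Degenerate
    cases (A has no outgoing or B no incoming edges) return p = 1, ns.
    """
    set_a, set_b = set(set_a), set(set_b)
    src, tgt = _edge_arrays(network)
    d_total = len(src)
    if d_total < 1:
        raise ValueError("network has no edges")
    in_a = np.isin(src, list(set_a)) if set_a else np.zeros(d_total, bool)
    in_b = np.isin(tgt, list(set_b)) if set_b else np.zeros(d_total, bool)
    o_a = int(in_a.sum())
    d_b = int(in_b.sum())
    n_obs = int((in_a & in_b).sum())
    n_exp = o_a * d_b / d_total
    if o_a == 0 or d_b == 0:
        return NEATResult(
            name_a, name_b, 0, o_a, d_b, d_total, n_exp, 1.0, "0", flagged=True
        )
    rv = hypergeom(d_total, d_b, o_a)
    lower = rv.cdf(n_obs)
    upper = rv.sf(n_obs - 1)
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_obs > n_exp:
        direction = "+"
    elif n_obs < n_exp:
        direction = "-"
    else:
        direction = "0"
    return NEATResult(
        name_a, name_b, n_obs, o_a, d_b, d_total, n_exp, float(p), direction
    )


def neat_batch(
    network,
    gene_sets: Mapping[str, Iterable[str]],
    partition,
    fdr: float = 0.01,
    alternative: str = "two-sided",
    orientation: str = "block_to_set",
) -> pd.DataFrame:
    """All gene set x subnetwork tests with BH correction across the batch.

    ``partition`` is a SubnetworkPartition (or mapping label -> member
    set). By default edges are counted from the subnetwork into the gene
    set (``block_to_set``): candidate sets are target-gene sets, so their
    regulatory attachment to a subnetwork runs through the subnetwork's
    outgoing edges; use ``set_to_block`` for regulator sets. Calls are
    "+" (enriched) or "-" (depleted) at q < ``fdr``, otherwise "ns". The
    frame carries the observed/expected ratio for heatmap export.
    """
    if hasattr(partition, "label_order"):
        blocks = {l: partition.members(l) for l in partition.label_order}
    else:
        blocks = {l: set(m) for l, m in partition.items()}
    if not gene_sets or not blocks:
        raise ValueError("need at least one gene set and one subnetwork")
    if orientation not in ("block_to_set", "set_to_block"):
        raise ValueError(f"unknown orientation {orientation!r}")
    results = []
    keys = []
    for set_name, members in gene_sets.items():
        members = set(members)
        for block_name, block in blocks.items():
            if orientation == "block_to_set":
                r = neat_test(
                    network, block, members, alternative=alternative,
                    name_a=block_name, name_b=set_name,
                )
            else:
                r = neat_test(
                    network, members, block, alternative=alternative,
                    name_a=set_name, name_b=block_name,
                )
            if not members:
                r.flagged = True
            results.append(r)
            keys.append((set_name, block_name))
    frame = pd.DataFrame([asdict(r) for r in results])
    frame.insert(0, "gene_set", [k[0] for k in keys])
    frame.insert(1, "subnetwork", [k[1] for k in keys])
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame["ratio"] = [r.ratio for r in results]
    sig = (frame["q"] < fdr) & ~frame["flagged"]
    frame["call"] = "ns"
    frame.loc[sig & (frame["direction"] == "+"), "call"] = "+"
    frame.loc[sig & (frame["direction"] == "-"), "call"] = "-"
    return frame


def ratio_matrix(batch: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected ratio pivot (gene sets x subnetworks)."""
    return batch.pivot(index="gene_set", columns="subnetwork", values="ratio")
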