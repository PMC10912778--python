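"""N-degron classification of predicted protease cleavage sites.

A protease cut between P1 and P1' exposes a neo-N-terminus starting at
P1'. Destabilizing P1' residues route the C-terminal fragment to N-degron
(N-end rule) degradation; Nt-acetylation substrates follow a separate
route; Met/Pro leave the fragment effectively unchanged. Proteins are then
profiled by length-scaled site-class frequencies, binned into site
abundance level categories (SLC) by 1-D k-means, and clustered on PCA
scores with a BIC-selected Gaussian mixture; clusters whose mean N-degron
site frequency exceeds the global mean are flagged ``nerd_like``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

CLASS_NERD = "NERD"
CLASS_OTHER = "other"
CLASS_UNCHANGED = "unchanged"

_ALL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class NTermClassTable:
    """Disjoint residue classes for the P1' (neo-N-terminal) residue.

    The default encodes the canonical N-end-rule fates: primary, secondary
    and tertiary destabilizing residues -> NERD; Nt-acetylation substrates
    -> other; Met and Pro -> unchanged. Fully user-replaceable.
    """

    classes: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            CLASS_NERD: frozenset("RKHFWYLIDENQ"),
            CLASS_OTHER: frozenset("ASTCGV"),
            CLASS_UNCHANGED: frozenset("MP"),
        }
    )

    def __post_init__(self) -> None:
        seen = set()
        for name, residues in self.classes.items():
            overlap = seen & set(residues)
            if overlap:
                raise ValueError(f"residues {sorted(overlap)} in multiple classes")
            seen |= set(residues)
        if seen != _ALL_AA:
            missing = _ALL_AA - seen
            raise ValueError(f"classes must cover all residues; missing {sorted(missing)}")

    def class_of(self, residue: str) -> str:
        for name, residues in self.classes.items():
            if residue in residues:
                return name
        raise KeyError(residue)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.classes)


DEFAULT_CLASS_TABLE = NTermClassTable()


@dataclass(frozen=True)
class CleavageSite:
    """One predicted cut: ``position`` is the 1-based P1 residue index;
    the scissile bond lies between P1 and P1'."""

    protein: str
    position: int
    window: str = ""
    score: float = 0.0

    def validate(self, sequence: str) -> None:
        if not 1 <= self.position < len(sequence):
            raise ValueError(
                f"site position {self.position} invalid for protein "
                f"{self.protein!r} of length {len(sequence)}"
            )
        if self.window and self.window not in sequence:
            raise ValueError(
                f"window {self.window!r} inconsistent with sequence of "
                f"{self.protein!r}"
            )


def classify_nterminus(
    site: CleavageSite,
    sequence: str,
    table: NTermClassTable = DEFAULT_CLASS_TABLE,
) -> str:
    """Class of the neo-N-terminal residue created by the cut.

    A cut after the final residue releases no fragment and is classified
    ``unchanged``. Pure function of (sequence, position, table).
    """
    if site.position == len(sequence):
        warnings.warn(
            f"cut at final residue of {site.protein!r}; no neo-N-terminus",
            stacklevel=2,
        )
        return CLASS_UNCHANGED
    site.validate(sequence)
    p1_prime = sequence[site.position]  # 0-based index == 1-based P1' - 1
    return table.class_of(p1_prime)


def protein_profiles(
    sites: pd.DataFrame,
    sequences: Mapping[str, str],
    table: NTermClassTable = DEFAULT_CLASS_TABLE,
) -> pd.DataFrame:
    """Per-protein site counts and length-scaled class frequencies.

    Every protein in ``sequences`` gets a row; proteins without sites get
    all-zero frequencies. Duplicate (protein, position) rows are dropped
    with a warning. Class frequencies partition ``freq_total`` exactly.
    """
    unknown = set(sites["protein"]) - set(sequences)
    if unknown:
        raise ValueError(f"sites reference unknown proteins: {sorted(unknown)[:5]}")
    if sites.duplicated(["protein", "position"]).any():
        n_dup = int(sites.duplicated(["protein", "position"]).sum())
        warnings.warn(f"dropping {n_dup} duplicate cleavage sites", stacklevel=2)
        sites = sites.drop_duplicates(["protein", "position"])
    counts: Dict[str, Dict[str, int]] = {
        p: {c: 0 for c in table.names} for p in sequences
    }
    for _, row in sites.iterrows():
        site = CleavageSite(
            row["protein"], int(row["position"]),
            str(row.get("window", "") or ""), float(row.get("score", 0.0)),
        )
        cls = classify_nterminus(site, sequences[site.protein], table)
        counts[site.protein][cls] += 1
    rows = []
    for protein in sorted(sequences):
        length = len(sequences[protein])
        c = counts[protein]
        n_sites = sum(c.values())
        row = {"protein": protein, "length": length, "n_sites": n_sites}
        for cls in table.names:
            row[f"n_{cls}"] = c[cls]
            row[f"freq_{cls}"] = c[cls] / length
        row["freq_total"] = n_sites / length
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein")


def slc_categories(
    profiles: pd.DataFrame, k: int = 5, seed: int = 0
) -> pd.Series:
    """Site abundance level categories by 1-D k-means.

    Clusters log-transformed overall site frequencies (offset: half the
    smallest nonzero frequency) and orders labels by ascending centroid,
    so SLC 1 holds the fewest sites. Fewer distinct values than ``k``
    reduce ``k`` with a warning.
    """
    freq = profiles["freq_total"].to_numpy(dtype=float)
    nonzero = freq[freq > 0]
    eps = nonzero.min() / 2 if len(nonzero) else 1.0
    x = np.log(freq + eps).reshape(-1, 1)
    n_distinct = len(np.unique(x.round(12)))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"reducing SLC categories from {k} to {k_eff} (few distinct values)",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=int(seed))
    raw = km.fit_predict(x)
    order = np.argsort(km.cluster_centers_[:, 0])
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    return pd.Series(
        [relabel[int(l)] for l in raw], index=profiles.index, name="slc"
    )


def cluster_cleavage_patterns(
    profiles: pd.DataFrame,
    n_pcs: int = 10,
    seed: int = 0,
    max_components: int = 9,
    table: NTermClassTable = DEFAULT_CLASS_TABLE,
    include_slc: bool = False,
) -> pd.DataFrame:
    """Model-based clustering of cleavage-pattern profiles.

    Features are the per-class length-scaled frequencies (optionally plus
    a one-hot SLC encoding; off by default because the discrete axes
    violate the Gaussian mixture assumption and blur the continuous
    pattern space), standardized and projected on the first ``n_pcs``
    principal components; a full-covariance Gaussian mixture with
    1..``max_components`` components is selected by BIC. A cluster is
    ``nerd_like`` when its mean N-degron site frequency exceeds the
    global mean.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 proteins")
    feats = [f"freq_{c}" for c in table.names] + ["freq_total"]
    X = profiles[feats].to_numpy(dtype=float)
    if include_slc and "slc" in profiles.columns:
        onehot = pd.get_dummies(profiles["slc"], prefix="slc").to_numpy(dtype=float)
        X = np.column_stack([X, onehot])
    keep = X.std(axis=0) > 0
    X = X[:, keep] if keep.any() else X[:, :1]
    Xs = StandardScaler().fit_transform(X)
    n_comp_max = min(n_pcs, Xs.shape[1], Xs.shape[0])
    if n_comp_max < n_pcs:
        warnings.warn(
            f"truncating PCA to {n_comp_max} components (feature rank)",
            stacklevel=2,
        )
    scores = PCA(n_components=n_comp_max, random_state=int(seed)).fit_transform(Xs)
    best = None
    for n_comp in range(1, min(max_components, len(profiles)) + 1):
        gm = GaussianMixture(
            n_components=n_comp,
            covariance_type="full",
            random_state=int(seed),
            reg_covar=1e-6,
            n_init=10,
        ).fit(scores)
        bic = gm.bic(scores)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]
    labels = gm.predict(scores)
    out = pd.DataFrame({"pattern_cluster": labels}, index=profiles.index)
    global_mean = profiles[f"freq_{CLASS_NERD}"].mean()
    cluster_mean = profiles[f"freq_{CLASS_NERD}"].groupby(out["pattern_cluster"]).mean()
    nerd_like_clusters = set(cluster_mean.index[cluster_mean > global_mean])
    out["nerd_like"] = out["pattern_cluster"].isin(nerd_like_clusters)
    out.attrs["n_components"] = gm.n_components
    return out
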