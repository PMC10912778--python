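"""Time-course differential expression and misregulation profiles.

The model is a Gaussian linear model on log-scale expression: the null
fits a smooth degree-3 time trend, the full model adds a group indicator
(genotype or trait). The reported effect statistic is the Gaussian
likelihood ratio ``n * log(RSS0 / RSS1)``; p-values come from the exact
finite-sample F distribution of the same comparison (a monotone transform
of the LRT that is exactly calibrated under the model), and q-values from
Benjamini-Hochberg. Misregulation profiles classify genes as targets of
protease-destabilized activators or repressors from the sign pattern of
three pairwise genotype contrasts.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset, zscore_rows
from .synth import PROFILE_ACTIVATOR, PROFILE_NONE, PROFILE_REPRESSOR

_RSS_FLOOR = 1e-24


def normalize(raw: pd.DataFrame, samples: pd.DataFrame) -> ExpressionDataset:
    """Library-size scaling to the median depth followed by log2(x + 1).

    A variance-stabilizing stand-in: the median reference makes doubling a
    single library's depth leave its normalized values unchanged. All-zero
    samples are rejected.
    """
    if (raw < 0).any().any():
        raise ValueError("expression values must be nonnegative")
    lib = raw.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero samples: {bad}")
    scaled = raw * (lib.median() / lib)
    return ExpressionDataset(np.log2(scaled + 1.0), samples)


def time_basis(days: np.ndarray, df: int = 3) -> np.ndarray:
    """Orthonormal smooth-trend design (intercept + degree-``df``
    polynomial of scaled day)."""
    u = np.asarray(days, dtype=float)
    span = u.max() - u.min()
    u = (u - u.min()) / span if span > 0 else np.zeros_like(u)
    cols = [np.ones_like(u)] + [u ** (j + 1) for j in range(df)]
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def _lrt_shift(
    values: np.ndarray, days: np.ndarray, z: np.ndarray, spline_df: int = 3
) -> pd.DataFrame:
    """Vectorized group-shift LRT for all genes sharing one design.

    ``values`` is genes x samples, ``z`` the 0/1 group indicator
    (b > 0 means higher in the z = 1 group).
    """
    n = values.shape[1]
    q0 = time_basis(days, spline_df)
    x1 = np.column_stack([q0, z.astype(float)])
    q1, _ = np.linalg.qr(x1)
    p1 = np.linalg.matrix_rank(x1)
    if n <= p1:
        raise ValueError("not enough samples for the design")
    y = values
    r0 = y - (y @ q0) @ q0.T
    r1 = y - (y @ q1) @ q1.T
    rss0 = (r0**2).sum(axis=1)
    rss1 = (r1**2).sum(axis=1)
    beta, *_ = np.linalg.lstsq(x1, y.T, rcond=None)
    b = beta[-1]

    const = rss0 <= _RSS_FLOOR  # gene constant under the null fit
    lrt = np.zeros(len(rss0))
    ok = ~const
    lrt[ok] = n * np.log(rss0[ok] / np.maximum(rss1[ok], _RSS_FLOOR * rss0[ok]))
    lrt = np.maximum(lrt, 0.0)

    dof2 = n - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            rss1 > _RSS_FLOOR * np.maximum(rss0, 1.0),
            (rss0 - rss1) / (rss1 / dof2),
            np.inf,
        )
    f = np.where(const, 0.0, np.maximum(f, 0.0))
    p = stats.f.sf(f, 1, dof2)
    p = np.where(const, 1.0, p)
    b = np.where(const & (np.abs(b) < 1e-12), 0.0, b)
    return pd.DataFrame({"lrt_stat": lrt, "p": p, "b": b})


def timecourse_dge(
    expr: ExpressionDataset,
    contrast: Tuple[str, str],
    spline_df: int = 3,
) -> pd.DataFrame:
    """Pairwise genotype contrast over the shared time course.

    Returns a per-gene frame (lrt_stat, p, q, b) with ``b > 0`` meaning
    higher expression in the *second* genotype of ``contrast``. The frame
    carries ``attrs['contrast']``.
    """
    g_a, g_b = contrast
    meta = expr.samples
    keep = meta[meta["genotype"].isin([g_a, g_b])]
    for g in (g_a, g_b):
        sub = keep[keep["genotype"] == g]
        if sub["day"].nunique() < 2:
            raise ValueError(f"genotype {g!r} present at fewer than 2 timepoints")
        if sub.groupby("day").size().min() < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 replicates")
    cols = list(keep.index)
    values = expr.values[cols].to_numpy(dtype=float)
    z = (keep["genotype"] == g_b).to_numpy()
    res = _lrt_shift(values, keep["day"].to_numpy(), z, spline_df)
    res.index = expr.values.index
    res["q"] = bh_adjust(res["p"].to_numpy())
    res = res[["lrt_stat", "p", "q", "b"]]
    res.attrs["contrast"] = (g_a, g_b)
    return res


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _oriented_sign(res: pd.DataFrame, first: str, second: str) -> pd.Series:
    """Sign of (``first`` minus ``second``) from a contrast frame."""
    ga, gb = res.attrs["contrast"]
    if (ga, gb) == (second, first):
        return np.sign(res["b"])
    if (ga, gb) == (first, second):
        return -np.sign(res["b"])
    raise ValueError(
        f"contrast {(ga, gb)} does not compare {first!r} and {second!r}"
    )


def classify_profiles(
    dge_ko_wt: pd.DataFrame,
    dge_oe_wt: pd.DataFrame,
    dge_ko_oe: pd.DataFrame,
    q_max: float = 0.1,
    knockout: str = "dek1",
    overexpression: str = "oex1",
    reference: str = "WT",
) -> pd.DataFrame:
    """Misregulation profile from three pairwise contrasts.

    With signs oriented as (knockout rel WT, overexpressor rel WT,
    knockout rel overexpressor), the pattern (+, -, +) with all three
    contrasts significant marks an *activator target* (its upstream TF
    activates it and is destabilized by the protease); (-, +, -) marks a
    *repressor target*; anything else is ``none``. Genes missing from any
    contrast are ``none`` with ``missing`` set.
    """
    results = {
        "ko_wt": dge_ko_wt,
        "oe_wt": dge_oe_wt,
        "ko_oe": dge_ko_oe,
    }
    genes = dge_ko_wt.index.union(dge_oe_wt.index).union(dge_ko_oe.index)
    common = dge_ko_wt.index.intersection(dge_oe_wt.index).intersection(
        dge_ko_oe.index
    )
    s1 = _oriented_sign(dge_ko_wt, knockout, reference)
    s2 = _oriented_sign(dge_oe_wt, overexpression, reference)
    s3 = _oriented_sign(dge_ko_oe, knockout, overexpression)
    sig = pd.DataFrame(
        {
            "sig_ko_wt": dge_ko_wt["q"] < q_max,
            "sig_oe_wt": dge_oe_wt["q"] < q_max,
            "sig_ko_oe": dge_ko_oe["q"] < q_max,
        }
    ).reindex(common)
    all_sig = sig.all(axis=1)
    s = pd.DataFrame({"s1": s1, "s2": s2, "s3": s3}).reindex(common)
    activator = all_sig & (s["s1"] > 0) & (s["s2"] < 0) & (s["s3"] > 0)
    repressor = all_sig & (s["s1"] < 0) & (s["s2"] > 0) & (s["s3"] < 0)
    profile = pd.Series(PROFILE_NONE, index=genes, name="profile")
    profile.loc[activator.index[activator]] = PROFILE_ACTIVATOR
    profile.loc[repressor.index[repressor]] = PROFILE_REPRESSOR
    out = pd.DataFrame({"profile": profile})
    out["missing"] = ~out.index.isin(common)
    out["cumulative_effect"] = cumulative_misregulation(
        dge_ko_wt, dge_oe_wt, dge_ko_oe
    ).reindex(genes)
    for name, res in results.items():
        out[f"sig_{name}"] = res["q"].reindex(genes) < q_max
    return out


def cumulative_misregulation(*dge_results: pd.DataFrame) -> pd.Series:
    """Sum of the per-contrast LRT statistics (order-invariant)."""
    if not dge_results:
        raise ValueError("need at least one contrast")
    genes = dge_results[0].index
    for r in dge_results[1:]:
        genes = genes.union(r.index)
    total = pd.Series(0.0, index=genes, name="cumulative_effect")
    for r in dge_results:
        total = total.add(r["lrt_stat"].reindex(genes).fillna(0.0), fill_value=0.0)
    return total


def cluster_phases(
    expr: ExpressionDataset,
    genes: Sequence[str],
    genotype: str = "WT",
    k: int = 3,
    seed: int = 0,
) -> pd.Series:
    """k-means phase clusters of z-scored replicate-mean time profiles."""
    genes = [g for g in genes if g in expr.values.index]
    if not genes:
        return pd.Series(dtype=int, name="phase")
    meta = expr.samples[expr.samples["genotype"] == genotype]
    sub = expr.values.loc[genes, meta.index]
    prof = sub.T.groupby(meta["day"]).mean().T  # genes x days
    z = zscore_rows(prof.to_numpy())
    n_distinct = len(np.unique(z.round(12), axis=0))
    k_eff = min(k, n_distinct, len(genes))
    if k_eff < k:
        warnings.warn(
            f"reducing phase clusters from {k} to {k_eff} (degenerate profiles)",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=int(seed))
    labels = km.fit_predict(z)
    return pd.Series(labels, index=genes, name="phase")
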