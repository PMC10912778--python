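"""In-memory containers for expression data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("genotype", "day", "replicate")


@dataclass
class ExpressionDataset:
    """A genes x samples value matrix with per-sample metadata.

    ``values`` is log-scale after preprocessing; ``samples`` is indexed by
    sample id and carries genotype, day and replicate columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns {missing}")
        if not self.values.columns.equals(self.samples.index):
            # allow same set in different order; align
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("sample sheet does not match matrix columns")
            self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, ids) -> "ExpressionDataset":
        ids = list(ids)
        return ExpressionDataset(self.values[ids], self.samples.loc[ids])

    def samples_for(self, genotypes) -> list:
        """Sample ids whose genotype is in ``genotypes`` (day-ordered)."""
        keep = self.samples[self.samples["genotype"].isin(set(genotypes))]
        keep = keep.sort_values(["day", "genotype", "replicate"])
        return list(keep.index)

    def mean_profile(self, gene: str, genotype: str) -> pd.Series:
        """Replicate-averaged time profile of one gene in one genotype."""
        cols = self.samples[self.samples["genotype"] == genotype]
        vals = self.values.loc[gene, cols.index]
        return vals.groupby(cols["day"]).mean()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_g, n_s = self.values.shape
        return f"ExpressionDataset({n_g} genes x {n_s} samples)"


def make_sample_sheet(genotypes, days, replicates: int) -> pd.DataFrame:
    """Deterministic sample sheet for a full factorial genotype x day x
    replicate design, with ids like ``WT_d3_r1``."""
    rows = []
    for g in genotypes:
        for d in days:
            for r in range(1, replicates + 1):
                day_str = f"{d:g}"
                rows.append((f"{g}_d{day_str}_r{r}", g, float(d), r))
    sheet = pd.DataFrame(rows, columns=["sample", *SAMPLE_COLUMNS])
    return sheet.set_index("sample")


def zscore_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise z-score; constant rows map to zeros."""
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    out = np.zeros_like(mat)
    ok = sd[:, 0] > 0
    out[ok] = (mat[ok] - mu[ok]) / sd[ok]
    return out
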