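"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is TSV; graphs are GraphML (Cytoscape-compatible);
proteins are FASTA via Biopython. Writers and readers round-trip all
node/edge attributes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping, Set

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import ExpressionDataset


def write_expression(expr: ExpressionDataset, values_path, samples_path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene")
    expr.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression(values_path, samples_path) -> ExpressionDataset:
    values = read_table(values_path, index_col="gene")
    samples = read_table(samples_path, index_col="sample")
    values.columns.name = samples.index.name
    return ExpressionDataset(values, samples)


def read_table(path, index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def write_table(frame: pd.DataFrame, path, index_label=None) -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def write_gene_set(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_set(path) -> Set[str]:
    """One id per line; an empty file yields an empty set."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_regulators(classes: Mapping[str, str], path) -> None:
    frame = pd.DataFrame(
        sorted(classes.items()), columns=["gene", "class"]
    ).set_index("gene")
    write_table(frame, path, index_label="gene")


def read_regulators(path) -> Dict[str, str]:
    frame = read_table(path, index_col="gene")
    return dict(frame["class"])


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(str(path))
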