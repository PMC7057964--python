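"""Readers and writers for the pipeline's tab-delimited interchange files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix


def read_expression(
    expression_path, sample_meta_path, unit: str = "tpm"
) -> ExpressionMatrix:
    """Load a genes-as-rows expression TSV plus its sample metadata TSV."""
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta, unit=unit)


def read_traits(path) -> pd.DataFrame:
    """Colony trait TSV: colony id index, one column per trait."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_lengths(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]


def read_dnds(path) -> pd.DataFrame:
    """dN/dS TSV: gene id index, one column per species."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_candidate_lists(path) -> dict[str, list[str]]:
    """Two-column TSV ``list_name<TAB>gene_id`` -> name -> gene list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["list_name", "gene"])
    return {name: list(g) for name, g in df.groupby("list_name")["gene"]}


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    return path


def write_edge_list(graph, path) -> Path:
    """Write an undirected sample graph as a three-column edge-list TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample_a\tsample_b\tdistance\n")
        for a, b, data in graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('distance', '')}\n")
    return path
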