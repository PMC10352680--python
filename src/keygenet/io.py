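"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated.  Expression matrices travel as a gene × sample
TSV (first column the gene id) plus a two-column sample→group file;
interactomes use the STRING edge-list dialect (``protein1``, ``protein2``,
``combined_score``); drug targets use ``drug_id``/``atc_code``/``gene``.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import CentralityTable, ExpressionMatrix, InputError, KeyGeneSet


def write_expression(expr: ExpressionMatrix, matrix_path, groups_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample_id": list(expr.values.columns),
         "group": [expr.groups[s] for s in expr.values.columns]}
    ).to_csv(groups_path, sep="\t", index=False)


def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    if list(groups_df.columns) != ["sample_id", "group"]:
        raise InputError("groups file must have columns sample_id, group")
    groups = dict(zip(groups_df["sample_id"], groups_df["group"]))
    return ExpressionMatrix(values=values, groups=groups)


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(edges.columns):
        raise InputError(f"edge list must have columns {sorted(required)}")
    return edges


def write_deg_table(deg_table: pd.DataFrame, path) -> None:
    deg_table.to_csv(path, sep="\t", index_label="gene")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_drug_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_drug_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"drug_id", "atc_code", "gene"}
    if not required.issubset(table.columns):
        raise InputError(f"drug table must have columns {sorted(required)}")
    return table


def write_centrality_tables(tables: list[CentralityTable], tsv_path, params_path) -> None:
    """Long-format TSV (algorithm, gene, score, rank) + JSON parameter sidecar."""
    frames = [t.to_frame() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(tsv_path, sep="\t", index=False)
    params = {t.algorithm: t.params for t in tables}
    Path(params_path).write_text(json.dumps(params, indent=1, sort_keys=True))


def write_key_genes(key: KeyGeneSet, genes_path, provenance_path) -> None:
    Path(genes_path).write_text("\n".join(key.sorted_genes) + "\n")
    payload = {"k": key.k, "genes": key.sorted_genes, "provenance": key.provenance}
    Path(provenance_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
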