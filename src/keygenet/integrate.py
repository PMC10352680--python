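"""Centrality-consensus key-gene nomination and per-group co-expression.

The integration strategy: take each algorithm's top-k genes (k = 10 by
default) and intersect the lists across all algorithms; genes present in
every list are the key genes.  Ties at the k-th score are resolved
lexicographically by gene id (include-first) and flagged in the provenance
so the choice can be audited.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import CentralityTable, ExpressionMatrix, InputError, KeyGeneSet


def top_k(table: CentralityTable, k: int = 10) -> list[str]:
    """The k highest-scoring genes, ties at rank k broken lexicographically.

    Returns all genes when the table has at most k entries.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(table.scores) == 0:
        raise InputError("empty centrality table")
    ordered = table.scores.sort_index().sort_values(
        ascending=False, kind="mergesort"
    )
    return list(ordered.index[:k])


def _tie_at_boundary(table: CentralityTable, k: int) -> bool:
    if len(table.scores) <= k:
        return False
    ordered = table.scores.sort_index().sort_values(ascending=False, kind="mergesort")
    return bool(ordered.iloc[k - 1] == ordered.iloc[k])


def intersect_key_genes(
    tables: Sequence[CentralityTable], k: int = 10
) -> KeyGeneSet:
    """Intersect the per-algorithm top-k lists into the key-gene set.

    All tables must cover the same node set.  The provenance records each
    algorithm's ranked top-k list with scores and whether a tie crossed the
    rank-k boundary.
    """
    if not tables:
        raise InputError("at least one centrality table is required")
    node_sets = {t.nodes for t in tables}
    if len(node_sets) != 1:
        raise InputError("centrality tables cover different node sets")

    provenance: dict = {}
    genes: set | None = None
    for t in tables:
        top = top_k(t, k)
        provenance[t.algorithm] = {
            "top": top,
            "scores": {g: float(t.scores[g]) for g in top},
            "tie_at_boundary": _tie_at_boundary(t, k),
            "params": dict(t.params),
        }
        genes = set(top) if genes is None else genes & set(top)
    return KeyGeneSet(genes=frozenset(genes or set()), k=k, provenance=provenance)


def key_gene_correlation(
    expr: ExpressionMatrix, genes: KeyGeneSet | Iterable[str]
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlation of the key genes, per sample group.

    Returns one symmetric gene × gene matrix per group label.  A gene with
    zero variance within a group yields missing (NaN) correlations there,
    with a warning.
    """
    gene_list = sorted(genes.genes if isinstance(genes, KeyGeneSet) else set(genes))
    missing = [g for g in gene_list if g not in expr.values.index]
    if missing:
        raise InputError(f"key genes absent from expression matrix: {missing}")
    out: dict[str, pd.DataFrame] = {}
    for group in sorted(set(expr.groups.values())):
        samples = expr.samples(group)
        if len(samples) < 3:
            raise InputError(f"group '{group}' needs >= 3 samples for correlation")
        sub = expr.values.loc[gene_list, samples]
        flat = sub.std(axis=1, ddof=0) == 0
        if flat.any():
            warnings.warn(
                f"zero-variance gene(s) in group '{group}': "
                f"{list(sub.index[flat])}; correlations reported as missing",
                stacklevel=2,
            )
        corr = sub.T.corr(method="pearson")
        np.fill_diagonal(corr.values, np.where(flat, np.nan, 1.0))
        out[group] = corr
    return out
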