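"""Shared in-memory containers for the pipeline stages.

Tabular results (differential-expression tables, drug-target tables,
rankings) are plain :class:`pandas.DataFrame` objects with documented column
schemas; graphs are :class:`networkx.Graph`.  The thin dataclasses here wrap
only the objects that carry extra, non-tabular state (group assignments,
algorithm parameters, provenance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"


class InvalidConfigError(ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(ValueError):
    """An input object violates a stage precondition."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values with a two-level group factor.

    Parameters
    ----------
    values
        Genes as rows, samples as columns; log2 scale, all finite.
    groups
        Mapping ``sample_id -> {"control", "case"}`` covering every column.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InputError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise InputError(f"samples without group assignment: {missing[:5]}")
        bad = {g for g in self.groups.values()} - {CONTROL, CASE}
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("non-finite expression values")
        for level in (CONTROL, CASE):
            if len(self.samples(level)) < 2:
                raise InputError(
                    f"group '{level}' has fewer than 2 samples; "
                    "at least 2 are required per group"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples(group)]


@dataclass
class CentralityTable:
    """Per-node scores of one centrality algorithm.

    ``scores`` is indexed by node id in sorted order (deterministic output);
    ``params`` records the algorithm parameters verbatim, including the RNG
    seed for stochastic algorithms.
    """

    algorithm: str
    scores: pd.Series
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.sort_index()
        self.scores.name = "score"
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.algorithm}: non-finite centrality score")

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with deterministic rank (ties lexicographic)."""
        df = self.scores.rename("score").reset_index().rename(columns={"index": "gene"})
        df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        df.insert(0, "algorithm", self.algorithm)
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True)


@dataclass
class KeyGeneSet:
    """Intersection of per-algorithm top-k gene lists, with provenance."""

    genes: frozenset
    k: int
    provenance: dict = field(default_factory=dict)

    @property
    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DrugRanking:
    """Per-drug key-gene hit counts and candidate calls.

    ``table`` columns: drug_id, atc_code, n_key_genes, key_genes (comma
    joined, sorted), candidate.  Drugs hitting zero key genes are excluded.
    ``histogram`` maps n_key_genes -> number of drugs.
    """

    table: pd.DataFrame
    histogram: pd.Series
    candidate_min: int

    @property
    def candidates(self) -> list[str]:
        return sorted(self.table.loc[self.table["candidate"], "drug_id"])
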