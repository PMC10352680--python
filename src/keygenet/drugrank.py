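"""Drug–key-gene bipartite ranking for repurposing candidates.

Drugs (rows of a drug→gene target table with ATC codes) are restricted to
the nervous-system ATC branch, counted by how many key genes they target,
and flagged as repurposing candidates when they reach ``candidate_min``
key genes (default 3, i.e. drugs affecting three or four of four key genes).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .containers import DrugRanking, InputError, KeyGeneSet

DRUG_COLUMNS = ["drug_id", "atc_code", "gene"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in DRUG_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"drug table missing columns: {missing}")
    if table.duplicated(subset=["drug_id", "gene"]).any():
        raise InputError("duplicate (drug_id, gene) pairs in drug table")


def filter_nervous_system_drugs(
    table: pd.DataFrame, atc_prefix: str = "N"
) -> pd.DataFrame:
    """Rows whose ATC code starts with ``atc_prefix`` (class N = nervous system)."""
    _check_table(table)
    return table[table["atc_code"].astype(str).str.startswith(atc_prefix)].reset_index(
        drop=True
    )


def rank_drugs(
    table: pd.DataFrame,
    key_genes: KeyGeneSet | set[str] | frozenset,
    candidate_min: int = 3,
) -> DrugRanking:
    """Count key-gene targets per drug and call repurposing candidates.

    Drugs targeting no key gene are excluded.  The histogram maps the number
    of key genes hit to the number of drugs hitting exactly that many.
    """
    _check_table(table)
    keys = set(key_genes.genes if isinstance(key_genes, KeyGeneSet) else key_genes)
    if not keys:
        raise InputError("key-gene set is empty")
    hits = table[table["gene"].isin(keys)]
    rows = []
    for drug_id, sub in hits.groupby("drug_id", sort=True):
        targets = sorted(set(sub["gene"]))
        rows.append(
            {
                "drug_id": drug_id,
                "atc_code": sub["atc_code"].iloc[0],
                "n_key_genes": len(targets),
                "key_genes": ",".join(targets),
                "candidate": len(targets) >= candidate_min,
            }
        )
    ranking = pd.DataFrame(
        rows, columns=["drug_id", "atc_code", "n_key_genes", "key_genes", "candidate"]
    )
    ranking = ranking.sort_values(
        ["n_key_genes", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    hist = (
        ranking["n_key_genes"].value_counts().sort_index()
        if len(ranking)
        else pd.Series(dtype=int)
    )
    hist.index.name = "n_key_genes"
    hist.name = "n_drugs"
    return DrugRanking(table=ranking, histogram=hist, candidate_min=candidate_min)


def export_bipartite(ranking: DrugRanking) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list and node attributes of the drug–key-gene bipartite network.

    Returns
    -------
    (edges, nodes)
        ``edges`` has columns ``drug_id``/``gene``; ``nodes`` has columns
        ``node``, ``kind`` (drug/gene) and ``candidate`` (drugs only).
    """
    if len(ranking.table) == 0:
        raise InputError("empty drug ranking")
    edges = []
    for _, row in ranking.table.iterrows():
        for g in row["key_genes"].split(","):
            edges.append({"drug_id": row["drug_id"], "gene": g})
    edges_df = pd.DataFrame(edges).sort_values(["drug_id", "gene"]).reset_index(drop=True)
    drug_nodes = ranking.table[["drug_id", "candidate"]].rename(
        columns={"drug_id": "node"}
    )
    drug_nodes["kind"] = "drug"
    gene_nodes = pd.DataFrame(
        {"node": sorted(edges_df["gene"].unique()), "candidate": False, "kind": "gene"}
    )
    nodes_df = pd.concat([drug_nodes, gene_nodes], ignore_index=True)[
        ["node", "kind", "candidate"]
    ]
    return edges_df, nodes_df


def bipartite_graph(ranking: DrugRanking) -> nx.Graph:
    """The bipartite network as a graph (GraphML-serializable attributes)."""
    edges_df, nodes_df = export_bipartite(ranking)
    G = nx.Graph()
    for _, row in nodes_df.iterrows():
        G.add_node(row["node"], kind=row["kind"], candidate=bool(row["candidate"]))
    G.add_edges_from(edges_df.itertuples(index=False, name=None))
    return G
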