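"""Score filtering, DEG-induced subnetwork construction, core extraction.

The interactome arrives as a scored undirected edge list (STRING dialect:
``protein1``, ``protein2``, ``combined_score`` in 0–1000).  Edges above the
confidence threshold (strict, default > 900) between differentially
expressed genes form the differential gene network; dropping everything
outside the largest connected component ("removing scatters") yields the
core network that the centrality stage consumes.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .containers import InputError

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["protein1", "protein2", "combined_score"]


def _check_edge_list(edges: pd.DataFrame) -> None:
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise InputError(f"edge list missing columns: {missing}")
    if len(edges) and not edges["combined_score"].between(0, 1000).all():
        raise InputError("combined_score values must lie in [0, 1000]")


def filter_interactions(edges: pd.DataFrame, min_score: int = 900) -> pd.DataFrame:
    """Retain edges with ``combined_score`` strictly greater than ``min_score``."""
    _check_edge_list(edges)
    return edges[edges["combined_score"] > min_score].reset_index(drop=True)


def build_deg_network(edges: pd.DataFrame, degs: pd.DataFrame) -> nx.Graph:
    """Induce the (filtered) interactome on the DEG set.

    Parameters
    ----------
    edges
        Score-filtered edge list.
    degs
        Differential-expression table indexed by gene with an ``is_deg``
        column (as produced by :func:`keygenet.diffexpr.run_differential_expression`).

    Returns
    -------
    networkx.Graph
        Simple undirected graph over DEGs that carry at least one retained
        edge.  ``G.graph['n_deg']`` records the DEG count and
        ``G.graph['n_deg_isolated']`` the DEGs without any retained edge.
    """
    _check_edge_list(edges)
    deg_set = set(degs.index[degs["is_deg"]])
    G = nx.Graph()
    for a, b in zip(edges["protein1"], edges["protein2"]):
        if a != b and a in deg_set and b in deg_set:
            G.add_edge(a, b)
    G.graph["n_deg"] = len(deg_set)
    G.graph["n_deg_isolated"] = len(deg_set) - G.number_of_nodes()
    if G.number_of_nodes() == 0:
        logger.warning("no DEG pair is connected in the filtered interactome")
    return G


def extract_core(network: nx.Graph, min_component_size: int | None = None) -> nx.Graph:
    """Remove scattered components, keeping the main connected subgraph.

    By default returns the largest connected component (ties broken in
    favour of the component containing the lexicographically smallest node
    id).  If ``min_component_size`` is given, the union of all components of
    at least that size is kept instead — note the result may then be
    disconnected.

    The number of removed nodes and edges is recorded in
    ``G.graph['n_scatter_nodes']`` / ``['n_scatter_edges']``.
    """
    if network.number_of_nodes() == 0:
        logger.warning("extract_core called on an empty network")
        return network.copy()
    comps = [sorted(c) for c in nx.connected_components(network)]
    if min_component_size is not None:
        keep: set = set()
        for c in comps:
            if len(c) >= min_component_size:
                keep.update(c)
    else:
        best = max(len(c) for c in comps)
        tied = [c for c in comps if len(c) == best]
        keep = set(min(tied, key=lambda c: c[0]))
    core = network.subgraph(keep).copy()
    core.graph["n_scatter_nodes"] = network.number_of_nodes() - core.number_of_nodes()
    core.graph["n_scatter_edges"] = network.number_of_edges() - core.number_of_edges()
    return core
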