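"""Node-centrality algorithms for the key-gene consensus.

Seven algorithms feed the consensus intersection:

====================  =========================================================
degree                Deg(x) = |N(x)|
epc                   edge-percolated component: mean fraction of the network
                      reachable from x across randomly edge-deleted replicates
laplacian             Lap(x) = Deg(x)² + Deg(x) + 2·Σ_{y∈N(x)} Deg(y), the
                      drop in Laplacian energy when x is removed
mnc                   size of the largest connected component of the subgraph
                      induced by x's neighbourhood
katz                  Σ_{k≥0} Σ_y α^k (A^k)_{xy}, row sums of (I − αA)^{-1}
radiality             Σ_{y≠x} (d + 1 − s(x,y)) / (|V| − 1), d the diameter
slc                   semi-local: Σ_{y∈N(x)} Σ_{z∈N(y)} B(z), B(z) the number
                      of nodes within two steps of z
====================  =========================================================

Four shortest-path measures (closeness, betweenness, stress, reciprocal
eccentricity) are provided for comparison; they do not enter the consensus.

All functions take a simple undirected :class:`networkx.Graph` and return a
:class:`~keygenet.containers.CentralityTable` with nodes in sorted order.
Distance-based measures (radiality, closeness, betweenness, stress,
ec_centricity) require a connected graph — run
:func:`keygenet.netbuild.extract_core` first.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .containers import CentralityTable, InputError


def _nodes(G: nx.Graph) -> list:
    return sorted(G.nodes)


def _require_connected(G: nx.Graph, algorithm: str) -> None:
    if G.number_of_nodes() == 0 or not nx.is_connected(G):
        raise InputError(
            f"{algorithm} requires a connected graph; apply extract_core first"
        )


def _table(algorithm: str, G: nx.Graph, score: dict, **params) -> CentralityTable:
    s = pd.Series({n: float(score[n]) for n in _nodes(G)}, dtype=float)
    return CentralityTable(algorithm=algorithm, scores=s, params=params)


def degree(G: nx.Graph) -> CentralityTable:
    """Number of direct neighbours of each node."""
    return _table("degree", G, dict(G.degree))


def laplacian_centrality(G: nx.Graph) -> CentralityTable:
    """Laplacian centrality: Deg² + Deg + 2·(sum of neighbour degrees).

    Equals the drop in Laplacian graph energy (Σ deg² + 2|E|) caused by
    deleting the node; exact integer arithmetic.
    """
    deg = dict(G.degree)
    score = {
        x: deg[x] ** 2 + deg[x] + 2 * sum(deg[y] for y in G[x]) for x in G.nodes
    }
    return _table("laplacian", G, score)


def mnc(G: nx.Graph) -> CentralityTable:
    """Maximum neighbourhood component: largest connected component of N(x)."""
    score = {}
    for x in G.nodes:
        nbrs = list(G[x])
        if not nbrs:
            score[x] = 0
            continue
        sub = G.subgraph(nbrs)
        score[x] = max(len(c) for c in nx.connected_components(sub))
    return _table("mnc", G, score)


def katz(G: nx.Graph, alpha: float = 0.1) -> CentralityTable:
    """Katz centrality: damped count of walks of every length from each node.

    Computed in closed form as row sums of (I − αA)^{-1}; the walk of length
    zero contributes 1 to every node.  Requires α < 1/λ_max, with λ_max the
    spectral radius of the adjacency matrix.
    """
    nodes = _nodes(G)
    if not nodes:
        return _table("katz", G, {}, alpha=alpha)
    A = nx.to_numpy_array(G, nodelist=nodes)
    lam_max = float(np.max(np.linalg.eigvalsh(A))) if len(nodes) > 1 else 0.0
    if lam_max > 0 and alpha >= 1.0 / lam_max:
        raise ValueError(
            f"katz diverges: alpha={alpha} must be < 1/lambda_max = {1.0 / lam_max:.6g}"
        )
    vec = np.linalg.solve(np.eye(len(nodes)) - alpha * A, np.ones(len(nodes)))
    return _table("katz", G, dict(zip(nodes, vec)), alpha=alpha)


def _bfs_depths(G: nx.Graph, source) -> dict:
    return nx.single_source_shortest_path_length(G, source)


def radiality(G: nx.Graph) -> CentralityTable:
    """Diameter-rescaled closeness: Σ_{y≠x} (d + 1 − s(x,y)) / (|V| − 1)."""
    _require_connected(G, "radiality")
    n = G.number_of_nodes()
    if n < 2:
        raise InputError("radiality undefined on a single-node graph")
    ecc = nx.eccentricity(G)
    d = max(ecc.values())
    score = {}
    for x in G.nodes:
        dist = _bfs_depths(G, x)
        score[x] = sum(d + 1 - s for y, s in dist.items() if y != x) / (n - 1)
    return _table("radiality", G, score)


def slc(G: nx.Graph) -> CentralityTable:
    """Semi-local centrality over the two-step neighbourhood.

    B(z) counts the nodes within distance two of z (direct plus two-step
    neighbours); the score of x sums B(z) over all neighbours z of all
    neighbours y of x, with multiplicity.
    """
    B = {}
    for z in G.nodes:
        within2 = set(G[z])
        for y in G[z]:
            within2.update(G[y])
        within2.discard(z)
        B[z] = len(within2)
    score = {
        x: sum(B[z] for y in G[x] for z in G[y]) for x in G.nodes
    }
    return _table("slc", G, score)


def epc(
    G: nx.Graph,
    threshold: float = 0.5,
    n_reduced: int = 1000,
    seed: int = 0,
    normalized: bool = True,
) -> CentralityTable:
    """Edge-percolated component centrality (Monte Carlo).

    Each of ``n_reduced`` replicates assigns every edge an independent
    uniform random number in [0, 1) and deletes edges whose number falls
    below ``threshold``; a node's contribution from a replicate is the
    number of nodes connected to it there (itself included).  With
    ``normalized=True`` (default) the replicate contributions are averaged
    and divided by |V|, so an edgeless graph scores 1/|V| at every node and
    a reliably connected one approaches 1; ``normalized=False`` reports the
    raw sum over replicates divided by |V| (a monotone rescaling by
    ``n_reduced`` — rankings are identical).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    nodes = _nodes(G)
    n = len(nodes)
    if n == 0:
        return _table("epc", G, {}, threshold=threshold, n_reduced=n_reduced,
                      rng_seed=seed, normalized=normalized)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array(
        [(idx[u], idx[v]) for u, v in G.edges()], dtype=np.int32
    ).reshape(-1, 2)
    m = len(edges)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n, dtype=np.int64)
    for _ in range(n_reduced):
        if m:
            keep = rng.random(m) >= threshold
            ii, jj = edges[keep, 0], edges[keep, 1]
        else:
            ii = jj = np.empty(0, dtype=np.int32)
        adj = sparse.coo_matrix(
            (np.ones(len(ii), dtype=np.int8), (ii, jj)), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels, minlength=labels.max() + 1)
        totals += sizes[labels]
    denom = n * n_reduced if normalized else n
    score = dict(zip(nodes, totals / denom))
    return _table("epc", G, score, threshold=threshold, n_reduced=n_reduced,
                  rng_seed=seed, normalized=normalized)


def closeness(G: nx.Graph) -> CentralityTable:
    """Classic closeness: (|V| − 1) / Σ_y s(x, y)."""
    _require_connected(G, "closeness")
    return _table("closeness", G, nx.closeness_centrality(G))


def betweenness(G: nx.Graph) -> CentralityTable:
    """Unnormalized shortest-path betweenness (each unordered pair once)."""
    _require_connected(G, "betweenness")
    return _table("betweenness", G, nx.betweenness_centrality(G, normalized=False))


def _sp_counts(G: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs geodesic distances and shortest-path counts via BFS."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), -1, dtype=np.int32)
    S = np.zeros((n, n), dtype=np.float64)
    for s in nodes:
        si = idx[s]
        D[si, si] = 0
        S[si, si] = 1.0
        q = deque([s])
        while q:
            v = q.popleft()
            vi = idx[v]
            for w in G[v]:
                wi = idx[w]
                if D[si, wi] == -1:
                    D[si, wi] = D[si, vi] + 1
                    q.append(w)
                if D[si, wi] == D[si, vi] + 1:
                    S[si, wi] += S[si, vi]
    return D, S


def stress(G: nx.Graph) -> CentralityTable:
    """Stress centrality: number of shortest paths passing through each node.

    Σ over unordered pairs {s, t} (s ≠ x ≠ t) of σ_st(x), the count of
    s–t geodesics through x; σ_st(x) = σ_sx · σ_xt when x lies on an s–t
    geodesic.
    """
    _require_connected(G, "stress")
    nodes = _nodes(G)
    D, S = _sp_counts(G, nodes)
    n = len(nodes)
    score = {}
    for xi, x in enumerate(nodes):
        on_path = D[:, xi][:, None] + D[xi, :][None, :] == D
        cnt = np.outer(S[:, xi], S[xi, :]) * on_path
        cnt[xi, :] = 0.0
        cnt[:, xi] = 0.0
        np.fill_diagonal(cnt, 0.0)
        score[x] = 0.5 * float(cnt.sum())
    return _table("stress", G, score)


def ec_centricity(G: nx.Graph) -> CentralityTable:
    """Reciprocal eccentricity: 1 / max_y s(x, y)."""
    _require_connected(G, "ec_centricity")
    if G.number_of_nodes() == 1:
        raise InputError("ec_centricity undefined on a single-node graph")
    ecc = nx.eccentricity(G)
    return _table("ec_centricity", G, {x: 1.0 / e for x, e in ecc.items()})


#: The seven algorithms whose top-k lists are intersected for key genes.
INTEGRATION_ALGORITHMS = {
    "degree": degree,
    "epc": epc,
    "laplacian": laplacian_centrality,
    "mnc": mnc,
    "katz": katz,
    "radiality": radiality,
    "slc": slc,
}

#: Shortest-path measures used only for comparison.
COMPARISON_ALGORITHMS = {
    "closeness": closeness,
    "betweenness": betweenness,
    "stress": stress,
    "ec_centricity": ec_centricity,
}


def run_integration_algorithms(
    G: nx.Graph,
    katz_alpha: float = 0.1,
    epc_threshold: float = 0.5,
    epc_n_reduced: int = 1000,
    epc_seed: int = 0,
) -> list[CentralityTable]:
    """Run all seven consensus algorithms on the core network."""
    return [
        degree(G),
        epc(G, threshold=epc_threshold, n_reduced=epc_n_reduced, seed=epc_seed),
        laplacian_centrality(G),
        mnc(G),
        katz(G, alpha=katz_alpha),
        radiality(G),
        slc(G),
    ]


def run_comparison_algorithms(G: nx.Graph) -> list[CentralityTable]:
    """Run the four shortest-path comparison measures."""
    return [fn(G) for fn in COMPARISON_ALGORITHMS.values()]
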