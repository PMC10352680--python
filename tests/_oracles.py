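"""Independent brute-force oracles for the centrality and network stages.

Everything here is written from first principles (own BFS / exhaustive
enumeration / truncated series) and deliberately avoids the code paths it
checks — these are slow reference implementations for small graphs only.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Plain BFS geodesic distances from ``source`` over an adjacency dict."""
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def graph_to_adj(G) -> dict:
    return {v: sorted(G[v]) for v in G.nodes}


def components(adj: dict) -> list[set]:
    seen: set = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def laplacian_energy(G) -> int:
    """Laplacian graph energy: sum of squared degrees plus twice the edge count."""
    degs = [d for _, d in G.degree]
    return sum(d * d for d in degs) + 2 * G.number_of_edges()


def laplacian_energy_drop(G) -> dict:
    """Energy drop E(G) - E(G - x) for every node x (exact integers)."""
    out = {}
    for x in G.nodes:
        H = G.copy()
        H.remove_node(x)
        out[x] = laplacian_energy(G) - laplacian_energy(H)
    return out


def mnc_brute(G) -> dict:
    out = {}
    for x in G.nodes:
        nbrs = set(G[x])
        adj = {v: [w for w in G[v] if w in nbrs] for v in nbrs}
        out[x] = max((len(c) for c in components(adj)), default=0)
    return out


def slc_brute(G) -> dict:
    adj = graph_to_adj(G)
    B = {}
    for z in G.nodes:
        dist = bfs_distances(adj, z)
        B[z] = sum(1 for w, d in dist.items() if w != z and d <= 2)
    return {x: sum(B[z] for y in G[x] for z in G[y]) for x in G.nodes}


def radiality_brute(G) -> dict:
    adj = graph_to_adj(G)
    n = len(adj)
    all_dist = {v: bfs_distances(adj, v) for v in adj}
    diam = max(max(d.values()) for d in all_dist.values())
    return {
        x: sum(diam + 1 - s for y, s in all_dist[x].items() if y != x) / (n - 1)
        for x in adj
    }


def closeness_brute(G) -> dict:
    adj = graph_to_adj(G)
    n = len(adj)
    return {
        x: (n - 1) / sum(bfs_distances(adj, x).values()) for x in adj
    }


def ec_centricity_brute(G) -> dict:
    adj = graph_to_adj(G)
    return {x: 1.0 / max(bfs_distances(adj, x).values()) for x in adj}


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Enumerate every geodesic from s to t by depth-first expansion."""
    dist = bfs_distances(adj, s)
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(path)
            return
        for w in adj[v]:
            if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                extend(path + [w])

    extend([s])
    return paths


def betweenness_brute(G) -> dict:
    adj = graph_to_adj(G)
    nodes = sorted(adj)
    out = {x: 0.0 for x in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        for x in nodes:
            if x in (s, t):
                continue
            through = sum(1 for p in paths if x in p)
            out[x] += through / len(paths)
    return out


def stress_brute(G) -> dict:
    adj = graph_to_adj(G)
    nodes = sorted(adj)
    out = {x: 0.0 for x in nodes}
    for s, t in itertools.combinations(nodes, 2):
        for p in _all_shortest_paths(adj, s, t):
            for x in p[1:-1]:
                out[x] += 1.0
    return out


def katz_series(G, alpha: float, n_terms: int = 200) -> dict:
    """Truncated power series Σ_k α^k A^k 1 (row sums)."""
    nodes = sorted(G.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in G.edges():
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    total = np.ones(n)
    term = np.ones(n)
    for _ in range(n_terms):
        term = alpha * (A @ term)
        total += term
    return dict(zip(nodes, total))


def epc_exhaustive(G, threshold: float = 0.5) -> tuple[dict, dict]:
    """Exact EPC expectation and per-replicate SD over all edge subsets.

    Each edge is retained independently with probability 1 - ``threshold``.
    Returns (expectation, sd) of the normalized per-replicate statistic
    |component(x)| / |V| for every node x.
    """
    nodes = sorted(G.nodes)
    n = len(nodes)
    edges = sorted(tuple(sorted(e)) for e in G.edges())
    m = len(edges)
    p_keep = 1.0 - threshold
    mean = {x: 0.0 for x in nodes}
    second = {x: 0.0 for x in nodes}
    for kept in itertools.product([0, 1], repeat=m):
        w = 1.0
        adj = {v: [] for v in nodes}
        for (u, v), k in zip(edges, kept):
            w *= p_keep if k else (1.0 - p_keep)
            if k:
                adj[u].append(v)
                adj[v].append(u)
        for comp in components(adj):
            val = len(comp) / n
            for x in comp:
                mean[x] += w * val
                second[x] += w * val * val
    sd = {x: float(np.sqrt(max(second[x] - mean[x] ** 2, 0.0))) for x in nodes}
    return mean, sd
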