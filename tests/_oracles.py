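"""Brute-force graph-metric oracles for small graphs (N <= ~8).

Independent of networkx and of the implementation under test: distances by
explicit Bellman relaxation, betweenness by exhaustive shortest-path
enumeration, coreness by literal peeling, clustering by triangle counting.
"""

from itertools import permutations

import numpy as np


def bf_distances(adj):
    """All-pairs hop distances by repeated relaxation; inf if unreachable."""
    n = adj.shape[0]
    b = (adj > 0).astype(int)
    dist = np.where(b, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for _ in range(n):
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if dist[i, k] + dist[k, j] < dist[i, j]:
                        dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def bf_density(adj):
    n = adj.shape[0]
    e = np.count_nonzero(np.triu(adj, 1))
    return 2.0 * e / (n * (n - 1))


def bf_cpl_efficiency(adj):
    dist = bf_distances(adj)
    n = adj.shape[0]
    ds = [dist[i, j] for i in range(n) for j in range(n) if i != j]
    finite = [d for d in ds if np.isfinite(d)]
    cpl = float(np.mean(finite)) if finite else float("inf")
    eff = float(np.mean([1.0 / d if np.isfinite(d) else 0.0 for d in ds]))
    return cpl, eff


def bf_radius_diameter(adj):
    dist = bf_distances(adj)
    ecc = dist.max(axis=1)
    return float(ecc.min()), float(ecc.max())


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate every shortest s->t path by depth-first search."""
    if not np.isfinite(dist[s, t]):
        return []
    b = adj > 0
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in np.flatnonzero(b[u]):
            # v is on some shortest path iff it advances toward t
            if dist[s, v] == len(path) and dist[s, v] + dist[v, t] == dist[s, t]:
                extend(path + [v])

    extend([s])
    return paths


def bf_node_betweenness(adj):
    n = adj.shape[0]
    dist = bf_distances(adj)
    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


def bf_edge_betweenness(adj):
    n = adj.shape[0]
    dist = bf_distances(adj)
    ebtw = {}
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] > 0:
                ebtw[(i, j)] = 0.0
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            for p in paths:
                for u, v in zip(p[:-1], p[1:]):
                    e = (min(u, v), max(u, v))
                    ebtw[e] += 1.0 / len(paths)
    return ebtw


def bf_clustering(adj):
    b = (adj > 0).astype(int)
    n = b.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(b[i])
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(
            b[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1:]
        )
        out[i] = tri / (k * (k - 1) / 2)
    return out


def bf_coreness(adj):
    """Iterative peeling: coreness k = belongs to k-core, not (k+1)-core."""
    b = (adj > 0).astype(int)
    n = b.shape[0]
    core = np.zeros(n, dtype=int)
    for k in range(1, n):
        alive = np.ones(n, dtype=bool)
        changed = True
        while changed:
            changed = False
            deg = (b * alive[None, :]).sum(axis=1)
            drop = alive & (deg < k)
            if drop.any():
                alive[drop] = False
                changed = True
        core[alive] = k
    return core


def bf_participation(adj, community_id):
    b = (adj > 0).astype(int)
    n = b.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = b[i].sum()
        if k == 0:
            continue
        frac = 0.0
        for c in np.unique(community_id):
            k_ic = int(b[i, community_id == c].sum())
            frac += (k_ic / k) ** 2
        out[i] = 1.0 - frac
    return out


def bf_overlap(adj, i, j):
    b = adj > 0
    return int(np.sum(b[i] & b[j]))


def bf_delta_cpl(adj, i, j):
    cpl0, _ = bf_cpl_efficiency(adj)
    a2 = adj.copy()
    a2[i, j] = a2[j, i] = 0.0
    cpl1, _ = bf_cpl_efficiency(a2)
    d = cpl1 - cpl0
    if not np.isfinite(d):
        return float("inf") if cpl1 > cpl0 else 0.0
    return d
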