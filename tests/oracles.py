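"""Independent brute-force oracles for the topology metrics.

Everything here is deliberately naive and self-contained: BFS over
adjacency dicts, exhaustive simple-path enumeration for betweenness, and
a dense eigendecomposition for eigenvector centrality.  None of it calls
the package code it is used to check.
"""

from collections import deque
from itertools import combinations

import numpy as np


def adjacency(graph):
    return {v: set(graph.neighbors(v)) for v in graph.nodes}


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def all_simple_paths(adj, source, target, limit):
    """All simple paths of length <= limit, by plain DFS."""
    paths = []
    stack = [(source, [source])]
    while stack:
        v, path = stack.pop()
        if v == target:
            paths.append(path)
            continue
        if len(path) > limit:
            continue
        for u in adj[v]:
            if u not in path:
                stack.append((u, path + [u]))
    return paths


def brute_betweenness(graph):
    """Pair-normalised betweenness by exhaustive shortest-path enumeration.

    Only sensible for very small graphs (<= ~8 nodes).
    """
    adj = adjacency(graph)
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        shortest = [
            p for p in all_simple_paths(adj, s, t, dist[t] + 1) if len(p) - 1 == dist[t]
        ]
        for path in shortest:
            for v in path[1:-1]:
                score[v] += 1.0 / len(shortest)
    norm = (n - 1) * (n - 2) / 2
    if norm <= 0:
        return {v: 0.0 for v in nodes}
    return {v: s / norm for v, s in score.items()}


def brute_closeness(graph):
    adj = adjacency(graph)
    n = len(adj)
    return {
        v: (n - 1) / sum(bfs_distances(adj, v).values()) for v in adj
    }


def brute_eccentricity(graph):
    adj = adjacency(graph)
    return {v: max(bfs_distances(adj, v).values()) for v in adj}


def brute_mspl(graph):
    adj = adjacency(graph)
    nodes = sorted(adj)
    total = 0
    count = 0
    for s, t in combinations(nodes, 2):
        total += bfs_distances(adj, s)[t]
        count += 1
    return total / count


def brute_clustering(graph):
    adj = adjacency(graph)
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def dense_eigenvector(graph):
    """Principal eigenvector of the adjacency matrix, scaled so max = 1."""
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.edges:
        a[index[u], index[v]] = a[index[v], index[u]] = 1.0
    eigenvalues, eigenvectors = np.linalg.eigh(a)
    principal = np.abs(eigenvectors[:, np.argmax(eigenvalues)])
    principal /= principal.max()
    return dict(zip(nodes, principal))
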