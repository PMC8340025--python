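"""Brute-force graph oracles used to cross-check the centrality code.

Independent of networkx: plain BFS over adjacency sets, with explicit
enumeration of shortest-path counts for betweenness.
"""

from collections import deque


def bfs_distances(adj, source):
    """Distances and shortest-path counts from one source by plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    order = []
    q = deque([source])
    while q:
        v = q.popleft()
        order.append(v)
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma, order


def brute_betweenness(adj):
    """Unnormalized betweenness with even split over equal-length paths.

    For every node pair (s, t) and interior node v, the contribution is
    (#shortest s-t paths through v) / (#shortest s-t paths); each undirected
    pair is counted once.
    """
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, sig_s, _ = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            dist_t, sig_t, _ = bfs_distances(adj, t)
            d = dist_s[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d:
                    bc[v] += sig_s[v] * sig_t[v] / sig_s[t]
    return bc


def brute_eccentricity(adj):
    """Max BFS distance within each node's connected component."""
    ecc = {}
    for v in adj:
        dist, _, _ = bfs_distances(adj, v)
        ecc[v] = max(dist.values())
    return ecc


def adjacency_from_edges(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj
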