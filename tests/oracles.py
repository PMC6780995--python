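"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def oracle_adjacency(tiles, domain):
    """Tile adjacency by pairwise shared-boundary length of the clipped
    polygons (polygon-union semantics of cluster merging)."""
    eps = 1e-9 * max(domain._diameter(), 1.0)
    pairs = set()
    for i in range(len(tiles)):
        for j in range(i + 1, len(tiles)):
            if tiles[i].intersection(tiles[j]).length > eps:
                pairs.add((i, j))
    return pairs


def oracle_components(n, pairs, marks):
    """BFS connected components over same-color adjacency."""
    adj = {i: [] for i in range(n)}
    for i, j in pairs:
        if marks[i] == marks[j]:
            adj[i].append(j)
            adj[j].append(i)
    seen, n_comp = set(), 0
    for s in range(n):
        if s in seen:
            continue
        n_comp += 1
        stack = [s]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u])
    return n_comp


def brute_force_mingling(xy, marks, k):
    """O(n^2) mingling oracle: full distance matrix, ties broken by index."""
    n = len(xy)
    out = np.empty(n)
    for i in range(n):
        d2 = ((xy - xy[i]) ** 2).sum(axis=1)
        order = sorted((dd, j) for j, dd in enumerate(d2) if j != i)
        nbrs = [j for _, j in order[:k]]
        out[i] = np.mean([marks[j] != marks[i] for j in nbrs])
    return out
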