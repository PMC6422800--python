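"""Independent naive reference implementations used only to cross-check the
package's tree algorithms.  Everything here is deliberately simple-minded:
exhaustive enumeration and literal definition-following, no shared code
with the implementation under test.
"""

from __future__ import annotations

import itertools
import math


def enumerate_labeled_trees(n: int):
    """Yield the edge list of every labeled tree on n nodes, each exactly
    once, by enumerating all Prüfer sequences."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield prufer_decode_naive(list(seq), n)


def prufer_decode_naive(seq: list[int], n: int) -> list[tuple[int, int]]:
    """Textbook Prüfer decoding using explicit degree bookkeeping."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    used = [False] * n
    for x in seq:
        leaf = min(i for i in range(n) if degree[i] == 1 and not used[i])
        edges.append((leaf, x))
        used[leaf] = True
        degree[leaf] -= 1
        degree[x] -= 1
    u, v = [i for i in range(n) if not used[i] and degree[i] == 1]
    edges.append((u, v))
    return edges


def max_spanning_tree_weight_bruteforce(weights) -> float:
    """Maximum total weight over ALL spanning trees, by trying every
    (n-1)-subset of edges and keeping those that form a tree."""
    n = len(weights)
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = -math.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            total = sum(weights[u][v] for u, v in subset)
            best = max(best, total)
    return best


def tree_metrics_naive(edges: list[tuple[int, int]], n: int) -> dict:
    """All global tree measures computed straight from their definitions:
    BFS hop distances from every node, betweenness by walking the unique
    path of every unordered pair, Pearson correlation by the covariance
    formula."""
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    deg = [len(a) for a in adj]

    # BFS parents and distances from every source
    dist = [[-1] * n for _ in range(n)]
    parent = [[-1] * n for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[s][v] < 0:
                        dist[s][v] = dist[s][u] + 1
                        parent[s][v] = u
                        nxt.append(v)
            queue = nxt

    # betweenness: interior nodes of each pair's unique path
    through = [0] * n
    for s in range(n):
        for t in range(s + 1, n):
            x = parent[s][t]
            while x != s and x != -1:
                through[x] += 1
                x = parent[s][x]
    pair_norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    bc = [c / pair_norm for c in through]

    ecc_raw = [max(row) for row in dist]
    diam_raw = max(ecc_raw)
    leaves = sum(1 for d in deg if d == 1)
    max_bc = max(bc)
    th = leaves / (2 * (n - 1) * max_bc) if n >= 3 and max_bc > 0 else math.nan
    kappa = sum(d * d for d in deg) / sum(deg)

    xs, ys = [], []
    for u, v in edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    r = sxy / math.sqrt(sxx * syy) if sxx > 0 and syy > 0 else math.nan

    return {
        "degree": [d / (n - 1) for d in deg],
        "bc": bc,
        "ecc_nodal": [e / (n - 1) for e in ecc_raw],
        "max_degree": max(deg) / (n - 1),
        "max_bc": max_bc,
        "ecc": sum(e / (n - 1) for e in ecc_raw) / n,
        "diameter": diam_raw / (n - 1),
        "leaf": leaves / n,
        "th": th,
        "kappa": kappa,
        "r": r,
    }
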