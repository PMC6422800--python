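"""Maximum-weight spanning trees of connectivity matrices and their
topology metrics.

The "minimum spanning tree" of the EEG-network literature is, for a
similarity matrix such as PLI, the spanning tree of *largest* total weight:
Kruskal's algorithm run on edges sorted in descending weight order,
discarding any edge that would close a loop.  Equivalently it is the
ordinary minimum spanning tree of (1 - PLI).  This module implements that
construction directly, plus the nodal and global tree measures used to
characterise the topology:

==========  =================================================================
degree      edges at a node, normalised by n - 1 (MaxDeg = max over nodes)
bc          betweenness centrality: fraction of the (n-1)(n-2)/2 pairs of
            other nodes whose unique tree path crosses the node
ecc         eccentricity: longest hop distance to any node, / (n - 1)
diameter    largest hop distance between any two nodes, / (n - 1)
leaf        fraction of degree-1 nodes
th          tree hierarchy  L / (2 m BCmax)  with L leaves, m = n - 1 edges;
            ~0 for a path, 0.5 for a star, higher between the extremes
kappa       degree divergence  sum(k^2) / sum(k); large when hubs exist
r           degree correlation: Pearson correlation of endpoint degrees over
            the symmetrised edge list; undefined (NaN) when degenerate
==========  =================================================================

Hop distances are unweighted: every tree edge counts 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeGraph", "NodalMetrics", "GlobalMSTMetrics",
    "max_spanning_tree", "nodal_metrics", "global_metrics",
    "epoch_average_metrics", "find_hub",
]


@dataclass
class TreeGraph:
    """An acyclic spanning subgraph: n labelled nodes, n - 1 weighted edges."""

    node_labels: list[str]
    edges: list[tuple[int, int, float]]  # (u, v, weight), u/v node indices

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v, _ in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for u, v, _ in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def is_tree(self) -> bool:
        """n - 1 edges, connected, acyclic (checked by union-find)."""
        n = self.n_nodes
        if len(self.edges) != n - 1:
            return False
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for u, v, _ in self.edges:
            ru, rv = find(u), find(v)
            if ru == rv:
                return False  # cycle
            parent[ru] = rv
        return True


@dataclass
class NodalMetrics:
    """Per-node tree measures; arrays indexed like the tree's node labels."""

    node_labels: list[str]
    degree_raw: np.ndarray      # int, edge count
    degree: np.ndarray          # degree_raw / (n - 1)
    bc: np.ndarray              # betweenness, normalised to [0, 1]
    ecc_raw: np.ndarray         # int, hops
    ecc: np.ndarray             # ecc_raw / (n - 1)


@dataclass
class GlobalMSTMetrics:
    """Whole-tree summary measures (all normalised except kappa and r)."""

    max_degree: float
    max_bc: float
    ecc: float                  # mean of normalised nodal eccentricity
    diameter: float
    leaf: float
    th: float
    kappa: float
    r: float                    # NaN when undefined (degenerate variance)
    n_nodes: int = 0
    r_defined: int = field(default=1)   # epochs with defined r (for averages)
    n_epochs: int = field(default=1)

    _FIELDS = ("max_degree", "max_bc", "ecc", "diameter", "leaf", "th",
               "kappa", "r")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


# ---------------------------------------------------------------------------
# Tree construction


def max_spanning_tree(matrix: np.ndarray,
                      node_labels: list[str] | None = None) -> TreeGraph:
    """Build the maximum-weight spanning tree of a symmetric weight matrix.

    Kruskal's algorithm: sort all upper-triangle edges by descending weight
    (ties broken by lowest channel-index pair, so the result is deterministic
    across platforms), then add edges in order, discarding any edge that
    would close a loop, until all n nodes are spanned.

    Parameters
    ----------
    matrix
        Symmetric (n, n) array of edge weights (e.g. a PLI matrix).
    node_labels
        Optional labels; defaults to "ch00", "ch01", ...

    Returns
    -------
    TreeGraph with n - 1 edges maximising total weight.
    """
    w = np.asarray(matrix, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if node_labels is None:
        node_labels = [f"ch{i:02d}" for i in range(n)]

    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    # stable sort: descending weight, then ascending (i, j) for equal weights
    order = np.lexsort((ju, iu, -weights))

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int, float]] = []
    for k in order:
        u, v = int(iu[k]), int(ju[k])
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            edges.append((u, v, float(weights[k])))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:  # unreachable for a dense matrix
        raise ValueError("matrix does not define a connected graph")
    return TreeGraph(node_labels, edges)


# ---------------------------------------------------------------------------
# Metrics


def _hop_distances(adj: list[list[int]], n: int) -> np.ndarray:
    """All-pairs hop distances on a tree via BFS from every node."""
    dist = np.zeros((n, n), dtype=np.int64)
    for s in range(n):
        d = dist[s]
        d[:] = -1
        d[s] = 0
        stack = [s]
        while stack:
            nxt = []
            for u in stack:
                for v in adj[u]:
                    if d[v] < 0:
                        d[v] = d[u] + 1
                        nxt.append(v)
            stack = nxt
    return dist


def _tree_betweenness_raw(adj: list[list[int]], n: int) -> np.ndarray:
    """Unnormalised betweenness on a tree by subtree-size counting.

    Removing node v splits the tree into components of sizes s_1..s_k
    (one per neighbour); the pairs of other nodes routed through v number
    ((n-1)^2 - sum s_i^2) / 2.  Subtree sizes come from one rooted DFS,
    so the whole computation is O(n).
    """
    if n == 1:
        return np.zeros(1)
    # iterative DFS from node 0: order + parent
    parent = np.full(n, -1, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    idx = 0
    while stack:
        u = stack.pop()
        order[idx] = u
        idx += 1
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    if idx != n:
        raise ValueError("graph is not connected")
    size = np.ones(n, dtype=np.int64)
    for u in order[::-1]:
        if parent[u] >= 0:
            size[parent[u]] += size[u]

    bc = np.zeros(n, dtype=np.float64)
    total = n - 1  # nodes other than v
    for v in range(n):
        comp_sq = 0
        for c in adj[v]:
            s = size[c] if parent[c] == v else n - size[v]
            comp_sq += s * s
        bc[v] = (total * total - comp_sq) / 2.0
    return bc


def nodal_metrics(tree: TreeGraph) -> NodalMetrics:
    """Degree, betweenness, and eccentricity for every node of a tree."""
    n = tree.n_nodes
    if not tree.is_tree():
        raise ValueError("input is not a spanning tree")
    adj = tree.adjacency_lists()
    deg_raw = tree.degrees()
    dist = _hop_distances(adj, n)
    ecc_raw = dist.max(axis=1)
    bc_raw = _tree_betweenness_raw(adj, n)
    pair_norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return NodalMetrics(
        node_labels=list(tree.node_labels),
        degree_raw=deg_raw,
        degree=deg_raw / (n - 1),
        bc=bc_raw / pair_norm,
        ecc_raw=ecc_raw,
        ecc=ecc_raw / (n - 1),
    )


def global_metrics(tree: TreeGraph,
                   nodal: NodalMetrics | None = None) -> GlobalMSTMetrics:
    """Whole-tree topology summary (see module docstring for definitions)."""
    n = tree.n_nodes
    if nodal is None:
        nodal = nodal_metrics(tree)
    deg_raw = nodal.degree_raw
    leaf_count = int((deg_raw == 1).sum())
    max_bc = float(nodal.bc.max())
    m = n - 1  # edge count
    if n >= 3 and max_bc > 0:
        th = leaf_count / (2.0 * m * max_bc)
    else:
        th = math.nan
    kappa = float((deg_raw.astype(float) ** 2).sum() / deg_raw.sum())

    # degree correlation over the symmetrised edge list: each edge (u, v)
    # contributes both (k_u, k_v) and (k_v, k_u)
    x = np.array([deg_raw[u] for u, v, _ in tree.edges]
                 + [deg_raw[v] for u, v, _ in tree.edges], dtype=float)
    y = np.array([deg_raw[v] for u, v, _ in tree.edges]
                 + [deg_raw[u] for u, v, _ in tree.edges], dtype=float)
    if x.std() == 0 or y.std() == 0:
        r = math.nan
    else:
        r = float(np.corrcoef(x, y)[0, 1])

    return GlobalMSTMetrics(
        max_degree=float(nodal.degree.max()),
        max_bc=max_bc,
        ecc=float(nodal.ecc.mean()),
        diameter=float(nodal.ecc_raw.max()) / m,
        leaf=leaf_count / n,
        th=th,
        kappa=kappa,
        r=r,
        n_nodes=n,
        r_defined=0 if math.isnan(r) else 1,
        n_epochs=1,
    )


def epoch_average_metrics(metrics: list[GlobalMSTMetrics]) -> GlobalMSTMetrics:
    """Element-wise mean of per-epoch global metrics.

    The degree correlation r may be undefined in some epochs (NaN); it is
    averaged over the epochs where it is defined, and ``r_defined`` records
    how many contributed.
    """
    if not metrics:
        raise ValueError("empty metric list")
    out = {}
    for name in GlobalMSTMetrics._FIELDS:
        vals = np.array([getattr(g, name) for g in metrics], dtype=float)
        if name == "r":
            defined = ~np.isnan(vals)
            out[name] = float(vals[defined].mean()) if defined.any() else math.nan
            r_defined = int(defined.sum())
        else:
            out[name] = float(vals.mean())
    return GlobalMSTMetrics(n_nodes=metrics[0].n_nodes, r_defined=r_defined,
                            n_epochs=len(metrics), **out)


def find_hub(nodal_values: np.ndarray, node_labels: list[str]) -> str:
    """Locate the hub channel of a group: the node maximising the group-mean
    nodal statistic (degree or betweenness).

    Parameters
    ----------
    nodal_values
        Array (n_subjects, n_nodes) of a nodal statistic.
    node_labels
        Channel labels in montage order.

    Ties resolve to the lowest montage index (np.argmax convention).
    """
    vals = np.atleast_2d(np.asarray(nodal_values, dtype=float))
    if vals.shape[0] == 0:
        raise ValueError("empty group")
    if vals.shape[1] != len(node_labels):
        raise ValueError("nodal_values columns must match node_labels")
    return node_labels[int(vals.mean(axis=0).argmax())]
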