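"""Maximum spanning tree of a PLI network, leaf number and diameter.

The spanning tree keeps, of all N(N-1)/2 weighted connections, the N - 1
strongest ones that connect every node without forming a cycle — a unique
backbone that makes networks of different density directly comparable.
Built with Kruskal's algorithm over edges in descending weight order
(strong PLI = strong connection, so the tree collects the most efficient
connections); this is identical to the minimum spanning tree of the
reciprocal weights.

Tree shape is summarized by two numbers: the leaf number (count of
degree-1 nodes; bounds 2..m with m = N - 1) and the hop-count diameter
(longest shortest path; bounded by m - leaf_number + 2).  A chain has 2
leaves and diameter m; a star has m leaves and diameter 2.  Both are
normalized by m to lie in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, validate_weights

__all__ = ["SpanningTree", "TreeMeasures", "maximum_spanning_tree",
           "tree_measures"]


@dataclass
class SpanningTree:
    """A loopless connected subgraph on N labelled nodes with N - 1 edges."""

    labels: tuple[str, ...]
    edges: list[tuple[str, str, float]]
    degree: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {lab: [] for lab in self.labels}
        for a, b, _ in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass(frozen=True)
class TreeMeasures:
    """Leaf number and hop diameter of a spanning tree, raw and /m."""

    leaf_number: int
    diameter: int
    leaf_norm: float
    diameter_norm: float


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def maximum_spanning_tree(w: ConnectivityMatrix | np.ndarray,
                          labels: tuple[str, ...] | None = None
                          ) -> SpanningTree:
    """Kruskal's algorithm over edges sorted by descending weight.

    An edge is skipped iff adding it would close a cycle.  Ties are broken
    by lexicographic label pair so degenerate (equal-weight) inputs yield a
    reproducible tree.  Zero-weight pairs are absent edges; a disconnected
    input is a hard error.
    """
    if isinstance(w, ConnectivityMatrix):
        labels = w.labels if labels is None else labels
        w = w.weights
    else:
        w = np.asarray(w, dtype=float)
        validate_weights(w)
    n = w.shape[0]
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")

    iu, ju = np.triu_indices(n, 1)
    mask = w[iu, ju] > 0
    candidates = sorted(
        ((iu[k], ju[k], float(w[iu[k], ju[k]])) for k in np.flatnonzero(mask)),
        key=lambda e: (-e[2], min(labels[e[0]], labels[e[1]]),
                       max(labels[e[0]], labels[e[1]])),
    )
    uf = _UnionFind(n)
    edges: list[tuple[str, str, float]] = []
    for i, j, weight in candidates:
        if uf.union(i, j):
            a, b = sorted((labels[i], labels[j]))
            edges.append((a, b, weight))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError(
            f"graph is disconnected: spanning tree has {len(edges)} of the "
            f"required {n - 1} edges"
        )
    degree = {lab: 0 for lab in labels}
    for a, b, _ in edges:
        degree[a] += 1
        degree[b] += 1
    return SpanningTree(labels=tuple(labels), edges=edges, degree=degree)


def _bfs_farthest(adj: dict[str, list[str]], start: str) -> tuple[str, int]:
    dist = {start: 0}
    frontier = [start]
    far, far_d = start, 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    if dist[v] > far_d:
                        far, far_d = v, dist[v]
                    nxt.append(v)
        frontier = nxt
    return far, far_d


def tree_measures(tree: SpanningTree) -> TreeMeasures:
    """Leaf number (degree-1 count) and hop diameter, normalized by m.

    The diameter is found with a double breadth-first sweep, exact on
    trees.  For N nodes and m = N - 1 edges: 2 <= leaf <= m,
    2 <= diameter <= m - leaf + 2 (chain: 2 leaves, diameter m; star: m
    leaves, diameter 2).
    """
    m = tree.n_nodes - 1
    leaf = sum(1 for d in tree.degree.values() if d == 1)
    adj = tree.adjacency()
    u, _ = _bfs_farthest(adj, tree.labels[0])
    _, diameter = _bfs_farthest(adj, u)
    return TreeMeasures(
        leaf_number=leaf,
        diameter=diameter,
        leaf_norm=leaf / m,
        diameter_norm=diameter / m,
    )
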