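"""Minimum-spanning-tree clustering of the 2D map.

The map points form a complete graph weighted by Euclidean distance.  Its
minimum spanning tree is built exactly (Kruskal over all N(N-1)/2 edges;
the map never holds more than a few hundred pairs, so no approximate
neighbor graph is needed).  Cutting the k-1 heaviest tree edges leaves k
connected components, which are the clusters.

Real-valued coordinates make weight ties rare, but reproducibility demands
a rule: ties prefer the lexicographically smaller (i, j) index pair, both
when growing the tree and when choosing edges to cut.  Cluster ids 0..k-1
are assigned by descending component size, ties broken by the smallest
member row index.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist


@dataclasses.dataclass(frozen=True)
class MSTree:
    """Spanning tree over N points: edges as (i, j) index pairs with weights."""

    n_points: int
    edges: np.ndarray  # (N-1, 2) int, i < j
    weights: np.ndarray  # (N-1,)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclasses.dataclass(frozen=True)
class Clustering:
    """Partition of the map into k connected components after edge cuts."""

    labels: np.ndarray  # (N,) ints in 0..k-1, descending component size
    k: int
    cut_edges: tuple[tuple[int, int, float], ...]
    mst_total_weight: float

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(points: np.ndarray) -> MSTree:
    """Exact Euclidean MST of the point set (Kruskal on the complete graph)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2D array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    n = pts.shape[0]
    if n <= 1:
        return MSTree(n_points=n, edges=np.empty((0, 2), dtype=int), weights=np.empty(0))

    ii, jj = np.triu_indices(n, k=1)
    w = pdist(pts)
    order = np.lexsort((jj, ii, w))  # weight, then lexicographic (i, j)
    uf = _UnionFind(n)
    edges, weights = [], []
    for idx in order:
        if uf.union(int(ii[idx]), int(jj[idx])):
            edges.append((int(ii[idx]), int(jj[idx])))
            weights.append(float(w[idx]))
            if len(edges) == n - 1:
                break
    return MSTree(n_points=n, edges=np.array(edges, dtype=int), weights=np.array(weights))


def _label_components(n: int, kept_edges: np.ndarray) -> np.ndarray:
    uf = _UnionFind(n)
    for i, j in kept_edges:
        uf.union(int(i), int(j))
    roots = np.array([uf.find(i) for i in range(n)])
    comp_members: dict[int, list[int]] = {}
    for idx, r in enumerate(roots):
        comp_members.setdefault(int(r), []).append(idx)
    # descending size, then smallest member index
    ordered = sorted(comp_members.values(), key=lambda m: (-len(m), m[0]))
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(ordered):
        labels[members] = cid
    return labels


def cut_to_k(tree: MSTree, k: int) -> Clustering:
    """Remove the k-1 heaviest tree edges and label the components 0..k-1."""
    n = tree.n_points
    if not 1 <= k <= max(n, 1):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if tree.edges.shape[0] != max(n - 1, 0):
        raise ValueError("tree must span all points")

    if n == 0:
        return Clustering(np.empty(0, dtype=int), k, (), 0.0)
    # heaviest first; ties cut the lexicographically smaller (i, j) first
    order = np.lexsort((tree.edges[:, 1], tree.edges[:, 0], -tree.weights))
    cut_idx = order[: k - 1]
    keep_mask = np.ones(len(order), dtype=bool)
    keep_mask[cut_idx] = False
    labels = _label_components(n, tree.edges[keep_mask])
    cuts = tuple(
        (int(tree.edges[idx, 0]), int(tree.edges[idx, 1]), float(tree.weights[idx]))
        for idx in cut_idx
    )
    return Clustering(
        labels=labels, k=k, cut_edges=cuts, mst_total_weight=tree.total_weight
    )


def mst_cluster(points: np.ndarray, k: int) -> Clustering:
    """Convenience wrapper: build the MST and cut it to k clusters."""
    return cut_to_k(build_mst(points), k)
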