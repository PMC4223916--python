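"""Relaxed minimum spanning tree (RMST) role-similarity graph.

The similarity matrix Y is converted to the chord distance of the
unit-normalized feature rows, d_ij = sqrt(2 (1 - y_ij)).  The RMST keeps
the minimum spanning tree of the complete distance graph and re-adds any
direct link that beats the tree's bottleneck path once a local
nearest-neighbour scale is allowed for:

    keep (i, j)  iff  (i, j) in MST
                  or  mlink_ij + gamma * (d_i + d_j) > d_ij

where ``mlink_ij`` is the maximum edge weight on the unique MST path
between i and j and ``d_i`` is the distance from i to its nearest
neighbour.  The result emphasizes strong similarities and drops weak,
redundant ones while staying connected; the edge set grows monotonically
with gamma (complete graph in the limit).
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .graph_io import DirectedNetwork
from .rbs import SimilarityMatrix

__all__ = [
    "RoleSimilarityGraph",
    "similarity_to_distance",
    "minimum_spanning_tree",
    "mlink_all_pairs",
    "rmst",
    "DEFAULT_GAMMA",
]

DEFAULT_GAMMA = 0.5


@dataclass
class RoleSimilarityGraph:
    """Undirected RMST graph with similarity edge weights plus its
    construction record (distances, MST, local scales, bottleneck values)."""

    node_labels: tuple
    adjacency: np.ndarray = field(repr=False)  # symmetric, weights = y_ij
    gamma: float = DEFAULT_GAMMA
    D: np.ndarray = field(repr=False, default=None)
    mst_edges: tuple = ()
    local_scale: np.ndarray = field(repr=False, default=None)
    mlink: np.ndarray = field(repr=False, default=None)

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edge_set(self) -> frozenset:
        src, dst = np.nonzero(np.triu(self.adjacency, 1))
        return frozenset(zip(src.tolist(), dst.tolist()))

    def to_network(self) -> DirectedNetwork:
        """View as a (symmetric) DirectedNetwork for the community sweep."""
        return DirectedNetwork(self.node_labels, self.adjacency)


def similarity_to_distance(Y: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Chord distance d_ij = sqrt(2 (1 - y_ij)) between unit feature rows.

    y = 1 maps to 0, y = 0 to sqrt(2); zero diagonal, symmetric.
    """
    M = Y.Y if isinstance(Y, SimilarityMatrix) else np.asarray(Y, dtype=float)
    if (M < -1 - 1e-9).any() or (M > 1 + 1e-9).any():
        raise ValueError("similarities must lie in [-1, 1]")
    D = np.sqrt(2.0 * np.clip(1.0 - M, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return D


def minimum_spanning_tree(D: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal MST of the complete graph on distance matrix D.

    Equal-weight ties are broken by lexicographic edge order (i, j), so the
    tree is permutation-stable.
    """
    n = len(D)
    iu, ju = np.triu_indices(n, 1)
    order = np.lexsort((ju, iu, D[iu, ju]))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int]] = []
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b))
            if len(edges) == n - 1:
                break
    return edges


def mlink_all_pairs(
    tree_edges: list[tuple[int, int]], D: np.ndarray
) -> np.ndarray:
    """Maximum edge weight on the unique tree path between every pair.

    ``tree_edges`` must form a spanning tree over the nodes of D; computed
    by one tree traversal per root, O(N^2) total.
    """
    n = len(D)
    if len(tree_edges) != n - 1:
        raise ValueError(
            f"expected a spanning tree with {n - 1} edges, got {len(tree_edges)}"
        )
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in tree_edges:
        adj[a].append(b)
        adj[b].append(a)
    # with exactly n-1 edges, connectivity (checked below) implies a tree
    mlink = np.zeros((n, n))
    for root in range(n):
        visited = np.zeros(n, dtype=bool)
        visited[root] = True
        queue = deque([root])
        reached = 1
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if not visited[v]:
                    visited[v] = True
                    reached += 1
                    mlink[root, v] = max(mlink[root, u], D[u, v])
                    queue.append(v)
        if reached != n:
            raise ValueError("edge list is not a spanning tree (disconnected)")
    return mlink


def rmst(
    D: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    similarity: np.ndarray | SimilarityMatrix | None = None,
    node_labels=None,
) -> RoleSimilarityGraph:
    """Relaxed MST graph of the metric D.

    Includes every MST edge, plus any pair whose bottleneck tree path, once
    relaxed by the local scales, exceeds the direct distance (strict
    inequality).  Output edge weights are similarities: ``similarity`` if
    given, else the chord-distance inverse 1 - d^2/2.
    """
    D = np.asarray(D, dtype=float)
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if D.ndim != 2 or D.shape[0] != D.shape[1] or np.abs(D - D.T).max() > 1e-9:
        raise ValueError("D must be a symmetric square matrix")
    n = len(D)
    if node_labels is None:
        node_labels = (
            similarity.node_labels
            if isinstance(similarity, SimilarityMatrix)
            else tuple(str(i) for i in range(n))
        )
    Y = (
        similarity.Y
        if isinstance(similarity, SimilarityMatrix)
        else similarity
        if similarity is not None
        else 1.0 - D**2 / 2.0
    )

    tree = minimum_spanning_tree(D)
    mlink = mlink_all_pairs(tree, D)
    off = D + np.diag(np.full(n, np.inf))
    local = off.min(axis=1)  # nearest-neighbour distance d_i

    keep = mlink + gamma * np.add.outer(local, local) > D
    for a, b in tree:
        keep[a, b] = keep[b, a] = True
    np.fill_diagonal(keep, False)

    # floor kept-edge weights so zero-similarity MST edges still keep the
    # graph structurally connected
    A = np.where(keep, np.maximum(Y, 1e-12), 0.0)
    return RoleSimilarityGraph(
        node_labels=tuple(node_labels),
        adjacency=A,
        gamma=float(gamma),
        D=D,
        mst_edges=tuple(tree),
        local_scale=local,
        mlink=mlink,
    )
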