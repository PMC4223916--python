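"""Directed weighted networks: container, readers, writers and transforms.

The :class:`DirectedNetwork` is the object every analysis stage consumes.
Node identity is the string label; all matrices use the frozen 0-based
index order of ``node_labels`` (first-appearance order on load), which is
recorded in every tabular output so cross-module indexing is reproducible.

Edge semantics follow the follower-network convention: an edge ``u -> v``
means the source has declared interest in the target (u follows v);
content travels in the opposite direction.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .partition import Partition

__all__ = [
    "DirectedNetwork",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "read_partition_csv",
    "write_partition_csv",
    "largest_weakly_connected_component",
    "symmetrize",
    "coarse_grain",
]

logger = logging.getLogger(__name__)

_HEADER_WORDS = {"source", "target", "from", "to", "src", "dst", "weight", "node"}


@dataclass
class DirectedNetwork:
    """Weighted directed graph with stable node labels.

    ``adjacency[i, j]`` is the weight of the edge ``node_labels[i] ->
    node_labels[j]``; weights are strictly positive, at most one edge per
    ordered pair.  Self-loops are permitted by the container but flagged,
    and removed by default on load.
    """

    node_labels: tuple
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.node_labels = tuple(str(x) for x in self.node_labels)
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("duplicate node labels")
        A = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_labels)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match N={n}")
        if (A < 0).any() or not np.isfinite(A).all():
            raise ValueError("edge weights must be finite and nonnegative")
        self.adjacency = A
        self._index = {lab: i for i, lab in enumerate(self.node_labels)}

    # -- basic views -------------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    @property
    def total_weight(self) -> float:
        return float(self.adjacency.sum())

    @property
    def out_strength(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def in_strength(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    @property
    def dangling(self) -> tuple:
        """Labels of zero-out-degree nodes (content sinks of the walk)."""
        return tuple(
            lab for lab, s in zip(self.node_labels, self.out_strength) if s == 0
        )

    @property
    def has_self_loops(self) -> bool:
        return bool(np.diag(self.adjacency).any())

    def index_of(self, node) -> int:
        try:
            return self._index[str(node)]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def edges(self) -> Iterator[tuple]:
        src, dst = np.nonzero(self.adjacency)
        for i, j in zip(src, dst):
            yield (self.node_labels[i], self.node_labels[j],
                   float(self.adjacency[i, j]))

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.abs(self.adjacency - self.adjacency.T).max() <= tol)

    # -- transforms --------------------------------------------------------
    def without_self_loops(self) -> "DirectedNetwork":
        A = self.adjacency.copy()
        np.fill_diagonal(A, 0.0)
        return DirectedNetwork(self.node_labels, A)

    def canonicalize(self) -> "DirectedNetwork":
        """Reorder nodes to the first-appearance order of a written edge list.

        Writing and re-reading a canonicalized network is the identity
        (an edge list alone cannot preserve an arbitrary node order, since
        a node only appears once one of its edges does).  Edge-free nodes
        keep their relative order at the end.
        """
        order: list[int] = []
        seen = set()
        for i, j in zip(*np.nonzero(self.adjacency)):
            for idx in (int(i), int(j)):
                if idx not in seen:
                    seen.add(idx)
                    order.append(idx)
        order += [i for i in range(self.N) if i not in seen]
        labs = tuple(self.node_labels[i] for i in order)
        return DirectedNetwork(labs, self.adjacency[np.ix_(order, order)])

    def subnetwork(self, nodes: Sequence) -> "DirectedNetwork":
        """Induced subgraph on ``nodes``, original label order preserved."""
        keep = [self.index_of(n) for n in nodes]
        keep.sort()
        labs = tuple(self.node_labels[i] for i in keep)
        return DirectedNetwork(labs, self.adjacency[np.ix_(keep, keep)])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        g.add_weighted_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        labels = tuple(str(u) for u in g.nodes())
        idx = {u: i for i, u in enumerate(labels)}
        A = np.zeros((len(labels), len(labels)))
        for u, v, data in g.edges(data=True):
            A[idx[str(u)], idx[str(v)]] += float(data.get("weight", 1.0))
        return cls(labels, A)

    @classmethod
    def from_edges(
        cls,
        edge_iter: Iterable[tuple],
        keep_self_loops: bool = False,
        node_order: Sequence | None = None,
    ) -> "DirectedNetwork":
        """Build from (source, target[, weight]) tuples.

        Node order is first-appearance order unless ``node_order`` is given;
        duplicate ordered pairs are summed.
        """
        labels: list = []
        index: dict = {}
        if node_order is not None:
            for lab in node_order:
                lab = str(lab)
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
        triples = []
        n_loops = 0
        for row in edge_iter:
            u, v = str(row[0]), str(row[1])
            w = float(row[2]) if len(row) > 2 else 1.0
            for lab in (u, v):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            if u == v:
                n_loops += 1
                if not keep_self_loops:
                    continue
            triples.append((index[u], index[v], w))
        A = np.zeros((len(labels), len(labels)))
        for i, j, w in triples:
            A[i, j] += w
        net = cls(tuple(labels), A)
        if n_loops:
            logger.info(
                "%d self-loop(s) %s", n_loops,
                "retained" if keep_self_loops else "dropped",
            )
        return net


# ---------------------------------------------------------------------------
# Edge-list / GraphML IO
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise ValueError(f"{path}: empty edge-list file")
    first = sample.splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_edge_list(
    path,
    delimiter: str | None = None,
    weighted: bool = True,
    keep_self_loops: bool = False,
) -> DirectedNetwork:
    """Read a directed network from a TSV/CSV edge list.

    Columns are ``source, target[, weight]``.  A header row is autodetected
    (non-numeric third field, or recognisable column names).  Unweighted
    rows get weight 1; duplicate ordered pairs are summed; self-loops are
    dropped unless ``keep_self_loops``.  Malformed rows raise errors that
    name the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = delimiter or _sniff_delimiter(path)
    rows: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            row = [f.strip() for f in row if f.strip() != ""]
            if not row:
                continue
            if lineno == 1 and _looks_like_header(row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 fields, got {row!r}")
            if len(row) >= 3 and weighted:
                try:
                    w = float(row[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: weight {row[2]!r} is not a number"
                    ) from None
                if not w > 0:
                    raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            else:
                w = 1.0
            rows.append((row[0], row[1], w))
    if not rows:
        raise ValueError(f"{path}: no edges found")
    net = DirectedNetwork.from_edges(rows, keep_self_loops=keep_self_loops)
    logger.info(
        "read %s: N=%d, %d edges, %d dangling node(s)",
        path.name, net.N, net.n_edges, len(net.dangling),
    )
    return net


def _looks_like_header(row: list[str]) -> bool:
    if len(row) >= 3:
        try:
            float(row[2])
            return False
        except ValueError:
            return True
    return any(f.lower() in _HEADER_WORDS for f in row[:2])


def write_edge_list(net: DirectedNetwork, path, delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for u, v, w in net.edges():
            writer.writerow([u, v, format(w, ".17g")])


def read_graphml(path) -> DirectedNetwork:
    g = nx.read_graphml(Path(path))
    if not g.is_directed():
        g = g.to_directed()
    return DirectedNetwork.from_networkx(nx.DiGraph(g))


def write_graphml(net: DirectedNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), Path(path))


def read_partition_csv(path, node_order: Sequence | None = None) -> Partition:
    """Partition from a CSV with columns ``node, label``."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns node, label")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return Partition.from_mapping(mapping, node_order=node_order)


def write_partition_csv(partition: Partition, path) -> None:
    pd.DataFrame(
        {"node": list(partition.node_labels), "label": partition.labels}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def largest_weakly_connected_component(net: DirectedNetwork) -> DirectedNetwork:
    """Induced subgraph on the largest weakly connected node set.

    Ties are broken toward the component containing the lexicographically
    smallest label; original labels and their order are preserved.
    """
    if net.N < 1:
        raise ValueError("empty network")
    comps = list(nx.weakly_connected_components(net.to_networkx()))
    max_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == max_size), key=min)
    return net.subnetwork(sorted(best, key=net.index_of))


def symmetrize(net: DirectedNetwork) -> DirectedNetwork:
    """Ignore edge orientation: adjacency (A + A^T)/2, total weight preserved."""
    A = net.adjacency
    return DirectedNetwork(net.node_labels, (A + A.T) / 2.0)


def coarse_grain(net: DirectedNetwork, grouping: Partition) -> DirectedNetwork:
    """Collapse node groups into super-nodes.

    Weight g -> g' is the sum of all edge weights from members of g to
    members of g' (g = g' gives a self-loop carrying the within-group
    weight); total weight is conserved exactly.
    """
    missing = set(net.node_labels) - set(grouping.node_labels)
    if missing:
        raise ValueError(f"nodes missing from grouping: {sorted(missing)[:5]}")
    labels = grouping.aligned_labels(net.node_labels)
    k = int(labels.max()) + 1
    H = np.zeros((net.N, k))
    H[np.arange(net.N), labels] = 1.0
    coarse = H.T @ net.adjacency @ H
    return DirectedNetwork(tuple(str(c) for c in range(k)), coarse)
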