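"""Node partitions with canonical labelling.

A :class:`Partition` assigns every node of a network to exactly one
community.  Community labels are canonicalized to ``0..k-1`` ordered by the
smallest member index, so two partitions that differ only by a relabelling
compare equal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["Partition"]


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel communities 0..k-1 in order of first appearance."""
    out = np.empty(len(raw), dtype=np.int64)
    seen: dict = {}
    for i, lab in enumerate(raw):
        key = lab.item() if isinstance(lab, np.generic) else lab
        if key not in seen:
            seen[key] = len(seen)
        out[i] = seen[key]
    return out


@dataclass(frozen=True)
class Partition:
    """A partition of a fixed, ordered node set into communities.

    Parameters
    ----------
    node_labels
        Ordered node identifiers (the frozen index order of the network).
    labels
        Community membership per node, any hashable labels; canonicalized
        on construction.
    """

    node_labels: tuple
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        nodes = tuple(self.node_labels)
        if len(set(nodes)) != len(nodes):
            raise ValueError("node labels must be unique")
        raw = np.asarray(self.labels)
        if raw.shape != (len(nodes),):
            raise ValueError(
                f"labels shape {raw.shape} does not match {len(nodes)} nodes"
            )
        canon = _canonical_labels(raw)
        canon.setflags(write=False)
        object.__setattr__(self, "node_labels", nodes)
        object.__setattr__(self, "labels", canon)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_mapping(
        cls, assignment: Mapping, node_order: Sequence | None = None
    ) -> "Partition":
        """Build from a node -> community mapping.

        ``node_order`` fixes the index order; defaults to the mapping's
        iteration order.
        """
        nodes = tuple(node_order) if node_order is not None else tuple(assignment)
        missing = [n for n in nodes if n not in assignment]
        if missing:
            raise ValueError(f"nodes missing from assignment: {missing[:5]}")
        return cls(nodes, np.array([assignment[n] for n in nodes], dtype=object))

    @classmethod
    def singletons(cls, node_labels: Sequence) -> "Partition":
        return cls(tuple(node_labels), np.arange(len(node_labels)))

    @classmethod
    def all_in_one(cls, node_labels: Sequence) -> "Partition":
        return cls(tuple(node_labels), np.zeros(len(node_labels), dtype=np.int64))

    # -- views -------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def k(self) -> int:
        """Number of communities."""
        return int(self.labels.max()) + 1 if self.n else 0

    @property
    def assignment(self) -> dict:
        return {node: int(c) for node, c in zip(self.node_labels, self.labels)}

    def indicator(self) -> np.ndarray:
        """N x k one-hot community indicator matrix H."""
        H = np.zeros((self.n, self.k))
        H[np.arange(self.n), self.labels] = 1.0
        return H

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def communities(self) -> list[list]:
        out: list[list] = [[] for _ in range(self.k)]
        for node, c in zip(self.node_labels, self.labels):
            out[c].append(node)
        return out

    def community_of(self, node) -> int:
        try:
            i = self.node_labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
        return int(self.labels[i])

    def aligned_labels(self, node_order: Sequence) -> np.ndarray:
        """Membership array re-ordered to ``node_order`` (must be the same set)."""
        if set(node_order) != set(self.node_labels):
            raise ValueError("node sets differ")
        assign = self.assignment
        return np.array([assign[n] for n in node_order], dtype=np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.node_labels == other.node_labels and np.array_equal(
            self.labels, other.labels
        )

    def __hash__(self) -> int:
        return hash((self.node_labels, self.labels.tobytes()))
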