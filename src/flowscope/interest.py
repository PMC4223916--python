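"""Interest distance: the network viewed from a vantage node.

As the Markov sweep coarsens the partition, other nodes join the vantage
node's community at increasing Markov times.  The earliest such time is the
*interest distance* — an ultrametric-style notion of how near a node is to
the vantage point in terms of attention flow.  Nodes joining at the same
grid time form a *batch*, internally ranked by stationary probability
(PageRank) descending.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sweep import PartitionSequence

__all__ = ["InterestDistanceProfile", "interest_distance", "community_vantage_profile",
           "UNREACHED"]

#: Sentinel distance for nodes never co-clustered with the vantage within
#: the scanned time range.
UNREACHED = math.inf


@dataclass
class InterestDistanceProfile:
    """Per-node earliest co-clustering time from a vantage point.

    ``distance`` maps node -> earliest Markov time sharing a community with
    the vantage (``UNREACHED`` if never within the grid); ``batches`` lists
    ``(time, [nodes])`` with each batch ranked by pi descending (ties by
    label); ``non_persistent`` flags nodes that later leave the vantage's
    community again (they keep their earliest join time).
    """

    vantage: str
    distance: dict
    batches: list
    non_persistent: frozenset = field(default_factory=frozenset)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: node, distance, batch_index, pi_rank."""
        rows = []
        for b_idx, (t, members) in enumerate(self.batches):
            for rank, node in enumerate(members):
                rows.append((node, t, b_idx, rank))
        reached = {r[0] for r in rows}
        for node, d in self.distance.items():
            if node not in reached:
                rows.append((node, UNREACHED, -1, -1))
        df = pd.DataFrame(rows, columns=["node", "distance", "batch_index", "pi_rank"])
        return df.sort_values(["batch_index", "pi_rank"], key=lambda s: s.replace(-1, np.inf)
                              ).reset_index(drop=True)


def interest_distance(
    seq: PartitionSequence, vantage: str, pi: np.ndarray | None = None
) -> InterestDistanceProfile:
    """Interest-distance profile of ``vantage`` over the sweep ``seq``.

    For each node j the distance is ``min{t in grid : community_t(j) ==
    community_t(vantage)}``; the vantage itself gets the first grid time.
    ``pi`` defaults to the stationary distribution stored in the sweep.
    """
    vantage = str(vantage)
    if vantage not in seq.node_labels:
        raise KeyError(f"vantage {vantage!r} is not a node of the sweep")
    if pi is None:
        pi = seq.pi
    nodes = list(seq.node_labels)
    pi_of = dict(zip(nodes, pi))
    v_idx = nodes.index(vantage)

    distance: dict = {n: UNREACHED for n in nodes}
    batches: list = []
    joined: set = set()
    ever_joined_then_left: set = set()
    for t, part in zip(seq.times, seq.partitions):
        labels = part.aligned_labels(nodes)
        with_vantage = {n for n, c in zip(nodes, labels) if c == labels[v_idx]}
        newly = sorted(
            with_vantage - joined, key=lambda n: (-pi_of[n], n)
        )
        if newly:
            for n in newly:
                distance[n] = float(t)
            batches.append((float(t), newly))
            joined |= set(newly)
        ever_joined_then_left |= joined - with_vantage
    return InterestDistanceProfile(
        vantage=vantage,
        distance=distance,
        batches=batches,
        non_persistent=frozenset(ever_joined_then_left),
    )


def community_vantage_profile(
    seq: PartitionSequence,
    seed_node: str,
    reference_time: float,
    pi: np.ndarray | None = None,
) -> InterestDistanceProfile:
    """Group-vantage wrapper: view from the community of ``seed_node``.

    The group is the community containing ``seed_node`` at the first grid
    time >= ``reference_time``; a node's distance is the earliest time
    >= ``reference_time`` at which it shares a community with the seed.
    """
    mask = seq.times >= reference_time
    if not mask.any():
        raise ValueError(
            f"reference time {reference_time} is beyond the scanned grid"
        )
    sub = PartitionSequence(
        node_labels=seq.node_labels,
        times=seq.times[mask],
        partitions=[p for p, m in zip(seq.partitions, mask) if m],
        r=seq.r[mask],
        k=seq.k[mask],
        vi_runs=seq.vi_runs[mask],
        vi_cross=seq.vi_cross[np.ix_(mask, mask)],
        pi=seq.pi,
        tau=seq.tau,
        n_runs=seq.n_runs,
        master_seed=seq.master_seed,
    )
    return interest_distance(sub, seed_node, pi=pi)
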