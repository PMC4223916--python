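"""Flow roles and role-mix organigrams.

Roles are communities of the RMST role-similarity graph, found with the
same Markov Stability sweep used for interest communities (the number of
roles is whatever the most robust plateau says — nothing is imposed a
priori).  Detected roles are relabeled by descending mean in-strength of
their members in the original network, so role 0 is the most-followed
("reference") end of the spectrum and the last role the "listener" end.

Interest communities are then profiled by their *role mix* — the fraction
of members in each role — and the mixes clustered with plain k-means into
informational organigram types (broadcast, monologue, engaged dialogue,
dialogue in public, in the field's vocabulary).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .graph_io import DirectedNetwork
from .partition import Partition
from .rbs import FlowFeatureMatrix
from .rmst import RoleSimilarityGraph
from .sweep import (
    default_time_grid,
    select_robust_partitions,
    stability_sweep,
)

__all__ = [
    "RoleAssignment",
    "RoleMix",
    "OrganigramClustering",
    "detect_roles",
    "role_flow_profiles",
    "role_mix",
    "cluster_role_mixes",
    "retweet_cdf_table",
]

logger = logging.getLogger(__name__)


@dataclass
class RoleAssignment:
    """Node -> role labels plus the sweep diagnostics that selected them."""

    node_labels: tuple
    labels: np.ndarray = field(repr=False)
    n_roles: int = 1
    window: tuple | None = None
    mean_vi_runs: float = 0.0
    fallback: bool = False  # True when no robust plateau was found

    @property
    def assignment(self) -> dict:
        return {n: int(c) for n, c in zip(self.node_labels, self.labels)}

    def as_partition(self) -> Partition:
        return Partition(self.node_labels, self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": list(self.node_labels), "role": self.labels})


@dataclass
class RoleMix:
    """Per-community role-fraction vectors (each row sums to 1)."""

    communities: tuple
    fractions: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    n_roles: int = 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fractions,
            columns=[f"role_{r}" for r in range(self.n_roles)],
        )
        df.insert(0, "community", list(self.communities))
        return df


@dataclass
class OrganigramClustering:
    """k-means clustering of community role-mixes."""

    k: int
    labels: np.ndarray = field(repr=False)
    centroids: np.ndarray = field(repr=False)
    scores: dict = field(default_factory=dict)  # candidate k -> mean silhouette
    degenerate: bool = False


#: Relaxation for the role-similarity graph used in role detection.  Much
#: larger than the generic RMST default: role detection clusters the graph
#: with a diffusion process, and the aggressive sparsification that is right
#: for visualising a feature manifold leaves within-role point clouds as
#: slow-mixing chains that blur before they cohere.  A near-dense graph
#: keeps within-role mixing fast while near-orthogonal roles stay separated
#: by their low similarity weights.
DEFAULT_ROLE_GAMMA = 60.0

#: Restart-VI tolerance for accepting a role plateau.  Stricter than the
#: generic plateau default because near-duplicate feature rows produce
#: slowly creeping granular pseudo-plateaus that a loose tolerance admits.
DEFAULT_ROLE_VI_TOL = 0.01


def detect_roles(
    rsg: RoleSimilarityGraph,
    original: DirectedNetwork,
    times: np.ndarray | None = None,
    n_runs: int = 12,
    seed: int = 0,
    vi_tol: float | None = DEFAULT_ROLE_VI_TOL,
    min_plateau: int = 5,
) -> RoleAssignment:
    """Flow roles = communities of the RMST role-similarity graph.

    Runs the stability sweep on the (undirected) RMST graph and returns the
    representative partition of the most robust plateau — the longest
    window, ties broken toward the lowest mean restart-VI; trivial
    (singleton / all-in-one) plateaus and, when an interior plateau exists,
    grid-boundary-truncated plateaus are not eligible.  If no plateau
    qualifies, falls back to the partition at the median grid time and sets
    ``fallback``.  Roles are ordered by descending mean in-strength in the
    original network (role 0 = most followed).
    """
    if tuple(rsg.node_labels) != tuple(original.node_labels):
        raise ValueError("RMST graph and original network have different nodes")
    if rsg.D is not None and float(np.max(rsg.D)) < 1e-9:
        # all feature rows identical (e.g. a vertex-transitive graph):
        # every node plays the same role
        return RoleAssignment(
            node_labels=original.node_labels,
            labels=np.zeros(original.N, dtype=np.int64),
            n_roles=1,
        )
    if times is None:
        times = default_time_grid(n=64)
    seq = stability_sweep(
        rsg.to_network(), times=times, n_runs=n_runs, tau=1.0, seed=seed
    )
    windows = select_robust_partitions(seq, vi_tol=vi_tol, min_plateau=min_plateau)
    # the singleton and all-in-one plateaus exist for every network (t -> 0
    # and t -> infinity limits) and carry no role information
    windows = [w for w in windows if 1 < w[1].k < len(rsg.node_labels)]
    # prefer plateaus fully resolved inside the grid: a window truncated by
    # the grid boundary has unknown true extent, so its measured length is
    # not comparable with interior windows
    interior = [
        w for w in windows
        if w[0][0] > times[0] and w[0][1] < times[-1]
    ]
    candidates = interior or windows
    if candidates:
        def _win_stats(w):
            (t0, t1), part = w
            idx = (seq.times >= t0) & (seq.times <= t1)
            return (int(idx.sum()), -float(seq.vi_runs[idx].mean()))

        (t0, t1), part = max(candidates, key=_win_stats)
        idx = (seq.times >= t0) & (seq.times <= t1)
        assignment = RoleAssignment(
            node_labels=part.node_labels,
            labels=part.labels,
            n_roles=part.k,
            window=(t0, t1),
            mean_vi_runs=float(seq.vi_runs[idx].mean()),
            fallback=False,
        )
    else:
        logger.warning("no robust plateau on the role-similarity graph; "
                       "falling back to the median Markov time")
        mid = len(times) // 2
        part = seq.partitions[mid]
        assignment = RoleAssignment(
            node_labels=part.node_labels,
            labels=part.labels,
            n_roles=part.k,
            window=None,
            mean_vi_runs=float(seq.vi_runs[mid]),
            fallback=True,
        )
    return _relabel_by_in_strength(assignment, original)


def _relabel_by_in_strength(
    roles: RoleAssignment, net: DirectedNetwork
) -> RoleAssignment:
    in_s = net.in_strength
    labels = roles.as_partition().aligned_labels(net.node_labels)
    means = np.array(
        [in_s[labels == r].mean() for r in range(roles.n_roles)]
    )
    order = np.argsort(-means, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    new_labels = remap[labels]
    return RoleAssignment(
        node_labels=net.node_labels,
        labels=new_labels,
        n_roles=roles.n_roles,
        window=roles.window,
        mean_vi_runs=roles.mean_vi_runs,
        fallback=roles.fallback,
    )


def role_flow_profiles(
    roles: RoleAssignment, Xf: FlowFeatureMatrix
) -> pd.DataFrame:
    """Per-role mean log1p of unscaled walk counts at every length.

    One row per (role, direction, length); the in/out profile curves that
    characterise each role's pattern of incoming and outgoing interest.
    """
    if set(roles.node_labels) != set(Xf.node_labels):
        raise ValueError("role assignment and feature matrix node sets differ")
    order = [list(Xf.node_labels).index(n) for n in roles.node_labels]
    raw = np.log1p(Xf.unscaled()[order])
    rows = []
    for r in range(roles.n_roles):
        mask = roles.labels == r
        prof = raw[mask].mean(axis=0)
        for k in range(Xf.k_max):
            rows.append((r, "in", k + 1, prof[k]))
            rows.append((r, "out", k + 1, prof[Xf.k_max + k]))
    return pd.DataFrame(rows, columns=["role", "direction", "length", "mean_log1p"])


def role_mix(partition: Partition, roles: RoleAssignment) -> RoleMix:
    """Fraction of members of each role inside every community."""
    if set(partition.node_labels) != set(roles.node_labels):
        raise ValueError("partition and role assignment node sets differ")
    role_of = dict(zip(roles.node_labels, roles.labels))
    k = partition.k
    counts = np.zeros((k, roles.n_roles))
    for node, c in zip(partition.node_labels, partition.labels):
        counts[c, role_of[node]] += 1
    fractions = counts / counts.sum(axis=1, keepdims=True)
    return RoleMix(
        communities=tuple(range(k)),
        fractions=fractions,
        counts=counts,
        n_roles=roles.n_roles,
    )


def cluster_role_mixes(
    mix: RoleMix,
    k: int | str = "auto",
    n_restarts: int = 50,
    seed: int = 0,
) -> OrganigramClustering:
    """k-means organigram types from community role-mix vectors.

    Plain squared-Euclidean k-means on the raw fractions, best inertia over
    ``n_restarts`` seeded initializations.  ``k="auto"`` picks k in
    2..min(8, n_communities - 1) by maximum mean silhouette; identical
    mixes are reported as degenerate with k forced to 1.
    """
    X = mix.fractions
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 communities to cluster")
    if np.allclose(X, X[0], atol=1e-12):
        logger.warning("all role mixes identical; degenerate clustering, k=1")
        return OrganigramClustering(
            k=1,
            labels=np.zeros(n, dtype=int),
            centroids=X[:1].copy(),
            scores={},
            degenerate=True,
        )

    def _fit(kk: int) -> KMeans:
        return KMeans(
            n_clusters=kk, n_init=n_restarts, random_state=int(seed) % (2**32)
        ).fit(X)

    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {k!r}")
        candidates = range(2, min(8, n - 1) + 1)
        scores: dict[int, float] = {}
        fits: dict[int, KMeans] = {}
        for kk in candidates:
            km = _fit(kk)
            if len(np.unique(km.labels_)) < 2:
                continue
            scores[kk] = float(silhouette_score(X, km.labels_))
            fits[kk] = km
        if not scores:
            raise ValueError("silhouette selection failed for every candidate k")
        best = max(scores, key=lambda kk: (scores[kk], -kk))
        km = fits[best]
        return OrganigramClustering(
            k=best, labels=km.labels_, centroids=km.cluster_centers_, scores=scores
        )
    k = int(k)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of communities {n}")
    km = _fit(k)
    return OrganigramClustering(
        k=k, labels=km.labels_, centroids=km.cluster_centers_, scores={}
    )


def retweet_cdf_table(
    roles: RoleAssignment, counts: dict | pd.Series
) -> pd.DataFrame:
    """Per-role cumulative distribution of an externally supplied per-node
    count table (e.g. retweets).  Provided as a data hook only; no count
    data ships with the package.

    Returns rows (role, value, cdf) with cdf = P(count <= value) within the
    role.
    """
    counts = pd.Series(counts)
    rows = []
    for r in range(roles.n_roles):
        members = [n for n, c in zip(roles.node_labels, roles.labels) if c == r]
        vals = counts.reindex(members).dropna().sort_values().to_numpy()
        if len(vals) == 0:
            continue
        for i, v in enumerate(vals):
            rows.append((r, float(v), (i + 1) / len(vals)))
    return pd.DataFrame(rows, columns=["role", "value", "cdf"])
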