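"""Synthetic directed networks with known community, flow and role structure.

Every generator returns its ground truth alongside the network so tests
never have to re-derive it, and regenerates with a derived seed (up to 20
attempts) until the realization is weakly connected.

``generate_flow_trap`` is the directionality benchmark: within each block,
edges follow a consistent cyclic orientation over a random ordering of the
block's nodes, so walkers circulate and directed flow is retained; between
blocks, single-direction edges all follow a fixed random total order on the
blocks, which keeps every node's expected total (in+out) degree uniform.
With equal within/between edge probabilities the symmetrized network is a
homogeneous random graph — the planted structure is visible only to a
flow-aware (directed) analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_io import DirectedNetwork
from .partition import Partition
from .roles import RoleAssignment

__all__ = [
    "PlantedFlowSpec",
    "PlantedRoleSpec",
    "generate_directed_sbm",
    "generate_flow_trap",
    "generate_hierarchical_sbm",
    "generate_role_planted",
    "toy",
    "DEFAULT_ROLE_TEMPLATE",
]

_MAX_ATTEMPTS = 20


@dataclass
class PlantedFlowSpec:
    """Directed block model: sizes, within/between probabilities, orientation."""

    block_sizes: tuple = (25, 25, 25, 25)
    p_in: float = 0.3
    p_out: float = 0.02
    orientation: str = "uniform"  # or "cyclic-within-block"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_in <= 1 and 0 <= self.p_out <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.orientation not in ("uniform", "cyclic-within-block"):
            raise ValueError(f"unknown orientation rule {self.orientation!r}")
        if min(self.block_sizes) < 1:
            raise ValueError("block sizes must be positive")


@dataclass
class PlantedRoleSpec:
    """Planted role classes with a class-to-class follow-probability matrix.

    ``wiring[a, b]`` is the probability that a node of class a follows
    (edge toward) a node of class b.
    """

    class_sizes: tuple = (20, 20, 60)
    class_names: tuple = ("reference", "mediator", "listener")
    wiring: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.0, 0.0],  # references follow nobody
                [0.5, 0.0, 0.0],  # mediators follow references
                [0.0, 0.3, 0.0],  # listeners follow mediators; no followers
            ]
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        W = np.asarray(self.wiring, dtype=float)
        k = len(self.class_sizes)
        if W.shape != (k, k):
            raise ValueError(f"wiring must be {k}x{k}")
        if (W < 0).any() or (W > 1).any():
            raise ValueError("wiring probabilities must lie in [0, 1]")
        self.wiring = W


#: The canonical three-class template (references / mediators / listeners).
DEFAULT_ROLE_TEMPLATE = PlantedRoleSpec()


def _node_names(n: int) -> tuple:
    width = len(str(n - 1))
    return tuple(f"n{i:0{width}d}" for i in range(n))


def _blocks(block_sizes) -> np.ndarray:
    return np.repeat(np.arange(len(block_sizes)), block_sizes)


def _retry_connected(build, seed: int):
    """Call ``build(rng)`` with derived seeds until weakly connected."""
    children = np.random.SeedSequence(int(seed)).spawn(_MAX_ATTEMPTS)
    for child in children:
        A = build(np.random.default_rng(child))
        g = nx.from_numpy_array(A, create_using=nx.DiGraph)
        if nx.is_weakly_connected(g):
            return A
    raise RuntimeError(
        f"no weakly connected realization in {_MAX_ATTEMPTS} attempts; "
        "increase the edge probabilities"
    )


def generate_directed_sbm(spec: PlantedFlowSpec) -> tuple[DirectedNetwork, Partition]:
    """Directed stochastic block model with independent Bernoulli edges.

    Every ordered pair (i, j), i != j, gets an edge with probability p_in
    (same block) or p_out (different blocks).
    """
    membership = _blocks(spec.block_sizes)
    n = len(membership)
    same = membership[:, None] == membership[None, :]
    P = np.where(same, spec.p_in, spec.p_out)
    np.fill_diagonal(P, 0.0)

    def build(rng: np.random.Generator) -> np.ndarray:
        return (rng.random((n, n)) < P).astype(float)

    A = _retry_connected(build, spec.seed)
    names = _node_names(n)
    return DirectedNetwork(names, A), Partition(names, membership)


def generate_flow_trap(spec: PlantedFlowSpec) -> tuple[DirectedNetwork, Partition]:
    """Planted blocks retained by orientation rather than density contrast.

    Requires ``orientation="cyclic-within-block"``.  Within a block, each
    unordered pair is linked w.p. p_in and oriented forward along the
    shorter arc of a random circular ordering of the block (walkers
    circulate).  Between blocks, each unordered pair is linked w.p. p_out
    and oriented from the earlier to the later block in a random total
    order, so every node's expected in+out degree is uniform.
    """
    if spec.orientation != "cyclic-within-block":
        raise ValueError(
            "generate_flow_trap requires orientation='cyclic-within-block'"
        )
    membership = _blocks(spec.block_sizes)
    n = len(membership)
    n_blocks = len(spec.block_sizes)

    def build(rng: np.random.Generator) -> np.ndarray:
        A = np.zeros((n, n))
        block_order = rng.permutation(n_blocks)
        block_rank = np.empty(n_blocks, dtype=int)
        block_rank[block_order] = np.arange(n_blocks)
        # circular position of each node within its block
        pos = np.empty(n, dtype=int)
        for b in range(n_blocks):
            idx = np.flatnonzero(membership == b)
            pos[idx] = rng.permutation(len(idx))
        sizes = np.asarray(spec.block_sizes)
        for i in range(n):
            for j in range(i + 1, n):
                if membership[i] == membership[j]:
                    if rng.random() >= spec.p_in:
                        continue
                    nb = sizes[membership[i]]
                    fwd = (pos[j] - pos[i]) % nb
                    if fwd < nb - fwd or (2 * fwd == nb and pos[i] < pos[j]):
                        A[i, j] = 1.0
                    else:
                        A[j, i] = 1.0
                else:
                    if rng.random() >= spec.p_out:
                        continue
                    if block_rank[membership[i]] < block_rank[membership[j]]:
                        A[i, j] = 1.0
                    else:
                        A[j, i] = 1.0
        return A

    A = _retry_connected(build, spec.seed)
    names = _node_names(n)
    return DirectedNetwork(names, A), Partition(names, membership)


def generate_hierarchical_sbm(
    n_super: int = 2,
    n_sub: int = 2,
    sub_size: int = 12,
    p_sub: float = 0.45,
    p_super: float = 0.1,
    p_cross: float = 0.01,
    seed: int = 0,
) -> tuple[DirectedNetwork, Partition, Partition]:
    """Two-level planted hierarchy: sub-blocks nested in super-blocks.

    Edge probabilities: ``p_sub`` within a sub-block, ``p_super`` between
    sub-blocks of the same super-block, ``p_cross`` otherwise.  Returns
    (network, sub-block partition, super-block partition); in a sweep the
    sub-blocks merge before the super-blocks do.
    """
    n = n_super * n_sub * sub_size
    sub = np.repeat(np.arange(n_super * n_sub), sub_size)
    sup = sub // n_sub
    P = np.where(
        sub[:, None] == sub[None, :],
        p_sub,
        np.where(sup[:, None] == sup[None, :], p_super, p_cross),
    )
    np.fill_diagonal(P, 0.0)

    def build(rng: np.random.Generator) -> np.ndarray:
        return (rng.random((n, n)) < P).astype(float)

    A = _retry_connected(build, seed)
    names = _node_names(n)
    return DirectedNetwork(names, A), Partition(names, sub), Partition(names, sup)


def generate_role_planted(
    spec: PlantedRoleSpec = DEFAULT_ROLE_TEMPLATE,
) -> tuple[DirectedNetwork, RoleAssignment]:
    """Bernoulli edges per ordered class pair (edge = follower -> followee).

    The default template plants 20 references (followed w.p. 0.5 by the
    mediators, follow nobody), 20 mediators (follow references w.p. 0.5,
    followed by listeners w.p. 0.3) and 60 listeners (follow mediators,
    no followers of their own).  The pure-relay wiring keeps each planted
    class unimodal in walk-count feature space, so the three roles are a
    well-posed ground truth; mixing direct listener-to-reference follows
    would split the listener class into genuine sub-roles.
    """
    membership = _blocks(spec.class_sizes)
    n = len(membership)
    P = spec.wiring[membership[:, None], membership[None, :]]
    np.fill_diagonal(P, 0.0)

    def build(rng: np.random.Generator) -> np.ndarray:
        return (rng.random((n, n)) < P).astype(float)

    A = _retry_connected(build, spec.seed)
    names = _node_names(n)
    return DirectedNetwork(names, A), RoleAssignment(
        node_labels=names,
        labels=membership.copy(),
        n_roles=len(spec.class_sizes),
    )


def toy(name: str, *sizes: int) -> DirectedNetwork:
    """Canonical deterministic graphs used throughout the example suites.

    ``cycle(n)``, ``path(n)``, ``star_in(n)`` (leaves -> hub), ``star_out(n)``
    (hub -> leaves), ``ring_of_cliques(k, m)`` (k directed m-cliques joined
    cyclically by single edges).
    """
    if name == "cycle":
        (n,) = sizes
        names = _node_names(n)
        A = np.zeros((n, n))
        for i in range(n):
            A[i, (i + 1) % n] = 1.0
        return DirectedNetwork(names, A)
    if name == "path":
        (n,) = sizes
        names = _node_names(n)
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = 1.0
        return DirectedNetwork(names, A)
    if name == "star_in":
        (n,) = sizes
        names = _node_names(n)
        A = np.zeros((n, n))
        A[1:, 0] = 1.0
        return DirectedNetwork(names, A)
    if name == "star_out":
        (n,) = sizes
        names = _node_names(n)
        A = np.zeros((n, n))
        A[0, 1:] = 1.0
        return DirectedNetwork(names, A)
    if name == "ring_of_cliques":
        k, m = sizes
        n = k * m
        names = _node_names(n)
        A = np.zeros((n, n))
        for b in range(k):
            lo = b * m
            for i in range(m):
                for j in range(m):
                    if i != j:
                        A[lo + i, lo + j] = 1.0
            A[lo, ((b + 1) % k) * m] = 1.0
        return DirectedNetwork(names, A)
    raise ValueError(f"unknown toy graph {name!r}")
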