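"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use naive algorithms (walk enumeration, long-double
Taylor series, exhaustive partition search) so they stay independent of the
implementation paths they check.
"""
from __future__ import annotations

import numpy as np
import pytest

from flowscope import DirectedNetwork, toy


# ---------------------------------------------------------------------------
# Small digraph fixtures (<= 6 nodes, <= 12 edges, no self-loops)
# ---------------------------------------------------------------------------

def _random_digraph(n: int, p: float, seed: int) -> DirectedNetwork:
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(A, 0.0)
    if A.sum() == 0:
        A[0, 1] = 1.0
    return DirectedNetwork(tuple(f"v{i}" for i in range(n)), A)


@pytest.fixture(scope="session")
def small_digraph_suite() -> list[DirectedNetwork]:
    nets = [
        toy("path", 3),
        toy("cycle", 3),
        toy("cycle", 5),
        toy("star_in", 5),
        toy("star_out", 4),
    ]
    nets += [_random_digraph(n, p, seed)
             for n, p, seed in ((4, 0.4, 1), (5, 0.35, 2), (6, 0.3, 3),
                                (6, 0.25, 4), (5, 0.5, 5))]
    for net in nets:
        assert net.N <= 6 and net.n_edges <= 12 and not net.has_self_loops
    return nets


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def walk_count(net: DirectedNetwork, node_index: int, length: int,
               direction: str) -> float:
    """Exhaustive recursive enumeration of walks of a given length.

    ``direction="out"`` counts walks starting at the node, ``"in"`` walks
    ending at it.  Weighted walks multiply edge weights along the walk.
    """
    A = net.adjacency if direction == "out" else net.adjacency.T

    def rec(i: int, remaining: int) -> float:
        if remaining == 0:
            return 1.0
        return sum(A[i, j] * rec(j, remaining - 1)
                   for j in range(net.N) if A[i, j] != 0)

    return rec(node_index, length)


def brute_stability(pi: np.ndarray, P: np.ndarray, labels: np.ndarray) -> float:
    """Element-wise double sum over node pairs in the same community."""
    n = len(pi)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                total += pi[i] * P[i, j] - pi[i] * pi[j]
    return total


def taylor_expm(X: np.ndarray, tol: float = 1e-30) -> np.ndarray:
    """Matrix exponential by scaling-and-squaring with an extended-precision
    Taylor series (numpy long double)."""
    X = X.astype(np.longdouble)
    s = max(0, int(np.ceil(np.log2(max(1.0, float(np.abs(X).sum(axis=1).max()))))))
    Y = X / (2 ** s)
    result = np.eye(len(X), dtype=np.longdouble)
    term = np.eye(len(X), dtype=np.longdouble)
    k = 0
    while True:
        k += 1
        term = term @ Y / k
        result = result + term
        if float(np.abs(term).max()) < tol or k > 200:
            break
    for _ in range(s):
        result = result @ result
    return result.astype(float)


def set_partitions(n: int):
    """Yield every partition of range(n) as a label array."""
    def rec(i, parts):
        if i == n:
            lab = np.empty(n, dtype=np.int64)
            for c, members in enumerate(parts):
                for m in members:
                    lab[m] = c
            yield lab
            return
        for j in range(len(parts)):
            parts[j].append(i)
            yield from rec(i + 1, parts)
            parts[j].pop()
        parts.append([i])
        yield from rec(i + 1, parts)
        parts.pop()

    yield from rec(0, [])


def tree_path_max_edge(edges: list, D: np.ndarray, a: int, b: int) -> float:
    """Maximum edge weight on the unique tree path a..b by exhaustive DFS."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def dfs(u, target, seen, best):
        if u == target:
            return best
        for v in adj.get(u, []):
            if v not in seen:
                out = dfs(v, target, seen | {v}, max(best, D[u, v]))
                if out is not None:
                    return out
        return None

    return dfs(a, b, {a}, 0.0)
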