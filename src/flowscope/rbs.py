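"""Role-based similarity (RBS) from scaled walk counts of all lengths.

Each node's feature vector collects its numbers of incoming and outgoing
walks of lengths 1..K_max, geometrically damped by alpha = beta / lambda1
(beta in (0,1), lambda1 the spectral radius of the adjacency matrix) so the
"all lengths" series converges:

    column k of the in-block  = alpha^k * (A^T)^k 1   (walks ending at i)
    column k of the out-block = alpha^k *  A^k    1   (walks starting at i)

Walks may repeat nodes, as implied by the matrix powers.  Pairwise cosine
similarity of the feature rows gives the N x N matrix Y: nodes with similar
profiles of incoming and outgoing flow at every range have y close to 1 and
play the same flow role — from references (attract flow) through mediators
to listeners (emit flow).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import DirectedNetwork

__all__ = [
    "FlowFeatureMatrix",
    "SimilarityMatrix",
    "leading_eigenvalue",
    "build_feature_matrix",
    "cosine_similarity",
    "DEFAULT_BETA",
]

DEFAULT_BETA = 0.95

_EIG_TOL = 1e-10
_AUTO_STOP = 1e-8


@dataclass
class FlowFeatureMatrix:
    """N x 2 K_max matrix X(alpha): incoming-walk block, then outgoing."""

    node_labels: tuple
    X: np.ndarray = field(repr=False)
    alpha: float = 1.0
    beta: float = DEFAULT_BETA
    k_max: int = 1
    lambda1: float = 0.0
    adjacency: np.ndarray | None = field(repr=False, default=None)

    @property
    def N(self) -> int:
        return len(self.node_labels)

    def unscaled(self) -> np.ndarray:
        """Raw walk counts: column k of each block divided by alpha^k.

        When the adjacency is available the counts are recomputed by direct
        iteration, which is exact on unweighted graphs as long as they fit
        in float integers; otherwise (or on overflow) the scaled columns
        are divided back by alpha^k.
        """
        if self.adjacency is not None:
            A = self.adjacency
            v = np.ones(self.N)
            w = np.ones(self.N)
            cols_in, cols_out = [], []
            for _ in range(self.k_max):
                v = A.T @ v
                w = A @ w
                if not (np.isfinite(v).all() and np.isfinite(w).all()):
                    break
                cols_in.append(v.copy())
                cols_out.append(w.copy())
            if len(cols_in) == self.k_max:
                return np.column_stack(cols_in + cols_out)
        scale = self.alpha ** np.arange(1, self.k_max + 1, dtype=float)
        return self.X / np.concatenate([scale, scale])

    def in_block(self) -> np.ndarray:
        return self.X[:, : self.k_max]

    def out_block(self) -> np.ndarray:
        return self.X[:, self.k_max :]


@dataclass
class SimilarityMatrix:
    """Symmetric cosine-similarity matrix Y with unit diagonal."""

    node_labels: tuple
    Y: np.ndarray = field(repr=False)


def leading_eigenvalue(A: np.ndarray, tol: float = _EIG_TOL,
                       max_iter: int = 100_000) -> float:
    """Spectral radius of a nonnegative matrix by power iteration.

    Iterates on the diagonally shifted matrix A + I, whose self-loops make
    the iteration aperiodic (so it converges on directed cycles too) and
    whose spectral radius is exactly rho(A) + 1 for nonnegative A.
    Nilpotent (DAG) adjacency is detected exactly — the unshifted iterate
    of the all-ones vector reaches zero — and returns 0.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    n = len(A)
    # exact DAG detection: walks die out after at most n steps
    v = np.ones(n)
    for _ in range(n):
        v = A @ v
        if not v.any():
            return 0.0
    v = np.ones(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = A @ v + v  # (A + I) v
        norm = np.linalg.norm(w)
        w /= norm
        lam_new = float(w @ (A @ w + w))
        if abs(lam_new - lam) < tol and np.linalg.norm(w - v) < 1e-8:
            v = w
            lam = lam_new
            break
        v = w
        lam = lam_new
    return max(lam - 1.0, 0.0)


def build_feature_matrix(
    net: DirectedNetwork,
    beta: float = DEFAULT_BETA,
    k_max: int | str = "auto",
) -> FlowFeatureMatrix:
    """Accumulate scaled in/out walk-count features for every node.

    Iterates v_k = alpha A^T v_{k-1} and w_k = alpha A w_{k-1} from
    v_0 = w_0 = 1.  With ``k_max="auto"`` the iteration stops at the first
    k where both columns' max norms fall below 1e-8 times the largest
    earlier column (capped at 4 N).  If the adjacency is nilpotent
    (lambda1 = 0, only finitely many walks) alpha defaults to 1.
    """
    if not (0 < beta < 1):
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if net.N < 2:
        raise ValueError("need at least 2 nodes")
    A = net.adjacency
    lam = leading_eigenvalue(A)
    alpha = 1.0 if lam == 0.0 else beta / lam

    auto = isinstance(k_max, str)
    if auto:
        if k_max != "auto":
            raise ValueError(f"k_max must be an integer or 'auto', got {k_max!r}")
        cap = 4 * net.N
    else:
        cap = int(k_max)
        if cap < 1:
            raise ValueError("k_max must be >= 1")

    v = np.ones(net.N)
    w = np.ones(net.N)
    in_cols: list[np.ndarray] = []
    out_cols: list[np.ndarray] = []
    peak = 0.0
    for _ in range(cap):
        v = alpha * (A.T @ v)
        w = alpha * (A @ w)
        size = max(np.abs(v).max(), np.abs(w).max())
        if auto and in_cols and size < _AUTO_STOP * peak:
            break
        in_cols.append(v.copy())
        out_cols.append(w.copy())
        peak = max(peak, size)
        if size == 0.0:  # DAG walks exhausted
            break
    X = np.column_stack(in_cols + out_cols)
    return FlowFeatureMatrix(
        node_labels=net.node_labels,
        X=X,
        alpha=alpha,
        beta=beta,
        k_max=len(in_cols),
        lambda1=lam,
        adjacency=A,
    )


def cosine_similarity(Xf: FlowFeatureMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarities of the feature rows.

    All-zero rows (isolated nodes) get similarity 0 off-diagonal and 1 on
    the diagonal.  Entries lie in [0, 1] because the features are
    nonnegative.
    """
    X = Xf.X
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    Y = U @ U.T
    np.clip(Y, 0.0, 1.0, out=Y)
    np.fill_diagonal(Y, 1.0)
    return SimilarityMatrix(node_labels=Xf.node_labels, Y=Y)
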