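"""Within-class k-NN heat-kernel graph and local within-class preserving scatter.

The graph joins each sample to its k nearest neighbors *of the same class*
(symmetric OR rule), weights edges by the heat kernel exp(-d^2/t) and
row-normalizes.  The scatter matrix accumulates outer products of the
residual between each sample and the weighted average of its neighbors;
penalizing w' S w preserves local class geometry in the learned direction.

Conventions
-----------
* The row-normalization resolves the self-referential normalizer in the
  graph definition by dividing each raw heat-weight row by its raw sum.
* k-NN ties break toward the smaller sample index (determinism).
* Isolated nodes (singleton class, or no within-class neighbor) contribute
  zero to the scatter: with no neighborhood there is nothing to preserve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset

__all__ = [
    "GraphParams",
    "WithinClassGraph",
    "pairwise_sq_dists",
    "kernel_sq_dists",
    "knn_within_class",
    "heat_weights",
    "build_graph",
    "scatter_linear",
    "scatter_kernel",
]


@dataclass
class GraphParams:
    """k: within-class neighbor count; t: heat-kernel width (> 0)."""

    k: int = 3
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t <= 0:
            raise ValueError("t must be > 0")


@dataclass
class WithinClassGraph:
    """Row-normalized heat-kernel weights W on the symmetric within-class
    k-NN support; rows with at least one edge sum to 1."""

    W: np.ndarray
    edge_support: np.ndarray


def pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between all sample pairs."""
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    return np.clip(d2, 0.0, None)


def kernel_sq_dists(K: np.ndarray) -> np.ndarray:
    """Kernel-induced squared distances K_ii + K_jj - 2 K_ij."""
    diag = np.diag(K)
    d2 = diag[:, None] + diag[None, :] - 2.0 * K
    np.fill_diagonal(d2, 0.0)
    return np.clip(d2, 0.0, None)


def knn_within_class(y: np.ndarray, sq_dists: np.ndarray, k: int) -> np.ndarray:
    """Boolean edge support of the within-class k-NN graph (OR-symmetrized,
    no self edges).  k is truncated to class size - 1 with a warning."""
    y = np.asarray(y)
    N = y.shape[0]
    support = np.zeros((N, N), dtype=bool)
    for label in (1, -1):
        idx = np.flatnonzero(y == label)
        m = idx.size
        if m <= 1:
            continue
        kk = k
        if kk > m - 1:
            warnings.warn(
                f"k={k} exceeds class size - 1 ({m - 1}); truncating", stacklevel=2
            )
            kk = m - 1
        D = sq_dists[np.ix_(idx, idx)]
        for a in range(m):
            row = D[a].copy()
            row[a] = np.inf
            # stable argsort => ties broken by smaller index
            nbrs = np.argsort(row, kind="stable")[:kk]
            support[idx[a], idx[nbrs]] = True
    return support | support.T


def heat_weights(edge_support: np.ndarray, sq_dists: np.ndarray, t: float) -> WithinClassGraph:
    """Heat-kernel weights exp(-d^2/t) on supported edges, row-normalized by
    the raw row sum; rows with no edges stay all-zero."""
    if t <= 0:
        raise ValueError("t must be > 0")
    # subtract the row-wise minimum supported distance before exponentiating:
    # invariant under the row normalization, but immune to exp underflow
    masked = np.where(edge_support, sq_dists, np.inf)
    row_min = masked.min(axis=1)
    row_min[~np.isfinite(row_min)] = 0.0
    raw = np.where(edge_support, np.exp(-(sq_dists - row_min[:, None]) / t), 0.0)
    sums = raw.sum(axis=1)
    W = np.zeros_like(raw)
    nz = sums > 0
    W[nz] = raw[nz] / sums[nz, None]
    return WithinClassGraph(W=W, edge_support=edge_support)


def build_graph(
    y: np.ndarray, sq_dists: np.ndarray, params: GraphParams
) -> WithinClassGraph:
    """Support + weights in one call."""
    support = knn_within_class(y, sq_dists, params.k)
    return heat_weights(support, sq_dists, params.t)


def scatter_linear(ds: Dataset, G: WithinClassGraph) -> np.ndarray:
    """Local within-class preserving scatter S (n x n).

    S = sum_i r_i r_i' with residual r_i = x_i - sum_j W_ij x_j; since W is
    within-class only this equals the per-class matrix form
    X_c' (I - W_c)' (I - W_c) X_c summed over both classes.  Isolated rows
    contribute zero.
    """
    W = G.W
    R = ds.X - W @ ds.X
    isolated = W.sum(axis=1) == 0
    R[isolated] = 0.0
    S = R.T @ R
    return 0.5 * (S + S.T)


def scatter_kernel(
    K: np.ndarray, y: np.ndarray, G: WithinClassGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-side scatter terms, one per class.

    For class c with member indices C (size m_c),
    T_c = K_c A_c' A_c K_c'  with  K_c = K[:, C]  (N x m_c)  and
    A_c = I - W_c the residual operator on the class block of the graph.
    T_1 + T_2 plays the role eta-weighted locality regularizer inside Q.
    Isolated rows of A_c are zeroed (same convention as the linear case).
    """
    y = np.asarray(y)
    if K.shape[0] != K.shape[1] or K.shape[0] != y.shape[0]:
        raise ValueError("Gram matrix and labels have mismatched dimensions")
    terms = []
    for label in (1, -1):
        idx = np.flatnonzero(y == label)
        Kc = K[:, idx]
        Wc = G.W[np.ix_(idx, idx)]
        A = np.eye(idx.size) - Wc
        A[Wc.sum(axis=1) == 0] = 0.0
        B = A @ Kc.T
        T = B.T @ B
        terms.append(0.5 * (T + T.T))
    return terms[0], terms[1]


def check_psd(S: np.ndarray, rtol: float = 1e-8) -> bool:
    """True when S is symmetric with smallest eigenvalue >= -rtol * ||S||."""
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        return False
    eigs = np.linalg.eigvalsh(0.5 * (S + S.T))
    scale = max(np.abs(eigs).max(), 1e-300)
    return bool(eigs.min() >= -rtol * scale)
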