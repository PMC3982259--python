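"""Independent reference implementations used only as test oracles.

Everything here is deliberately written differently from the package
path it checks: brute-force enumeration, scalar double loops, and a
second QP solver on a re-parameterized formulation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import Bounds, minimize


def reference_qp_objective(H, u, nu, pos_mask):
    """Solve min 1/2 a'Ha, class sums = nu, 0 <= a <= u by eliminating one
    variable per class and running SLSQP on the reduced problem.

    Returns the optimal objective value.  Independent of the package's
    trust-constr + active-set path in both parameterization and algorithm.
    """
    H = np.asarray(H, float)
    u = np.asarray(u, float)
    pos_mask = np.asarray(pos_mask, bool)
    N = u.size
    dep_pos = int(np.flatnonzero(pos_mask)[-1])
    dep_neg = int(np.flatnonzero(~pos_mask)[-1])
    keep = np.array([i for i in range(N) if i not in (dep_pos, dep_neg)])

    def expand(z):
        a = np.empty(N)
        a[keep] = z
        a[dep_pos] = nu - z[pos_mask[keep]].sum()
        a[dep_neg] = nu - z[~pos_mask[keep]].sum()
        return a

    def f(z):
        a = expand(z)
        return 0.5 * a @ H @ a

    # feasible start: mass proportional to the caps within each class
    a0 = np.empty(N)
    for mask in (pos_mask, ~pos_mask):
        a0[mask] = nu * u[mask] / u[mask].sum()
    z0 = a0[keep]

    cons = [
        {"type": "ineq", "fun": lambda z: expand(z)[dep_pos]},
        {"type": "ineq", "fun": lambda z: u[dep_pos] - expand(z)[dep_pos]},
        {"type": "ineq", "fun": lambda z: expand(z)[dep_neg]},
        {"type": "ineq", "fun": lambda z: u[dep_neg] - expand(z)[dep_neg]},
    ]
    res = minimize(
        f,
        z0,
        method="SLSQP",
        bounds=Bounds(np.zeros(keep.size), u[keep]),
        constraints=cons,
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    return float(f(res.x))


def primal_objective_and_solution(X, y, mu, nu, v1, v2, eta, S):
    """Direct SLSQP solve of the primal (variables w, b, rho >= 0, xi >= 0).

    Valid as an oracle only where the learned rho is strictly positive, the
    regime in which the printed dual and the rho-constrained primal agree.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    N, n = X.shape
    pos = y == 1
    m1, m2 = int(pos.sum()), int((~pos).sum())

    def unpack(z):
        return z[:n], z[n], z[n + 1], z[n + 2 :]

    def fobj(z):
        w, b, rho, xi = unpack(z)
        return (
            0.5 * w @ w
            - nu * rho
            + (mu[pos] * xi[pos]).sum() / (v1 * m1)
            + (mu[~pos] * xi[~pos]).sum() / (v2 * m2)
            + 0.5 * eta * w @ S @ w
        )

    A = np.zeros((N, n + 2 + N))
    for i in range(N):
        if y[i] == 1:
            A[i, :n] = X[i]
            A[i, n] = 1.0
        else:
            A[i, :n] = -X[i]
            A[i, n] = -1.0
            A[i, n + 1] = -1.0
        A[i, n + 2 + i] = 1.0
    lb = np.concatenate([[-np.inf] * (n + 1), [0.0], np.zeros(N)])
    z0 = np.zeros(n + 2 + N)
    z0[n + 2 :] = 2.0
    res = minimize(
        fobj,
        z0,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda z: A @ z - 1.0}],
        bounds=Bounds(lb, np.full(n + 2 + N, np.inf)),
        options={"maxiter": 5000, "ftol": 1e-14},
    )
    w, b, rho, xi = unpack(res.x)
    return float(fobj(res.x)), w, float(b), float(rho)


def brute_knn_support(y, sq_dists, k):
    """All-pairs-sort within-class k-NN support with OR symmetrization."""
    y = np.asarray(y)
    N = y.size
    support = np.zeros((N, N), dtype=bool)
    for i in range(N):
        same = [j for j in range(N) if j != i and y[j] == y[i]]
        kk = min(k, len(same))
        ranked = sorted(same, key=lambda j: (sq_dists[i, j], j))[:kk]
        for j in ranked:
            support[i, j] = True
    return support | support.T


def scatter_outer_products(X, W):
    """Residual outer-product accumulation of the locality scatter; isolated
    rows (zero weight row) contribute nothing."""
    X = np.asarray(X, float)
    N, n = X.shape
    S = np.zeros((n, n))
    for i in range(N):
        if W[i].sum() == 0:
            continue
        r = X[i] - sum(W[i, j] * X[j] for j in range(N))
        S += np.outer(r, r)
    return S


def membership_linear_scalar(X, y, delta):
    """Scalar-loop evaluation of the linear fuzzy membership."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    mu = np.empty(y.size)
    for label in (1, -1):
        idx = [i for i in range(y.size) if y[i] == label]
        mean = X[idx].mean(axis=0)
        dmax = max(np.sqrt(((X[j] - mean) ** 2).sum()) for j in idx)
        for i in idx:
            d = np.sqrt(((X[i] - mean) ** 2).sum())
            mu[i] = 1.0 - d / (dmax + delta)
    return mu


def feature_distance_double_loop(K, i, members):
    """Kernel-expansion feature-space distance, written as explicit sums."""
    members = list(members)
    m = len(members)
    s1 = sum(K[i, j] for j in members)
    s2 = sum(K[s, t] for s in members for t in members)
    return float(np.sqrt(max(K[i, i] - 2.0 * s1 / m + s2 / (m * m), 0.0)))
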