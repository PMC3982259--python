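"""Kernelized FSVM-CIP.

The linear machinery carries over through the representer expansion
w = sum_i beta_i phi(x_i).  With Gram matrix K, within-class graph built
from kernel-induced distances and kernel-side scatter terms T_1, T_2:

    Q = K + eta * (T_1 + T_2)
    M = Y K' Q^{-1} K Y          (symmetric PSD; checked at runtime)

The dual in alpha is the same box-equality QP as the linear case with M in
place of H; then beta* = Q^{-1} K Y alpha* and the decision function is
f(x) = sgn(sum_i beta_i* K(x, x_i) + b*).  Thresholds b*, rho* come from
the active margin constraints of the support vectors, exactly as in the
linear case, using the training decision values (K beta*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import qp
from .datasets import Dataset
from .linear import HyperParams, MarginBoundReport, upper_bounds, verify_margin_bounds
from .locality import WithinClassGraph, build_graph, kernel_sq_dists, scatter_kernel
from .membership import MembershipParams, compute_membership

__all__ = [
    "KernelSpec",
    "KernelModel",
    "gram",
    "tau_squared",
    "sigma_grid",
    "assemble_Q",
    "assemble_M",
    "fit_kernel",
    "decision_kernel",
    "predict_kernel",
    "KernelFSVMCIP",
]


@dataclass
class KernelSpec:
    """Kernel choice.  The Gaussian kernel is exp(-||u - v||^2 / sigma);
    the customary spread heuristic sets sigma near tau^2, the mean squared
    norm of the training rows."""

    name: str = "rbf"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.name == "rbf" and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def gram(X: np.ndarray, Xother: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel evaluations K[a, b] = K(X[a], Xother[b])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xother = np.atleast_2d(np.asarray(Xother, dtype=float))
    if X.shape[1] != Xother.shape[1]:
        raise ValueError("feature dimensions differ")
    if spec.name == "linear":
        return X @ Xother.T
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Xother * Xother, axis=1)[None, :]
        - 2.0 * X @ Xother.T
    )
    return np.exp(-np.clip(d2, 0.0, None) / spec.sigma)


def tau_squared(X: np.ndarray) -> float:
    """Mean squared row norm of the training data (RBF spread heuristic)."""
    return float(np.mean(np.sum(np.asarray(X, dtype=float) ** 2, axis=1)))


def sigma_grid(X: np.ndarray) -> list[float]:
    """The nine-point spread grid {tau^2/16, ..., 16 tau^2}."""
    t2 = tau_squared(X)
    return [t2 * 2.0**p for p in range(-4, 5)]


def assemble_Q(
    K: np.ndarray, y: np.ndarray, G: WithinClassGraph, eta: float
) -> np.ndarray:
    """Q = K + eta * (T_1 + T_2); symmetric, PSD as a sum of Gram-like terms."""
    T1, T2 = scatter_kernel(K, y, G)
    Q = K + eta * (T1 + T2)
    return 0.5 * (Q + Q.T)


def _factor_with_ridge(Q: np.ndarray):
    """Cholesky of Q, escalating a tiny trace-scaled ridge when the
    factorization fails (Q is only guaranteed PSD, not PD)."""
    N = Q.shape[0]
    base = max(np.trace(Q) / N, 1e-300)
    for ridge in (0.0, 1e-10 * base, 1e-8 * base, 1e-6 * base):
        try:
            return cho_factor(Q + ridge * np.eye(N)), ridge
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("Q numerically singular beyond ridge capacity")


def assemble_M(
    K: np.ndarray, y: np.ndarray, Q: np.ndarray, psd_rtol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """M = Y K' Q^{-1} K Y via symmetric solves; the PSD property of M is
    asserted at runtime (min eigenvalue >= -psd_rtol * ||M||)."""
    factor, ridge = _factor_with_ridge(Q)
    Z = cho_solve(factor, K)  # Q^{-1} K
    M = (y[:, None] * y[None, :]) * (K.T @ Z)
    M = 0.5 * (M + M.T)
    eigs = np.linalg.eigvalsh(M)
    scale = max(float(np.abs(eigs).max()), 1e-300)
    if eigs.min() < -psd_rtol * scale:
        raise np.linalg.LinAlgError(
            f"M is not PSD within tolerance (min eig {eigs.min():.3e})"
        )
    return M, ridge


@dataclass
class KernelModel:
    beta: np.ndarray
    alpha: np.ndarray
    b_star: float
    rho_star: float
    sv1: np.ndarray
    sv2: np.ndarray
    xi: np.ndarray
    me1: np.ndarray
    me2: np.ndarray
    u: np.ndarray
    margins: np.ndarray  # training decision values without b
    train_X: np.ndarray
    spec: KernelSpec
    hp: HyperParams
    mu: np.ndarray
    tol_sv: float
    threshold_label_factor: bool
    ridge: float
    metadata: dict = field(default_factory=dict)


def fit_kernel(
    ds: Dataset,
    mu: np.ndarray,
    hp: HyperParams,
    spec: KernelSpec,
    sv_mode: str = "interior",
    threshold_label_factor: bool = False,
) -> KernelModel:
    """Assemble Q and M, solve the dual, recover beta*, b*, rho*.

    ``threshold_label_factor`` reproduces a printed variant that inserts an
    extra label factor y_j inside the threshold expansions; the default
    (False) is the variant consistent with the decision function and with
    the linear-kernel reduction, and the choice is recorded in metadata.
    """
    K = gram(ds.X, ds.X, spec)
    G = build_graph(ds.y, kernel_sq_dists(K), hp.graph)
    Q = assemble_Q(K, ds.y, G, hp.eta)
    M, ridge = assemble_M(K, ds.y, Q)
    u = upper_bounds(mu, hp, ds.pos_mask)
    res = qp.solve_box_equality_qp(M, u, hp.nu, ds.pos_mask)
    alpha = res.alpha

    factor, _ = _factor_with_ridge(Q)
    beta = cho_solve(factor, K @ (ds.y * alpha))
    g = K @ beta  # training decision values (no bias)
    g_thr = K @ (ds.y * beta) if threshold_label_factor else g

    tol_sv = 1e-8 * float(u.max())
    sv1 = np.flatnonzero(ds.pos_mask & (alpha > tol_sv))
    sv2 = np.flatnonzero(~ds.pos_mask & (alpha > tol_sv))
    if sv1.size == 0 or sv2.size == 0:
        raise ValueError(
            "a class has no support vectors; increase nu or decrease that "
            "class's v parameter"
        )

    def _thr(mask):
        sv = mask & (alpha > tol_sv)
        if sv_mode == "interior":
            interior = sv & (alpha < u - tol_sv)
            if interior.any():
                return np.flatnonzero(interior)
        return np.flatnonzero(sv)

    t1, t2 = _thr(ds.pos_mask), _thr(~ds.pos_mask)
    b_star = 1.0 - float(g_thr[t1].mean())
    rho_star = -1.0 - b_star - float(g_thr[t2].mean())

    xi = np.where(
        ds.pos_mask,
        np.clip(1.0 - (g + b_star), 0.0, None),
        np.clip(1.0 + rho_star + (g + b_star), 0.0, None),
    )
    me1 = np.flatnonzero(ds.pos_mask & (xi > tol_sv))
    me2 = np.flatnonzero(~ds.pos_mask & (xi > tol_sv))
    return KernelModel(
        beta=beta,
        alpha=alpha,
        b_star=b_star,
        rho_star=rho_star,
        sv1=sv1,
        sv2=sv2,
        xi=xi,
        me1=me1,
        me2=me2,
        u=u,
        margins=g,
        train_X=ds.X.copy(),
        spec=spec,
        hp=hp,
        mu=mu,
        tol_sv=tol_sv,
        threshold_label_factor=threshold_label_factor,
        ridge=ridge,
        metadata={
            "threshold_variant": "label_factor" if threshold_label_factor else "y_free",
            "solver_status": res.status,
        },
    )


def decision_kernel(model: KernelModel, Xnew: np.ndarray) -> np.ndarray:
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"expected {model.train_X.shape[1]} features, got {Xnew.shape[1]}"
        )
    return gram(Xnew, model.train_X, model.spec) @ model.beta + model.b_star


def predict_kernel(model: KernelModel, Xnew: np.ndarray) -> np.ndarray:
    """f(x) = sgn(sum_i beta_i K(x, x_i) + b*), ties to +1."""
    return np.where(decision_kernel(model, Xnew) >= 0.0, 1, -1)


class KernelFSVMCIP:
    """Kernel estimator: feature-space memberships by default, kernel graph,
    Q/M assembly, dual QP, thresholds."""

    def __init__(
        self,
        hp: HyperParams | None = None,
        spec: KernelSpec | None = None,
        sv_mode: str = "interior",
        threshold_label_factor: bool = False,
    ):
        self.hp = hp or HyperParams()
        self.spec = spec or KernelSpec()
        self.sv_mode = sv_mode
        self.threshold_label_factor = threshold_label_factor

    def fit(self, ds: Dataset) -> "KernelFSVMCIP":
        K = gram(ds.X, ds.X, self.spec)
        params = self.hp.membership
        if params.space != "feature":
            params = MembershipParams(
                family=params.family, delta=params.delta, lam=params.lam, space="feature"
            )
        self.mu_ = compute_membership(ds, params, K=K)
        self.model_ = fit_kernel(
            ds,
            self.mu_,
            self.hp,
            self.spec,
            sv_mode=self.sv_mode,
            threshold_label_factor=self.threshold_label_factor,
        )
        self.report_ = self._margin_bound_report(ds)
        self.train_ = ds
        return self

    def _margin_bound_report(self, ds: Dataset) -> MarginBoundReport:
        m = self.model_

        class _Shim:
            pass

        shim = _Shim()
        shim.me1, shim.me2, shim.sv1, shim.sv2 = m.me1, m.me2, m.sv1, m.sv2
        return verify_margin_bounds(shim, m.mu, m.hp, ds.pos_mask)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return decision_kernel(self.model_, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_kernel(self.model_, X)
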