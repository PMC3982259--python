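"""Linear fuzzy SVM for class imbalance (FSVM-CIP), primal/dual machinery.

Model
-----
With canonical ordering (positives 1..m1, negatives m1+1..N) the primal is

    min_{w,b,rho,xi}  1/2 w'w - nu*rho
                      + 1/(v1*m1) sum_{i<=m1} mu_i xi_i
                      + 1/(v2*m2) sum_{j>m1}  mu_j xi_j
                      + eta/2 w' S w
    s.t.   w'x_i + b  >=  1 - xi_i          (positives)
         -(w'x_j + b) >=  1 + rho - xi_j    (negatives)
           xi >= 0,  rho >= 0,

where S is the local within-class preserving scatter and mu the fuzzy
memberships.  The majority class must clear margin 1, the minority class
margin 1 + rho with rho learned, and the per-sample cost mu/(v_c m_c) lets
class-specific cost scaling counteract hyperplane skew.

The dual is the box-equality QP of :mod:`fsvmcip.qp` with
H_ij = y_i y_j x_i' (I + eta*S)^{-1} x_j, upper bounds u = mu/(v_c m_c)
and both class sums pinned at nu.  The primal solution is recovered via
w* = (I + eta*S)^{-1} sum_i alpha_i y_i x_i; b* and rho* come from the
active margin constraints of the support vectors (by default the strictly
interior ones, whose slacks are exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import qp
from .datasets import Dataset
from .locality import GraphParams, build_graph, pairwise_sq_dists, scatter_linear
from .membership import MembershipParams, compute_membership

__all__ = [
    "HyperParams",
    "DualProblem",
    "DualSolution",
    "MarginBoundReport",
    "assemble_linear_dual",
    "solve_dual",
    "recover_linear",
    "predict_linear",
    "decision_linear",
    "verify_margin_bounds",
    "LinearFSVMCIP",
]


@dataclass
class HyperParams:
    """nu: margin-mass parameter; v1, v2: per-class cost scalers (smaller v
    means costlier errors for that class); eta: scatter-margin tradeoff."""

    nu: float = 1.0
    v1: float = 0.01
    v2: float = 0.01
    eta: float = 1.0
    graph: GraphParams = field(default_factory=GraphParams)
    membership: MembershipParams = field(
        default_factory=lambda: MembershipParams(family="linear")
    )

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.v1 <= 0 or self.v2 <= 0:
            raise ValueError("nu, v1, v2 must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass
class DualProblem:
    H: np.ndarray
    u: np.ndarray
    nu: float
    pos_mask: np.ndarray


@dataclass
class DualSolution:
    alpha: np.ndarray
    w: np.ndarray
    b_star: float
    rho_star: float
    sv1: np.ndarray
    sv2: np.ndarray
    xi: np.ndarray
    me1: np.ndarray
    me2: np.ndarray
    u: np.ndarray
    margins: np.ndarray  # w' x_i on training data
    tol_sv: float


def upper_bounds(mu: np.ndarray, hp: HyperParams, pos_mask: np.ndarray) -> np.ndarray:
    m1 = int(pos_mask.sum())
    m2 = int((~pos_mask).sum())
    u = np.empty_like(mu, dtype=float)
    u[pos_mask] = mu[pos_mask] / (hp.v1 * m1)
    u[~pos_mask] = mu[~pos_mask] / (hp.v2 * m2)
    return u


def regularized_solve(S: np.ndarray, eta: float, B: np.ndarray) -> np.ndarray:
    """Solve (I + eta*S) Z = B by Cholesky; never forms the inverse."""
    n = S.shape[0]
    A = np.eye(n) + eta * 0.5 * (S + S.T)
    return cho_solve(cho_factor(A), B)


def assemble_linear_dual(
    ds: Dataset, mu: np.ndarray, hp: HyperParams, S: np.ndarray
) -> DualProblem:
    """H_ij = y_i y_j x_i' (I + eta*S)^{-1} x_j, symmetrized; feasibility of
    nu against both classes' total cost mass is checked up front."""
    Z = regularized_solve(S, hp.eta, ds.X.T)  # (n, N)
    G = ds.X @ Z
    H = (ds.y[:, None] * ds.y[None, :]) * G
    H = 0.5 * (H + H.T)
    u = upper_bounds(mu, hp, ds.pos_mask)
    qp.check_feasible(u, hp.nu, ds.pos_mask)
    return DualProblem(H=H, u=u, nu=hp.nu, pos_mask=ds.pos_mask)


def solve_dual(dp: DualProblem, tol: float = 1e-8) -> np.ndarray:
    res = qp.solve_box_equality_qp(dp.H, dp.u, dp.nu, dp.pos_mask, tol=tol)
    return res.alpha


def _threshold_indices(
    alpha: np.ndarray, u: np.ndarray, mask: np.ndarray, tol_sv: float, sv_mode: str
) -> np.ndarray:
    sv = mask & (alpha > tol_sv)
    if sv_mode == "interior":
        interior = sv & (alpha < u - tol_sv)
        if interior.any():
            return np.flatnonzero(interior)
    return np.flatnonzero(sv)


def recover_linear(
    ds: Dataset,
    mu: np.ndarray,
    hp: HyperParams,
    S: np.ndarray,
    alpha: np.ndarray,
    sv_mode: str = "interior",
) -> DualSolution:
    """Recover (w*, b*, rho*), support-vector and margin-error sets.

    b* = 1 - mean_{SV1} w'x and rho* = -1 - b* - mean_{SV2} w'x, i.e. the
    thresholds that make the averaged active margin constraints exact.
    ``sv_mode="interior"`` (default) averages over strictly interior SVs,
    whose slacks vanish; ``"all"`` averages over every SV as the closed
    SV-set definition reads.
    """
    u = upper_bounds(mu, hp, ds.pos_mask)
    tol_sv = 1e-8 * float(u.max())
    w = regularized_solve(S, hp.eta, ds.X.T @ (alpha * ds.y))
    g = ds.X @ w

    sv1 = np.flatnonzero(ds.pos_mask & (alpha > tol_sv))
    sv2 = np.flatnonzero(~ds.pos_mask & (alpha > tol_sv))
    if sv1.size == 0 or sv2.size == 0:
        raise ValueError(
            "a class has no support vectors; increase nu or decrease that "
            "class's v parameter"
        )
    t1 = _threshold_indices(alpha, u, ds.pos_mask, tol_sv, sv_mode)
    t2 = _threshold_indices(alpha, u, ~ds.pos_mask, tol_sv, sv_mode)
    b_star = 1.0 - float(g[t1].mean())
    rho_star = -1.0 - b_star - float(g[t2].mean())

    xi = np.where(
        ds.pos_mask,
        np.clip(1.0 - (g + b_star), 0.0, None),
        np.clip(1.0 + rho_star + (g + b_star), 0.0, None),
    )
    me1 = np.flatnonzero(ds.pos_mask & (xi > tol_sv))
    me2 = np.flatnonzero(~ds.pos_mask & (xi > tol_sv))
    return DualSolution(
        alpha=alpha,
        w=w,
        b_star=b_star,
        rho_star=rho_star,
        sv1=sv1,
        sv2=sv2,
        xi=xi,
        me1=me1,
        me2=me2,
        u=u,
        margins=g,
        tol_sv=tol_sv,
    )


def decision_linear(sol: DualSolution, Xnew: np.ndarray) -> np.ndarray:
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != sol.w.shape[0]:
        raise ValueError(
            f"expected {sol.w.shape[0]} features, got {Xnew.shape[1]}"
        )
    return Xnew @ sol.w + sol.b_star


def predict_linear(sol: DualSolution, Xnew: np.ndarray) -> np.ndarray:
    """sign(w'x + b*), with the tie sign(0) mapped to +1 (majority class)."""
    return np.where(decision_linear(sol, Xnew) >= 0.0, 1, -1)


@dataclass
class MarginBoundReport:
    """Margin-error / support-vector mass bounds, one chain per class:

        mean_mu(ME_c) * #ME_c  <=  nu * v_c * m_c  <=  mean_mu(SV_c) * #SV_c

    which restates sum_{ME} u <= nu <= sum_{SV} u under u = mu/(v_c m_c).
    All six raw quantities are reported per class so the chain can be
    audited; the left bound is vacuous when a class has no margin errors.
    """

    per_class: dict
    holds: bool


def verify_margin_bounds(
    sol: DualSolution,
    mu: np.ndarray,
    hp: HyperParams,
    pos_mask: np.ndarray,
    rtol: float = 1e-6,
) -> MarginBoundReport:
    report = {}
    ok = True
    for name, mask, v_c, me, sv in (
        ("positive", pos_mask, hp.v1, sol.me1, sol.sv1),
        ("negative", ~pos_mask, hp.v2, sol.me2, sol.sv2),
    ):
        m_c = int(mask.sum())
        mid = hp.nu * v_c * m_c
        me_mean = float(mu[me].mean()) if me.size else float("nan")
        sv_mean = float(mu[sv].mean()) if sv.size else float("nan")
        left = me_mean * me.size if me.size else 0.0
        right = sv_mean * sv.size if sv.size else 0.0
        tol = rtol * max(1.0, mid)
        left_ok = (me.size == 0) or (left <= mid + tol)
        right_ok = (sv.size > 0) and (mid <= right + tol)
        ok = ok and left_ok and right_ok
        report[name] = {
            "n_me": int(me.size),
            "mean_mu_me": me_mean,
            "n_sv": int(sv.size),
            "mean_mu_sv": sv_mean,
            "left": left,
            "middle": mid,
            "right": right,
            "left_ok": bool(left_ok),
            "right_ok": bool(right_ok),
            "left_vacuous": me.size == 0,
        }
    return MarginBoundReport(per_class=report, holds=bool(ok))


class LinearFSVMCIP:
    """scikit-learn-style estimator wrapping the linear pipeline:
    memberships -> within-class graph -> scatter -> dual QP -> thresholds."""

    def __init__(self, hp: HyperParams | None = None, sv_mode: str = "interior"):
        self.hp = hp or HyperParams()
        self.sv_mode = sv_mode

    def fit(self, ds: Dataset) -> "LinearFSVMCIP":
        hp = self.hp
        params = hp.membership
        if params.space != "input":
            params = MembershipParams(
                family=params.family, delta=params.delta, lam=params.lam, space="input"
            )
        self.mu_ = compute_membership(ds, params)
        sq = pairwise_sq_dists(ds.X)
        self.graph_ = build_graph(ds.y, sq, hp.graph)
        self.S_ = scatter_linear(ds, self.graph_)
        dp = assemble_linear_dual(ds, self.mu_, hp, self.S_)
        alpha = solve_dual(dp)
        self.dual_ = dp
        self.solution_ = recover_linear(ds, self.mu_, hp, self.S_, alpha, self.sv_mode)
        self.report_ = verify_margin_bounds(self.solution_, self.mu_, hp, ds.pos_mask)
        self.train_ = ds
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return decision_linear(self.solution_, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_linear(self.solution_, X)
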