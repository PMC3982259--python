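"""Convex quadratic-programming backend for the classifier duals.

Both the linear and the kernel dual share one structure:

    minimize    1/2 a' H a
    subject to  sum_{i in pos} a_i = nu,   sum_{j in neg} a_j = nu,
                0 <= a <= u                 (elementwise)

with H symmetric positive semidefinite and u the fuzzy-membership-scaled
cost caps.  The problem is solved with scipy's trust-constr (exact
gradient and Hessian, deterministic start) and then refined by one or two
exact active-set steps: variables numerically at a bound are pinned and
the reduced equality-constrained KKT system is solved directly, which
drives KKT residuals to linear-solve precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize

__all__ = ["QPResult", "InfeasibleError", "check_feasible", "solve_box_equality_qp"]


class InfeasibleError(ValueError):
    """The equality mass nu exceeds a class's total upper-bound mass."""


@dataclass
class QPResult:
    alpha: np.ndarray
    objective: float
    status: str
    kkt_residual: float


def check_feasible(u: np.ndarray, nu: float, pos_mask: np.ndarray, tol: float = 1e-12) -> None:
    if nu <= 0:
        raise InfeasibleError("nu must be > 0")
    for name, mask in (("positive", pos_mask), ("negative", ~pos_mask)):
        cap = float(u[mask].sum())
        if cap < nu - tol * max(1.0, nu):
            raise InfeasibleError(
                f"nu={nu} exceeds the {name} class's total cost mass {cap:.6g}; "
                f"reduce nu or the class's v parameter"
            )


def _feasible_start(u: np.ndarray, nu: float, pos_mask: np.ndarray) -> np.ndarray:
    x0 = np.empty_like(u)
    for mask in (pos_mask, ~pos_mask):
        x0[mask] = nu * u[mask] / u[mask].sum()
    return np.minimum(x0, u)


def _objective(H: np.ndarray, a: np.ndarray) -> float:
    return 0.5 * float(a @ H @ a)


def _equality_rows(pos_mask: np.ndarray) -> np.ndarray:
    A = np.zeros((2, pos_mask.size))
    A[0, pos_mask] = 1.0
    A[1, ~pos_mask] = 1.0
    return A


def _solve_reduced_kkt(
    H: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    free: np.ndarray,
    fixed_val: np.ndarray,
):
    """Equality-constrained QP on the free variables; returns (alpha_free, lam)."""
    nf = int(free.sum())
    Hff = H[np.ix_(free, free)]
    rhs_top = -H[np.ix_(free, ~free)] @ fixed_val[~free]
    Af = A_eq[:, free]
    rhs_bot = b_eq - A_eq[:, ~free] @ fixed_val[~free]
    KKT = np.block([[Hff, -Af.T], [Af, np.zeros((2, 2))]])
    rhs = np.concatenate([rhs_top, rhs_bot])
    sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
    # two rounds of iterative refinement: the KKT system can be poorly
    # conditioned and downstream complementarity checks need tight margins
    for _ in range(2):
        resid = rhs - KKT @ sol
        if np.abs(resid).max() <= 1e-14 * max(1.0, np.abs(rhs).max()):
            break
        corr, *_ = np.linalg.lstsq(KKT, resid, rcond=None)
        sol = sol + corr
    return sol[:nf], sol[nf:]


def _active_set_polish(
    H: np.ndarray,
    u: np.ndarray,
    nu: float,
    pos_mask: np.ndarray,
    alpha: np.ndarray,
) -> np.ndarray:
    """Primal active-set refinement started from a feasible near-optimum.

    Repeatedly solves the KKT system of the equality-constrained QP on the
    current free set; steps toward that solution with a ratio test against
    the box (pinning the blocking variable), and releases bound variables
    whose multiplier sign violates optimality.  Terminates at a point with
    KKT residuals at linear-solve precision, or returns the best feasible
    iterate if the iteration cap is hit.
    """
    N = u.size
    A_eq = _equality_rows(pos_mask)
    b_eq = np.array([nu, nu])
    u_scale = max(float(u.max()), 1e-300)
    tol_a = 1e-9 * u_scale
    alpha = np.clip(alpha, 0.0, u)
    best = alpha.copy()
    best_obj = _objective(H, best)
    low = alpha <= tol_a
    high = alpha >= u - tol_a
    alpha[low] = 0.0
    alpha[high] = u[high]
    g_scale = max(float(np.abs(H).max()) * u_scale, 1e-300)
    tol_g = 1e-11 * g_scale

    for _ in range(6 * N + 20):
        free = ~(low | high)
        fixed_val = np.where(high, u, 0.0)
        if free.any():
            af, lam = _solve_reduced_kkt(H, A_eq, b_eq, free, fixed_val)
            cand = fixed_val.copy()
            cand[free] = af
        else:
            cand = fixed_val.copy()
            lam = None
        d = cand - alpha
        if np.abs(d).max() <= tol_a:
            # adopt the KKT solution outright so stationarity holds to
            # linear-solve precision even for sub-tolerance corrections
            alpha = np.clip(cand, 0.0, u)
        else:
            # ratio test against the box on the free components
            step = 1.0
            blocker = -1
            blocker_high = False
            for i in np.flatnonzero(free):
                if d[i] < -tol_a and alpha[i] + d[i] < -tol_a:
                    s = alpha[i] / -d[i]
                    if s < step:
                        step, blocker, blocker_high = s, i, False
                elif d[i] > tol_a and alpha[i] + d[i] > u[i] + tol_a:
                    s = (u[i] - alpha[i]) / d[i]
                    if s < step:
                        step, blocker, blocker_high = s, i, True
            alpha = alpha + step * d
            alpha = np.clip(alpha, 0.0, u)
            if blocker >= 0:
                if blocker_high:
                    high[blocker] = True
                    alpha[blocker] = u[blocker]
                else:
                    low[blocker] = True
                    alpha[blocker] = 0.0
                continue
            # full step taken: fall through to the release test

        g = H @ alpha
        if lam is None:
            lam = np.zeros(2)
            for c, mask in enumerate((pos_mask, ~pos_mask)):
                hi_c = high & mask
                lo_c = low & mask
                top = g[hi_c].max() if hi_c.any() else -np.inf
                bot = g[lo_c].min() if lo_c.any() else np.inf
                lam[c] = 0.5 * (min(top, bot) + max(top, bot)) if np.isfinite(top) or np.isfinite(bot) else 0.0
        # multiplier sign check on the bound variables
        worst_i, worst_v = -1, tol_g
        for c, mask in enumerate((pos_mask, ~pos_mask)):
            for i in np.flatnonzero(low & mask):
                v = lam[c] - g[i]  # wants to grow from 0
                if v > worst_v:
                    worst_i, worst_v = i, v
            for i in np.flatnonzero(high & mask):
                v = g[i] - lam[c]  # wants to shrink from u
                if v > worst_v:
                    worst_i, worst_v = i, v
        obj = _objective(H, alpha)
        if obj <= best_obj + 1e-14 * max(1.0, abs(best_obj)):
            best, best_obj = alpha.copy(), obj
        if worst_i < 0:
            return alpha
        low[worst_i] = False
        high[worst_i] = False
    return best


def kkt_residual(
    H: np.ndarray, u: np.ndarray, nu: float, pos_mask: np.ndarray, alpha: np.ndarray
) -> float:
    """Max violation of stationarity/complementarity of the box-equality QP,
    using the optimal multipliers implied by the free variables."""
    g = H @ alpha
    tol_a = 1e-7 * max(float(u.max()), 1e-300)
    res = 0.0
    for mask in (pos_mask, ~pos_mask):
        free = mask & (alpha > tol_a) & (alpha < u - tol_a)
        lam = float(np.median(g[free])) if free.any() else None
        if lam is None:
            continue
        # free: gradient equals lam; at 0: gradient >= lam; at u: gradient <= lam
        res = max(res, float(np.abs(g[free] - lam).max()) if free.any() else 0.0)
        at0 = mask & (alpha <= tol_a)
        atU = mask & (alpha >= u - tol_a)
        if at0.any():
            res = max(res, float(np.clip(lam - g[at0], 0, None).max()))
        if atU.any():
            res = max(res, float(np.clip(g[atU] - lam, 0, None).max()))
    return res


def solve_box_equality_qp(
    H: np.ndarray,
    u: np.ndarray,
    nu: float,
    pos_mask: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 100_000,
) -> QPResult:
    """Solve the dual QP; deterministic, no randomized initialization."""
    H = 0.5 * (H + H.T)
    u = np.asarray(u, dtype=float)
    check_feasible(u, nu, pos_mask)
    x0 = _feasible_start(u, nu, pos_mask)
    A_eq = _equality_rows(pos_mask)

    res = minimize(
        lambda a: _objective(H, a),
        x0,
        jac=lambda a: H @ a,
        hess=lambda a: H,
        method="trust-constr",
        bounds=Bounds(np.zeros_like(u), u),
        constraints=[LinearConstraint(A_eq, [nu, nu], [nu, nu])],
        options={"gtol": tol * 1e-2, "xtol": 1e-14, "maxiter": maxiter},
    )
    alpha = np.clip(res.x, 0.0, u)
    alpha = _active_set_polish(H, u, nu, pos_mask, alpha)
    status = "polished" if res.success else f"unconverged: {res.message}"
    return QPResult(
        alpha=alpha,
        objective=_objective(H, alpha),
        status=status,
        kkt_residual=kkt_residual(H, u, nu, pos_mask, alpha),
    )
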