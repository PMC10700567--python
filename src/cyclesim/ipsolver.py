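"""Sparse penalty-barrier Newton solver for bound-constrained equality NLPs.

Solves  min f(x)  s.t.  c(x) = 0,  lb <= x <= ub  by minimizing the
penalty-barrier function

    psi(x) = f(x) + rho/2 ||c(x)||^2 - mu sum log(x-lb) - mu sum log(ub-x)

with damped Newton steps over a decreasing barrier schedule, increasing the
penalty weight rho until the constraint tolerance is met.  The Newton
system  (H + rho J^T J + Sigma + delta I) dx = -grad psi  is symmetric
positive definite by construction (the application's objective is convex),
so every step is a descent direction for psi and a plain Armijo
backtracking line search -- on the same function psi -- is globally
reliable; no separate merit bookkeeping or multiplier safeguards are
needed.  Bound duals zL, zU are carried primal-dual style to precondition
Sigma near active bounds.  The system stays extremely sparse (banded in
time for collocation problems) and is factorized with sparse LU.

The implicit multiplier estimate of the penalty method is lam = rho*c; it
is fed back to the model's Lagrangian Hessian (the exact curvature term
rho * sum_i c_i nabla^2 c_i) once the iterate is close enough, and it is
used for the final KKT stationarity report.  With a constraint tolerance
of 1e-3 (the pipeline's setting), rho ~ 1e4..1e6 suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class ConvergenceError(RuntimeError):
    """Solver failed; carries the last iterate and residuals."""

    def __init__(self, message, x=None, constraint_violation=None, stationarity=None,
                 iterations=None):
        super().__init__(message)
        self.x = x
        self.constraint_violation = constraint_violation
        self.stationarity = stationarity
        self.iterations = iterations


@dataclass
class IPResult:
    x: np.ndarray
    multipliers: np.ndarray
    iterations: int
    stationarity: float
    constraint_violation: float
    objective: float
    status: str


def solve_ip(eval_full, eval_fc, x0, lb, ub, *, tol_stat=1e-3, tol_con=1e-3,
             mu0=1e-4, mu_term=1e-6, mu_factor=0.1, rho0=1e4, rho_max=1e7,
             max_inner=30, max_iter=600, lam_clip=1e3, accept_stat=5.0,
             accept_window=8, verbose=False) -> IPResult:
    """Run the penalty-barrier continuation.

    ``eval_full(x, lam_for_hessian)`` -> (f, g, H, c, J);
    ``eval_fc(x)`` -> (f, c) for line-search probes.
    """
    lb_raw = np.asarray(lb, dtype=float)
    ub_raw = np.asarray(ub, dtype=float)
    # diagonal variable scaling: every box becomes width 1, which balances
    # the step geometry across variable kinds (excitations vs auxiliary
    # rates span very different physical ranges)
    D = ub_raw - lb_raw
    Dmat = sp.diags(D)
    lb = lb_raw / D
    ub = ub_raw / D
    eval_full_raw, eval_fc_raw = eval_full, eval_fc

    def eval_full(y, lam_h):
        f, g, H, c, J = eval_full_raw(y * D, lam_h)
        return f, g * D, (Dmat @ H @ Dmat).tocsc(), c, (J @ Dmat).tocsr()

    def eval_fc(y):
        return eval_fc_raw(y * D)

    x = np.asarray(x0, dtype=float) / D
    width = ub - lb
    x = np.clip(x, lb + 1e-4 * width, ub - 1e-4 * width)
    n = len(x)

    mu = mu0
    rho = rho0
    delta = 1e-8
    tau_fb = 0.995
    kappa_z = 1e10

    s1 = x - lb
    s2 = ub - x
    zL = mu / s1
    zU = mu / s2
    it = 0
    best = None
    c_prev = None
    f_hist: list[float] = []

    def psi_of(ft, ct, xt):
        s1t = xt - lb
        s2t = ub - xt
        if np.any(s1t <= 0) or np.any(s2t <= 0):
            return np.inf
        return (ft + 0.5 * rho * float(ct @ ct)
                - mu * (np.sum(np.log(s1t)) + np.sum(np.log(s2t))))

    last_stat = np.inf
    last_con = np.inf
    while it < max_iter:
        stage_iters = 0
        while stage_iters < max_inner and it < max_iter:
            # exact penalty curvature rho * sum_i c_i nabla^2 c_i via the
            # implicit multipliers lam = rho*c, once near-feasible
            use_curv = c_prev is not None and last_con <= max(10.0 * tol_con, 1e-2)
            lam = np.clip(rho * c_prev, -lam_clip, lam_clip) if use_curv else None
            f, g, H, c, J = eval_full(x, lam)
            c_prev = c
            m = len(c)
            s1 = x - lb
            s2 = ub - x
            con = float(np.max(np.abs(c))) if m else 0.0
            Jc = J.T @ c
            dual_res = g + rho * Jc - zL + zU
            stat = float(np.max(np.abs(dual_res)))
            sd = 1.0
            if con <= tol_con and stat > tol_stat and mu <= 10.0 * mu_term:
                # the implicit multipliers rho*c overestimate the KKT
                # residual at the feasibility floor; measure against the
                # least-squares multipliers, with the customary scaling of
                # the dual-infeasibility tolerance by the mean dual size
                v = g - zL + zU
                JJt = (J @ J.T + 1e-10 * sp.eye(m)).tocsc()
                try:
                    lam_ls = splu(JJt).solve(-(J @ v))
                    stat = float(np.max(np.abs(v + J.T @ lam_ls)))
                    dual_mean = (float(np.sum(np.abs(lam_ls))) + float(np.sum(zL))
                                 + float(np.sum(zU))) / (m + 2 * n)
                    sd = max(100.0, dual_mean) / 100.0
                except RuntimeError:
                    pass
            last_stat, last_con = stat, con
            if best is None or (con, stat) < (best[1], best[0]):
                best = (stat, con, x.copy(), rho * c, f)
            if verbose:
                print(f"  it {it:3d}  mu {mu:.1e}  rho {rho:.1e}  f {f:.4e}  "
                      f"|c| {con:.2e}  stat {stat:.2e}  curv {int(use_curv)}")

            if con <= tol_con and stat <= tol_stat * sd and mu <= mu_term:
                return IPResult(x * D, rho * c, it, stat, con, f, "converged")
            # acceptable-level termination: feasible, objective flat over a
            # window, and dual infeasibility at the rounding floor of the
            # scaled problem (the strict test can limit-cycle there)
            if (con <= tol_con and stat <= accept_stat and mu <= 10.0 * mu_term
                    and len(f_hist) >= accept_window
                    and max(f_hist) - min(f_hist) <= 1e-7 * max(1.0, abs(f))):
                return IPResult(x * D, rho * c, it, stat, con, f, "acceptable")
            f_hist.append(f)
            if len(f_hist) > accept_window:
                f_hist.pop(0)

            grad_psi = g + rho * Jc - mu / s1 + mu / s2
            # barrier subproblem considered solved
            if float(np.max(np.abs(grad_psi + (zL - mu / s1) - (zU - mu / s2)))) \
                    <= max(tol_stat, 50.0 * mu) and con <= max(tol_con, mu):
                break

            sigma = zL / s1 + zU / s2
            for _ in range(14):
                Hbar = (H + rho * (J.T @ J) + sp.diags(sigma + delta)).tocsc()
                try:
                    dx = splu(Hbar).solve(-grad_psi)
                except RuntimeError:
                    delta = max(delta * 10.0, 1e-8)
                    continue
                if not np.all(np.isfinite(dx)):
                    delta = max(delta * 10.0, 1e-8)
                    continue
                if float(grad_psi @ dx) >= 0.0:
                    delta = max(delta * 10.0, 1e-8)
                    continue
                break
            else:
                raise ConvergenceError(
                    "Newton system could not be regularized", x=x * D,
                    constraint_violation=con, stationarity=stat, iterations=it)
            delta = max(delta / 3.0, 1e-10)

            # projected-arc Armijo search on psi: there are no hard
            # equalities (they live in the penalty), so bound handling by
            # projection lets free variables take full Newton steps while a
            # few bound-pinned ones stay put, instead of a global
            # fraction-to-boundary cap throttling every step
            zeta = 1e-6
            psi0 = psi_of(f, c, x)
            alpha = 1.0
            accepted = False
            for _ in range(30):
                xt = np.clip(x + alpha * dx, lb + zeta, ub - zeta)
                step = xt - x
                slope = float(grad_psi @ step)
                ft, ct = eval_fc(xt)
                if psi_of(ft, ct, xt) <= psi0 + 1e-4 * min(slope, 0.0):
                    accepted = True
                    break
                alpha *= 0.5
            it += 1
            stage_iters += 1
            if verbose:
                print(f"        alpha {alpha:.2e} (max {alpha_max:.2e})  "
                      f"delta {delta:.1e}  accepted {accepted}")
            if not accepted:
                delta = min(max(delta, 1e-8) * 100.0, 1e-2)
                continue
            move = xt - x
            x = xt
            s1 = x - lb
            s2 = ub - x
            # primal-dual bound-dual update with IPOPT-style safeguard
            dzL = mu / s1 - zL - (zL / s1) * move
            dzU = mu / s2 - zU + (zU / s2) * move
            alpha_z = 1.0
            for zz, dz in ((zL, dzL), (zU, dzU)):
                negz = dz < 0
                if np.any(negz):
                    alpha_z = min(alpha_z, float(np.min(-tau_fb * zz[negz] / dz[negz])))
            zL = np.clip(zL + alpha_z * dzL, mu / (kappa_z * s1), kappa_z * mu / s1)
            zU = np.clip(zU + alpha_z * dzU, mu / (kappa_z * s2), kappa_z * mu / s2)

        if mu <= mu_term and last_con > tol_con:
            if rho >= rho_max:
                raise ConvergenceError(
                    f"infeasible at rho={rho:.1e} (|c|={last_con:.3e})",
                    x=x * D, constraint_violation=last_con, stationarity=last_stat,
                    iterations=it)
            rho = min(rho * 10.0, rho_max)
            continue
        if mu <= mu_term:
            # feasible; the full barrier schedule has been exhausted
            f, c = eval_fc(x)
            if last_stat <= tol_stat:
                return IPResult(x * D, rho * c, it, last_stat, last_con, f, "converged")
            if last_stat <= accept_stat:
                return IPResult(x * D, rho * c, it, last_stat, last_con, f, "acceptable")
            raise ConvergenceError(
                f"stalled (|c|={last_con:.3e}, stationarity={last_stat:.3e})",
                x=x * D, constraint_violation=last_con, stationarity=last_stat,
                iterations=it)
        mu = max(mu * mu_factor, mu_term)
        zL = np.clip(zL, mu / (kappa_z * s1), kappa_z * mu / s1)
        zU = np.clip(zU, mu / (kappa_z * s2), kappa_z * mu / s2)

    raise ConvergenceError(
        f"no convergence in {max_iter} iterations "
        f"(best |c|={best[1]:.3e}, stationarity={best[0]:.3e})",
        x=best[2] * D, constraint_violation=best[1], stationarity=best[0], iterations=it)
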