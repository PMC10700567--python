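"""Direct-collocation muscle-redundancy solver.

Given prescribed kinematics and net joint moments, find muscle excitations,
activations, compliant-tendon auxiliary states, and reserve/residual
controls that satisfy per-node moment balance and the collocation defects
of the activation and tendon dynamics, minimizing either

    J1 = w1 (sum_i int e_i^2 + sum_j int u_j^2) + w2 sum_k int zdot_k^2

or J2 = J1 + w3 sum_legs int F_tf^2, where F_tf is the compressive
tibiofemoral force assembled from the same decision variables (so the
penalty is smooth and exact, not a post-hoc approximation).

Transcription: trapezoidal defect collocation on 51 nodes per revolution
(default) with a quarter-revolution lead-in before TDC, solved by the
structured interior-point method in :mod:`cyclesim.ipsolver`.  Compliant
tendons use the implicit formulation: the auxiliary state z is the
normalized fiber length, its derivative zdot is a control, and the
fiber-tendon force balance is an algebraic path constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from .dynamics import NetMoments, net_joint_moments
from .ipsolver import ConvergenceError, solve_ip
from .kinematics import TrialKinematics
from .model import (
    HillCurves,
    MusculoskeletalModel,
    MTUParams,
    moment_arm,
    mtu_length,
    pennation_cos,
)

__all__ = [
    "ObjectiveConfig",
    "CollocationGrid",
    "CollocationProblem",
    "RedundancySolution",
    "build_problem",
    "solve",
    "objective_value",
    "static_optimization_oracle",
    "ConvergenceError",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ObjectiveConfig:
    """Objective mode and weights.

    w1 scales the control effort (squared excitations and actuator
    controls), w2 the squared auxiliary-state derivatives of the compliant
    tendons, and w3 (J2 only) the squared compressive tibiofemoral force of
    both legs (1/N^2/s).  Solver convergence and constraint tolerances
    default to 1e-3 on the scaled problem.
    """

    mode: str = "J1"
    w1: float = 2.0
    w2: float = 1e-6
    w3: float = 1e-3
    convergence_tol: float = 1e-3
    constraint_tol: float = 1e-3

    def validate(self) -> None:
        if self.mode not in ("J1", "J2"):
            raise ValueError(f"unknown objective mode {self.mode!r}")
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("objective weights must be >= 0")


@dataclass
class CollocationGrid:
    """Node times spanning a lead-in before TDC plus one revolution.

    TDC (t = 0) and TDC + one revolution must both be nodes; only
    [0, 60/cadence] is analyzed downstream.
    """

    times: np.ndarray
    cadence: float
    scheme: str = "trapezoidal"

    @classmethod
    def from_cadence(cls, cadence: float, n_per_rev: int = 51,
                     lead_fraction: float = 0.25) -> "CollocationGrid":
        period = 60.0 / cadence
        h = period / (n_per_rev - 1)
        n_lead = int(math.ceil(lead_fraction * (n_per_rev - 1)))
        times = np.arange(-n_lead, n_per_rev) * h
        return cls(times=times, cadence=cadence)

    def validate(self) -> None:
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        if len(t) < 11:
            raise ValueError("need at least 11 nodes")
        period = 60.0 / self.cadence
        if min(np.abs(t)) > 1e-9 or min(np.abs(t - period)) > 1e-9:
            raise ValueError("TDC and TDC + one revolution must be grid nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def tdc_index(self) -> int:
        return int(np.argmin(np.abs(self.times)))

    @property
    def end_index(self) -> int:
        return int(np.argmin(np.abs(self.times - 60.0 / self.cadence)))

    @property
    def analyzed(self) -> slice:
        return slice(self.tdc_index, self.end_index + 1)


# ---------------------------------------------------------------------------
# Channels (per-node data prepared for the NLP)
# ---------------------------------------------------------------------------


@dataclass
class MuscleChannel:
    """Per-node data of one MTU entering the transcription."""

    name: str
    f_max: float
    tau_act: float
    tau_deact: float
    rigid: bool
    arms: dict[str, np.ndarray]  # dof -> (N,) moment arm
    kappa_act: np.ndarray | None = None  # rigid: fl*fv*f_max*cos(penn) per node
    kappa_pas: np.ndarray | None = None  # rigid: fp*f_max*cos(penn) per node
    l_mtu: np.ndarray | None = None  # compliant: MTU length per node
    l_opt: float | None = None
    l_slack: float | None = None
    penn_sin: float = 0.0
    knee_cos: np.ndarray | None = None  # compressive direction cosine


@dataclass
class ActuatorChannel:
    name: str
    dof: str
    capacity: float


# ---------------------------------------------------------------------------
# The transcribed problem
# ---------------------------------------------------------------------------


class CollocationProblem:
    """Sparse NLP of the muscle-redundancy optimal control problem.

    Decision variables per node: excitations e_i, activations a_i, actuator
    controls u_j, auxiliary states z_k (normalized fiber length of each
    compliant tendon) and their derivatives zdot_k.  Constraints: per-node
    moment balance per DOF, per-node tendon force balance, trapezoidal
    defects of the activation and auxiliary dynamics, and the initial
    excitation-activation tie.
    """

    #: bounds of the auxiliary normalized-fiber-length state
    Z_MIN, Z_MAX = 0.3, 1.9
    #: auxiliary-rate bound: fibers cannot shorten or lengthen faster than
    #: 0.95 v_max (keeps the force-velocity curve in its physical range)
    VZ_MAX = 9.5  # 1/s
    MOMENT_SCALE = 50.0  # N*m, row scaling of the moment balance
    W_SMOOTH = 2e-3  # excitation-rate regularization weight (s)

    def __init__(self, grid: CollocationGrid, muscles: list[MuscleChannel],
                 dof_demands: dict[str, np.ndarray], actuators: list[ActuatorChannel],
                 cfg: ObjectiveConfig, curves: HillCurves,
                 ftf_const: np.ndarray | None = None, leg_factor: float = 2.0):
        cfg.validate()
        grid.validate()
        self.grid = grid
        self.cfg = cfg
        self.curves = curves
        self.muscles = muscles
        self.actuators = actuators
        self.dof_names = list(dof_demands.keys())
        self.leg_factor = leg_factor

        for dof in self.dof_names:
            has_muscle = any(dof in mc.arms for mc in muscles)
            has_act = any(ac.dof == dof for ac in actuators)
            if not has_muscle and not has_act:
                raise ValueError(f"DOF {dof!r} has neither a muscle nor an actuator")

        self.times = grid.times
        self.N = len(self.times)
        self.h = np.diff(self.times)
        # trapezoid quadrature weights
        wq = np.zeros(self.N)
        wq[:-1] += self.h / 2.0
        wq[1:] += self.h / 2.0
        self.wq = wq

        self.nm = len(muscles)
        self.na = len(actuators)
        self.comp = [i for i, mc in enumerate(muscles) if not mc.rigid]
        self.nc = len(self.comp)
        self.stride = 2 * self.nm + self.na + 2 * self.nc
        self.n_var = self.stride * self.N

        self.demand = np.vstack([dof_demands[d] for d in self.dof_names])  # (nd, N)
        self.nd = len(self.dof_names)

        # row scaling per dof (pelvis residual rows scale by capacity)
        self.row_scale = np.empty(self.nd)
        for j, dof in enumerate(self.dof_names):
            caps = [ac.capacity for ac in actuators if ac.dof == dof]
            self.row_scale[j] = max([self.MOMENT_SCALE] + [c for c in caps if c > self.MOMENT_SCALE])

        self.ftf_const = ftf_const if ftf_const is not None else np.zeros(self.N)
        #: objective scaling applied inside eval_full/eval_fc (gradient-based,
        #: set by solve()); reported objective values are unscaled
        self.obj_scale = 1.0

        self._build_layout()
        self._build_patterns()

    # -- variable indexing --------------------------------------------------
    def idx_e(self, i, k):
        return k * self.stride + i

    def idx_a(self, i, k):
        return k * self.stride + self.nm + i

    def idx_u(self, m, k):
        return k * self.stride + 2 * self.nm + m

    def idx_z(self, ci, k):
        return k * self.stride + 2 * self.nm + self.na + ci

    def idx_vz(self, ci, k):
        return k * self.stride + 2 * self.nm + self.na + self.nc + ci

    def _build_layout(self):
        N, nm, na, nc, nd = self.N, self.nm, self.na, self.nc, self.nd
        self.n_con = nd * N + nc * N + nm * (N - 1) + nc * (N - 1) + nm
        self.row_moment = 0
        self.row_equil = nd * N
        self.row_actdef = self.row_equil + nc * N
        self.row_zdef = self.row_actdef + nm * (N - 1)
        self.row_tie = self.row_zdef + nc * (N - 1)

        lb = np.empty(self.n_var)
        ub = np.empty(self.n_var)
        k = np.arange(N)
        for i in range(nm):
            lb[self.idx_e(i, k)] = 0.0
            ub[self.idx_e(i, k)] = 1.0
            lb[self.idx_a(i, k)] = 0.0
            ub[self.idx_a(i, k)] = 1.0
        for m in range(na):
            lb[self.idx_u(m, k)] = -1.0
            ub[self.idx_u(m, k)] = 1.0
        for ci in range(nc):
            lb[self.idx_z(ci, k)] = self.Z_MIN
            ub[self.idx_z(ci, k)] = self.Z_MAX
            lb[self.idx_vz(ci, k)] = -self.VZ_MAX
            ub[self.idx_vz(ci, k)] = self.VZ_MAX
        self.lb, self.ub = lb, ub

    # -- sparsity patterns --------------------------------------------------
    def _build_patterns(self):
        N, nm, nd = self.N, self.nm, self.nd
        karr = np.arange(N)

        # moment balance: constant part (rigid muscle activations, actuators)
        rows_c, cols_c, vals_c = [], [], []
        # variable part (compliant z entries): (rows, cols, multiplier, comp-slot)
        rows_v, cols_v, mult_v, comp_v = [], [], [], []
        # constant offset per (j, k): rigid passive + (-demand), scaled
        self.mom_offset = -self.demand / self.row_scale[:, None]
        for j, dof in enumerate(self.dof_names):
            rows_jk = self.row_moment + karr * nd + j
            for i, mc in enumerate(self.muscles):
                if dof not in mc.arms:
                    continue
                r = mc.arms[dof]
                if mc.rigid:
                    rows_c.append(rows_jk)
                    cols_c.append(self.idx_a(i, karr))
                    vals_c.append(r * mc.kappa_act / self.row_scale[j])
                    self.mom_offset[j] += r * mc.kappa_pas / self.row_scale[j]
                else:
                    ci = self.comp.index(i)
                    rows_v.append(rows_jk)
                    cols_v.append(self.idx_z(ci, karr))
                    # multiplies the tendon force fT (N) and its derivative
                    mult_v.append(r / self.row_scale[j])
                    comp_v.append(np.full(N, ci))
            for m, ac in enumerate(self.actuators):
                if ac.dof == dof:
                    rows_c.append(rows_jk)
                    cols_c.append(self.idx_u(m, karr))
                    vals_c.append(np.full(N, ac.capacity / self.row_scale[j]))
        self._momA = sp.coo_matrix(
            (np.concatenate(vals_c), (np.concatenate(rows_c), np.concatenate(cols_c))),
            shape=(self.n_con, self.n_var)).tocsr() if rows_c else \
            sp.csr_matrix((self.n_con, self.n_var))
        if rows_v:
            self._mom_var_rows = np.concatenate(rows_v)
            self._mom_var_cols = np.concatenate(cols_v)
            self._mom_var_mult = np.concatenate(mult_v)
            self._mom_var_comp = np.concatenate(comp_v).astype(int)
        else:
            self._mom_var_rows = np.empty(0, dtype=int)
            self._mom_var_cols = np.empty(0, dtype=int)
            self._mom_var_mult = np.empty(0)
            self._mom_var_comp = np.empty(0, dtype=int)

        # tendon equilibrium rows: for compliant slot ci, node k ->
        # row_equil + k*nc + ci; entries at (a, z, vz)
        if self.nc:
            ci_arr = np.arange(self.nc)
            KK, CC = np.meshgrid(karr, ci_arr, indexing="ij")
            self._eq_rows = (self.row_equil + KK * self.nc + CC).ravel()
            mus_idx = np.array(self.comp)
            self._eq_cols_a = (KK * self.stride + nm + mus_idx[CC]).ravel()
            self._eq_cols_z = self.idx_z(CC, KK).ravel()
            self._eq_cols_vz = self.idx_vz(CC, KK).ravel()

        # activation defect rows: interval k (0..N-2), muscle i
        ii, kk = np.meshgrid(np.arange(nm), np.arange(N - 1), indexing="ij")
        self._ad_rows = (self.row_actdef + kk * nm + ii).ravel()
        self._ad_cols_a0 = self.idx_a(ii, kk).ravel()
        self._ad_cols_a1 = self.idx_a(ii, kk + 1).ravel()
        self._ad_cols_e0 = self.idx_e(ii, kk).ravel()
        self._ad_cols_e1 = self.idx_e(ii, kk + 1).ravel()
        self._ad_h = self.h[kk].ravel()

        # z defect rows (linear, constant pattern and values)
        if self.nc:
            cc, kk2 = np.meshgrid(np.arange(self.nc), np.arange(N - 1), indexing="ij")
            rows = (self.row_zdef + kk2 * self.nc + cc).ravel()
            entries = [
                (rows, self.idx_z(cc, kk2 + 1).ravel(), np.ones(rows.size)),
                (rows, self.idx_z(cc, kk2).ravel(), -np.ones(rows.size)),
                (rows, self.idx_vz(cc, kk2).ravel(), -self.h[kk2].ravel() / 2.0),
                (rows, self.idx_vz(cc, kk2 + 1).ravel(), -self.h[kk2].ravel() / 2.0),
            ]
            r = np.concatenate([e[0] for e in entries])
            c = np.concatenate([e[1] for e in entries])
            v = np.concatenate([e[2] for e in entries])
            self._zdefJ = sp.coo_matrix((v, (r, c)), shape=(self.n_con, self.n_var)).tocsr()
        else:
            self._zdefJ = sp.csr_matrix((self.n_con, self.n_var))

        # initial ties
        i_arr = np.arange(nm)
        tie_rows = self.row_tie + i_arr
        r = np.concatenate([tie_rows, tie_rows])
        c = np.concatenate([self.idx_e(i_arr, 0), self.idx_a(i_arr, 0)])
        v = np.concatenate([np.ones(nm), -np.ones(nm)])
        self._tieJ = sp.coo_matrix((v, (r, c)), shape=(self.n_con, self.n_var)).tocsr()

        # anti-chatter regularization: a small integral of squared excitation
        # rate.  The asymmetric activation/deactivation rates make sawtooth
        # excitations spuriously cheap under the raw effort objective; this
        # term removes that transcription artifact without measurably
        # changing activations or forces.  Excluded from reported objectives.
        rows_s, cols_s, vals_s = [], [], []
        kk3 = np.arange(N - 1)
        for i in range(nm):
            c0 = self.idx_e(i, kk3)
            c1 = self.idx_e(i, kk3 + 1)
            w = 2.0 * self.W_SMOOTH / self.h  # d2/de2 of w*(de)^2/h
            rows_s += [c0, c1, c0, c1]
            cols_s += [c0, c1, c1, c0]
            vals_s += [w, w, -w, -w]
        self._smoothH = sp.coo_matrix(
            (np.concatenate(vals_s), (np.concatenate(rows_s), np.concatenate(cols_s))),
            shape=(self.n_var, self.n_var)).tocsc()

        # constant objective Hessian diagonal
        diag = np.zeros(self.n_var)
        for i in range(nm):
            diag[self.idx_e(i, karr)] = 2.0 * self.cfg.w1 * self.wq
        for m in range(self.na):
            diag[self.idx_u(m, karr)] = 2.0 * self.cfg.w1 * self.wq
        for ci in range(self.nc):
            diag[self.idx_vz(ci, karr)] = 2.0 * self.cfg.w2 * self.wq
        self._obj_diag = diag

        # F_tf participation (J2): rigid knee-crossers via a, compliant via z
        self._ftf_a_idx = []  # (muscle index, kappa_c array)
        self._ftf_z_idx = []  # (comp slot, muscle index)
        for i, mc in enumerate(self.muscles):
            if mc.knee_cos is None:
                continue
            if mc.rigid:
                self._ftf_a_idx.append((i, mc.knee_cos * mc.kappa_act))
            else:
                self._ftf_z_idx.append((self.comp.index(i), i))
        # per-node variable list for the J2 Hessian block
        self._ftf_cols_per_node = None
        if self.cfg.mode == "J2" and (self._ftf_a_idx or self._ftf_z_idx):
            cols = []
            for i, _ in self._ftf_a_idx:
                cols.append(self.idx_a(i, karr))
            for ci, _ in self._ftf_z_idx:
                cols.append(self.idx_z(ci, karr))
            self._ftf_cols_per_node = np.array(cols)  # (P, N)
            P = len(cols)
            self._ftf_hess_rows = np.repeat(self._ftf_cols_per_node, P, axis=0).ravel()
            self._ftf_hess_cols = np.tile(self._ftf_cols_per_node, (P, 1)).ravel()

    # -- state unpacking ----------------------------------------------------
    def unpack(self, x):
        X = x.reshape(self.N, self.stride)
        nm, na, nc = self.nm, self.na, self.nc
        E = X[:, :nm].T
        A = X[:, nm : 2 * nm].T
        U = X[:, 2 * nm : 2 * nm + na].T
        Z = X[:, 2 * nm + na : 2 * nm + na + nc].T
        VZ = X[:, 2 * nm + na + nc :].T
        return E, A, U, Z, VZ

    # -- compliant tendon node quantities -----------------------------------
    def _tendon_eval(self, A, Z, VZ):
        """Vectorized Hill/tendon quantities for all compliant slots."""
        cur = self.curves
        out = {}
        nq = np.empty((self.nc, self.N))
        arrays = {k: np.empty((self.nc, self.N)) for k in
                  ("fT", "dfT", "phi", "dphi_da", "dphi_dz", "dphi_dvz", "d2fT",
                   "d2phi_dz2", "d2phi_dadz", "d2phi_dvz2", "d2phi_dzdvz",
                   "d2phi_dadvz")}
        vmax = cur.v_max
        for s, ci in enumerate(self.comp):
            mc = self.muscles[ci]
            z = Z[s]
            vz = VZ[s]
            a = A[ci]
            s2 = mc.penn_sin**2
            root = np.sqrt(np.maximum(z**2 - s2, 1e-9))
            eps = (mc.l_mtu - mc.l_opt * root) / mc.l_slack - 1.0
            ft = cur.ft(eps)
            dft = cur.dft(eps)
            deps = -(mc.l_opt / mc.l_slack) * z / root
            d2eps = (mc.l_opt / mc.l_slack) * s2 / root**3
            cosa = root / z
            dcosa = s2 / (z**2 * root)
            d2cosa = -s2 * (2.0 / (z**3 * root) + 1.0 / (z * root**3))
            fl = cur.fl(z)
            dfl = cur.dfl(z)
            d2fl = cur.d2fl(z)
            vn = vz / vmax
            fv = cur.fv(vn)
            dfv = cur.dfv(vn)
            d2fv = cur.d2fv(vn)
            fp = cur.fp(z)
            dfp = cur.dfp(z)
            d2fp = cur._fp_k * dfp
            beta = cur.fiber_damping
            fib = a * fl * fv + fp + beta * vn
            arrays["fT"][s] = mc.f_max * ft
            arrays["dfT"][s] = mc.f_max * dft * deps
            arrays["d2fT"][s] = mc.f_max * (cur.tendon_k * dft * deps**2 + dft * d2eps)
            arrays["phi"][s] = ft - fib * cosa
            arrays["dphi_da"][s] = -fl * fv * cosa
            arrays["dphi_dz"][s] = dft * deps - (a * dfl * fv + dfp) * cosa - fib * dcosa
            arrays["dphi_dvz"][s] = -(a * fl * dfv + beta) * cosa / vmax
            arrays["d2phi_dz2"][s] = (
                cur.tendon_k * dft * deps**2 + dft * d2eps
                - (a * d2fl * fv + d2fp) * cosa
                - 2.0 * (a * dfl * fv + dfp) * dcosa
                - fib * d2cosa
            )
            arrays["d2phi_dadz"][s] = -dfl * fv * cosa - fl * fv * dcosa
            arrays["d2phi_dvz2"][s] = -a * fl * d2fv * cosa / vmax**2
            arrays["d2phi_dzdvz"][s] = (-a * dfl * dfv * cosa
                                        - (a * fl * dfv + beta) * dcosa) / vmax
            arrays["d2phi_dadvz"][s] = -fl * dfv * cosa / vmax
            nq[s] = eps
        out.update(arrays)
        out["eps"] = nq
        return out

    def _activation_terms(self, E, A, second_order=False):
        ca = np.array([1.0 / mc.tau_act for mc in self.muscles])[:, None]
        cd = np.array([1.0 / mc.tau_deact for mc in self.muscles])[:, None]
        from .model import _ACT_BLEND_K as _KB
        kb = _KB
        d = E - A
        s = 1.0 / (1.0 + np.exp(-kb * d))
        rc = cd + (ca - cd) * s
        g = d * rc
        sp_ = kb * s * (1.0 - s)
        dg = rc + d * (ca - cd) * sp_
        if not second_order:
            return g, dg  # dg/dE = dg, dg/dA = -dg
        d2g = (ca - cd) * (2.0 * sp_ + d * kb * sp_ * (1.0 - 2.0 * s))
        return g, dg, d2g

    def _ftf_series(self, A, tq):
        F = self.ftf_const.copy()
        for i, kap in self._ftf_a_idx:
            F = F + kap * A[i]
        for s_idx, (ci_slot, i) in enumerate(self._ftf_z_idx):
            F = F + self.muscles[i].knee_cos * tq["fT"][ci_slot]
        return F

    # -- NLP callbacks ------------------------------------------------------
    def constraints(self, x, tq=None, g_act=None):
        E, A, U, Z, VZ = self.unpack(x)
        c = np.zeros(self.n_con)
        # moment balance (constant part + offsets)
        c += self._momA @ x
        off = self.mom_offset  # (nd, N)
        karr = np.arange(self.N)
        for j in range(self.nd):
            c[self.row_moment + karr * self.nd + j] += off[j]
        if self.nc:
            if tq is None:
                tq = self._tendon_eval(A, Z, VZ)
            np.add.at(c, self._mom_var_rows,
                      self._mom_var_mult * tq["fT"][self._mom_var_comp,
                                                    self._mom_var_cols // self.stride])
            c[self._eq_rows] = tq["phi"].T.ravel()
        if g_act is None:
            g_act, _ = self._activation_terms(E, A)
        defect = A[:, 1:] - A[:, :-1] - (self.h / 2.0) * (g_act[:, 1:] + g_act[:, :-1])
        c[self.row_actdef : self.row_zdef] = defect.T.ravel()
        c += self._zdefJ @ x
        c[self.row_tie :] = E[:, 0] - A[:, 0]
        return c

    def jacobian(self, x, tq):
        E, A, U, Z, VZ = self.unpack(x)
        _, dg = self._activation_terms(E, A)
        parts_r, parts_c, parts_v = [], [], []
        # moment balance variable entries
        if self._mom_var_rows.size:
            node = self._mom_var_cols // self.stride
            vals = self._mom_var_mult * tq["dfT"][self._mom_var_comp, node]
            parts_r.append(self._mom_var_rows)
            parts_c.append(self._mom_var_cols)
            parts_v.append(vals)
        # tendon equilibrium entries
        if self.nc:
            parts_r += [self._eq_rows] * 3
            parts_c += [self._eq_cols_a, self._eq_cols_z, self._eq_cols_vz]
            parts_v += [tq["dphi_da"].T.ravel(), tq["dphi_dz"].T.ravel(),
                        tq["dphi_dvz"].T.ravel()]
        # activation defects
        kk = np.arange(self.N - 1)
        dg0 = dg[:, :-1].ravel()  # (nm, N-1) order i-major
        dg1 = dg[:, 1:].ravel()
        h = np.tile(self.h, (self.nm, 1)).ravel()
        parts_r += [self._ad_rows] * 4
        parts_c += [self._ad_cols_a0, self._ad_cols_a1, self._ad_cols_e0, self._ad_cols_e1]
        parts_v += [
            -1.0 - (h / 2.0) * (-dg0),
            1.0 - (h / 2.0) * (-dg1),
            -(h / 2.0) * dg0,
            -(h / 2.0) * dg1,
        ]
        J = sp.coo_matrix(
            (np.concatenate(parts_v), (np.concatenate(parts_r), np.concatenate(parts_c))),
            shape=(self.n_con, self.n_var)).tocsr()
        return J + self._momA + self._zdefJ + self._tieJ

    def objective(self, x, tq=None):
        E, A, U, Z, VZ = self.unpack(x)
        J = self.cfg.w1 * (np.sum(self.wq * E**2) + np.sum(self.wq * U**2))
        J += self.cfg.w2 * np.sum(self.wq * VZ**2)
        if self.cfg.mode == "J2" and self._ftf_cols_per_node is not None:
            if tq is None:
                tq = self._tendon_eval(A, Z, VZ) if self.nc else {}
            F = self._ftf_series(A, tq)
            J += self.leg_factor * self.cfg.w3 * np.sum(self.wq * F**2)
        return float(J)

    def gradient_hessian(self, x, tq, lam=None):
        # _obj_diag holds 2*w*wq, so the gradient of w*wq*x^2 is _obj_diag*x
        g = self._obj_diag * x
        H_rows = [np.arange(self.n_var)]
        H_cols = [np.arange(self.n_var)]
        H_vals = [self._obj_diag.copy()]
        if self.cfg.mode == "J2" and self._ftf_cols_per_node is not None:
            E, A, U, Z, VZ = self.unpack(x)
            F = self._ftf_series(A, tq)
            cw = 2.0 * self.leg_factor * self.cfg.w3 * self.wq  # (N,)
            # gradient entries per participating variable
            grads = []  # (P, N) dF/dvar
            for i, kap in self._ftf_a_idx:
                grads.append(kap)
            for ci_slot, i in self._ftf_z_idx:
                grads.append(self.muscles[i].knee_cos * tq["dfT"][ci_slot])
            G = np.array(grads)  # (P, N)
            np.add.at(g, self._ftf_cols_per_node, cw * F * G)
            # Gauss-Newton block: cw_k * G_k G_k^T, plus exact diagonal term
            P = G.shape[0]
            block = cw[None, None, :] * G[:, None, :] * G[None, :, :]
            H_rows.append(self._ftf_hess_rows)
            H_cols.append(self._ftf_hess_cols)
            H_vals.append(block.reshape(P * P, self.N).ravel())
            # exact curvature of the compliant (z) contributions
            nA = len(self._ftf_a_idx)
            for s_idx, (ci_slot, i) in enumerate(self._ftf_z_idx):
                d2 = self.muscles[i].knee_cos * tq["d2fT"][ci_slot]
                cols = self._ftf_cols_per_node[nA + s_idx]
                H_rows.append(cols)
                H_cols.append(cols)
                H_vals.append(cw * F * d2)
        # exact constraint curvature (Lagrangian Hessian): the stiff tendon
        # exponential and the activation blend carry the significant
        # second-order terms; without them Newton stalls near the solution.
        if lam is not None:
            if self._mom_var_rows.size:
                node = self._mom_var_cols // self.stride
                vals = (lam[self._mom_var_rows] * self._mom_var_mult
                        * tq["d2fT"][self._mom_var_comp, node])
                H_rows.append(self._mom_var_cols)
                H_cols.append(self._mom_var_cols)
                H_vals.append(vals)
            if self.nc:
                le = lam[self._eq_rows]
                pairs = [
                    (self._eq_cols_z, self._eq_cols_z, "d2phi_dz2", False),
                    (self._eq_cols_a, self._eq_cols_z, "d2phi_dadz", True),
                    (self._eq_cols_vz, self._eq_cols_vz, "d2phi_dvz2", False),
                    (self._eq_cols_z, self._eq_cols_vz, "d2phi_dzdvz", True),
                    (self._eq_cols_a, self._eq_cols_vz, "d2phi_dadvz", True),
                ]
                for r_, c_, key, sym in pairs:
                    v = le * tq[key].T.ravel()
                    H_rows.append(r_)
                    H_cols.append(c_)
                    H_vals.append(v)
                    if sym:
                        H_rows.append(c_)
                        H_cols.append(r_)
                        H_vals.append(v)
            E, A, U, Z, VZ = self.unpack(x)
            _, _, d2g = self._activation_terms(E, A, second_order=True)
            la = lam[self._ad_rows]
            h = np.tile(self.h, (self.nm, 1)).ravel()
            for g2, cols in ((d2g[:, :-1].ravel(), (self._ad_cols_e0, self._ad_cols_a0)),
                             (d2g[:, 1:].ravel(), (self._ad_cols_e1, self._ad_cols_a1))):
                v = la * (-h / 2.0) * g2
                ce, ca_ = cols
                H_rows += [ce, ca_, ce, ca_]
                H_cols += [ce, ca_, ca_, ce]
                H_vals += [v, v, -v, -v]
        H = sp.coo_matrix(
            (np.concatenate(H_vals), (np.concatenate(H_rows), np.concatenate(H_cols))),
            shape=(self.n_var, self.n_var)).tocsc()
        return g, H

    def eval_full(self, x, lam=None):
        E, A, U, Z, VZ = self.unpack(x)
        tq = self._tendon_eval(A, Z, VZ) if self.nc else {}
        s = self.obj_scale
        # the Lagrangian Hessian terms carry unscaled multipliers, so scale
        # them back up to the scaled objective's units
        lam_in = lam if lam is None or s == 1.0 else lam / s
        sx = self._smoothH @ x
        f = (self.objective(x, tq=tq) + 0.5 * float(x @ sx)) * s
        c = self.constraints(x, tq=tq)
        J = self.jacobian(x, tq)
        g, H = self.gradient_hessian(x, tq, lam=lam_in)
        return f, (g + sx) * s, (H + self._smoothH) * s, c, J

    def eval_fc(self, x):
        E, A, U, Z, VZ = self.unpack(x)
        tq = self._tendon_eval(A, Z, VZ) if self.nc else {}
        f = self.objective(x, tq=tq) + 0.5 * float(x @ (self._smoothH @ x))
        return f * self.obj_scale, self.constraints(x, tq=tq)

    # -- initial guess ------------------------------------------------------
    def rigid_equivalent_kappas(self):
        """(kappa_act, kappa_pas) per muscle treating every tendon as rigid;
        used for the static-optimization initial guess."""
        cur = self.curves
        ka = np.empty((self.nm, self.N))
        kp = np.empty((self.nm, self.N))
        for i, mc in enumerate(self.muscles):
            if mc.rigid:
                ka[i] = mc.kappa_act
                kp[i] = mc.kappa_pas
            else:
                s2 = mc.penn_sin**2
                proj = np.maximum((mc.l_mtu - mc.l_slack) / mc.l_opt, 0.05)
                z = np.sqrt(proj**2 + s2)
                cosa = proj / z
                v_mtu = np.gradient(mc.l_mtu, self.times)
                vn = np.clip(v_mtu * cosa / (mc.l_opt * cur.v_max), -0.95, 0.95)
                ka[i] = cur.fl(z) * cur.fv(vn) * mc.f_max * cosa
                kp[i] = cur.fp(z) * mc.f_max * cosa
        return ka, kp

    def initial_guess(self) -> np.ndarray:
        """Deterministic warm start from a per-node static optimization.

        Per node: a convex QP over (a, u) minimizing effort (plus the
        tibiofemoral penalty in J2 mode) under linearized (rigid-equivalent)
        moment balance; then the compliant z solve the tendon equilibrium at
        those activations, vz by differencing, and e = a.
        """
        ka, kp = self.rigid_equivalent_kappas()
        A = np.zeros((self.nm, self.N))
        U = np.zeros((self.na, self.N))
        kap_c = np.zeros((self.nm, self.N))
        if self.cfg.mode == "J2":
            for i, mc in enumerate(self.muscles):
                if mc.knee_cos is not None:
                    kap_c[i] = mc.knee_cos * ka[i]
        prev = np.concatenate([np.full(self.nm, 0.05), np.zeros(self.na)])
        for k in range(self.N):
            Aeq = np.zeros((self.nd, self.nm + self.na))
            beq = np.zeros(self.nd)
            for j, dof in enumerate(self.dof_names):
                for i, mc in enumerate(self.muscles):
                    if dof in mc.arms:
                        Aeq[j, i] = mc.arms[dof][k] * ka[i, k]
                        beq[j] -= mc.arms[dof][k] * kp[i, k]
                for m, ac in enumerate(self.actuators):
                    if ac.dof == dof:
                        Aeq[j, self.nm + m] = ac.capacity
                beq[j] += self.demand[j, k]
                Aeq[j] /= self.row_scale[j]
                beq[j] /= self.row_scale[j]
            w3n = 2.0 * self.leg_factor * self.cfg.w3 if self.cfg.mode == "J2" else 0.0
            kc_k = kap_c[:, k]
            F0 = self.ftf_const[k]

            def qp_obj(v, kc_k=kc_k, F0=F0, w3n=w3n):
                a = v[: self.nm]
                u = v[self.nm :]
                val = self.cfg.w1 * (np.sum(a**2) + np.sum(u**2))
                grad = np.concatenate([2 * self.cfg.w1 * a, 2 * self.cfg.w1 * u])
                if w3n > 0.0:
                    F = F0 + kc_k @ a
                    val += 0.5 * w3n * F**2
                    grad[: self.nm] += w3n * F * kc_k
                return val, grad

            cons = {"type": "eq", "fun": lambda v, Aeq=Aeq, beq=beq: Aeq @ v - beq,
                    "jac": lambda v, Aeq=Aeq: Aeq}
            bounds = [(0.0, 1.0)] * self.nm + [(-1.0, 1.0)] * self.na
            res = minimize(qp_obj, prev, jac=True, method="SLSQP", bounds=bounds,
                           constraints=[cons],
                           options={"maxiter": 120, "ftol": 1e-10})
            v = res.x if res.success else np.clip(prev, 0.0, 1.0)
            A[:, k] = np.clip(v[: self.nm], 0.0, 1.0)
            U[:, k] = np.clip(v[self.nm :], -1.0, 1.0)
            prev = v

        Z = np.empty((self.nc, self.N))
        for s_idx, ci in enumerate(self.comp):
            Z[s_idx] = self._equilibrium_z(self.muscles[ci], A[ci])
        VZ = np.gradient(Z, self.times, axis=1) if self.nc else np.empty((0, self.N))
        VZ = np.clip(VZ, -0.9 * self.VZ_MAX, 0.9 * self.VZ_MAX)

        x0 = np.zeros(self.n_var)
        karr = np.arange(self.N)
        for i in range(self.nm):
            x0[self.idx_e(i, karr)] = A[i]
            x0[self.idx_a(i, karr)] = A[i]
        for m in range(self.na):
            x0[self.idx_u(m, karr)] = U[m]
        for s_idx in range(self.nc):
            x0[self.idx_z(s_idx, karr)] = Z[s_idx]
            x0[self.idx_vz(s_idx, karr)] = VZ[s_idx]
        return x0

    def _equilibrium_z(self, mc: MuscleChannel, a: np.ndarray) -> np.ndarray:
        """Vectorized bisection for the tendon equilibrium at zero fiber
        velocity, given activations."""
        cur = self.curves
        lo = np.full(self.N, self.Z_MIN + 1e-3)
        hi = np.full(self.N, self.Z_MAX - 1e-3)

        def resid(z):
            s2 = mc.penn_sin**2
            root = np.sqrt(np.maximum(z**2 - s2, 1e-9))
            eps = (mc.l_mtu - mc.l_opt * root) / mc.l_slack - 1.0
            cosa = root / z
            return cur.ft(eps) - (a * cur.fl(z) + cur.fp(z)) * cosa

        rlo = resid(lo)
        for _ in range(70):
            mid = 0.5 * (lo + hi)
            rm = resid(mid)
            same = np.sign(rm) == np.sign(rlo)
            lo = np.where(same, mid, lo)
            rlo = np.where(same, rm, rlo)
            hi = np.where(same, hi, mid)
        return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Problem construction from a trial
# ---------------------------------------------------------------------------


def build_problem(model: MusculoskeletalModel, trial, moments: NetMoments,
                  cfg: ObjectiveConfig, grid: CollocationGrid, side: str = "r",
                  inter=None) -> CollocationProblem:
    """Transcribe the muscle-redundancy problem of one leg.

    Decision variables are the controls (excitations, actuator controls),
    activations, and compliant-tendon auxiliary states at the grid nodes.
    Pelvis DOFs carry residual actuators against the (zero, by dynamic
    consistency) post-saddle pelvis demand.  In J2 mode the compressive
    tibiofemoral force is assembled from the same variables; under the
    generator's bilateral symmetry the two legs contribute equal integrals,
    handled by a leg factor of 2.
    """
    cfg.validate()
    grid.validate()
    kin: TrialKinematics = trial.kin
    times = grid.times
    if times[0] < kin.time[0] or times[-1] > kin.time[-1]:
        raise ValueError("collocation grid extends beyond the trial time span")

    leg_dofs = [f"hip_flexion_{side}", f"knee_flexion_{side}", f"ankle_dorsiflexion_{side}"]
    q = {d: kin.angle(d, times) for d in leg_dofs}
    qd = {d: kin.velocity(d, times) for d in leg_dofs}

    if inter is None:
        _, inter = net_joint_moments(kin, trial.loads[side], model, trial.geom, side=side)

    muscles = []
    cur = model.hill_curves
    for mtu in model.mtus_for_leg(side):
        arms = {d: np.asarray(moment_arm(mtu, d, q[d])) for d in mtu.moment_arm_coeffs
                if d in q}
        l_mtu = np.asarray(mtu_length(mtu, q, model.reference_posture))
        v_mtu = np.zeros_like(l_mtu)
        for d in arms:
            v_mtu -= arms[d] * qd[d]
        knee_cos = None
        kd = f"knee_flexion_{side}"
        if kd in arms and mtu.insertion_distance:
            sinphi = np.clip(np.abs(arms[kd]) / mtu.insertion_distance, 0.0, 0.98)
            knee_cos = np.sqrt(1.0 - sinphi**2)
        mc = MuscleChannel(
            name=mtu.name, f_max=mtu.f_max, tau_act=mtu.tau_act, tau_deact=mtu.tau_deact,
            rigid=mtu.rigid_tendon, arms=arms, penn_sin=math.sin(mtu.pennation_opt),
            knee_cos=knee_cos,
        )
        if mtu.rigid_tendon:
            s2 = mc.penn_sin**2
            proj = np.maximum((l_mtu - mtu.l_slack) / mtu.l_opt, 0.05)
            z = np.sqrt(proj**2 + s2)
            cosa = proj / z
            vn = np.clip(v_mtu * cosa / (mtu.l_opt * cur.v_max), -0.95, 0.95)
            mc.kappa_act = cur.fl(z) * cur.fv(vn) * mtu.f_max * cosa
            # passive element includes the parallel fiber damper
            mc.kappa_pas = (cur.fp(z) + cur.fiber_damping * vn) * mtu.f_max * cosa
        else:
            mc.l_mtu = l_mtu
            mc.l_opt = mtu.l_opt
            mc.l_slack = mtu.l_slack
        muscles.append(mc)

    demands: dict[str, np.ndarray] = {}
    for d in leg_dofs:
        demands[d] = np.interp(times, moments.time, moments[d])
    for d in ("pelvis_x", "pelvis_y", "pelvis_tilt"):
        demands[d] = np.zeros(len(times))  # saddle closure absorbs the pelvis load

    actuators = []
    for ac in model.actuators:
        if ac.dof in demands:
            actuators.append(ActuatorChannel(ac.name, ac.dof, ac.capacity))

    # muscle-free compressive intersegmental contribution to F_tf
    axial = np.interp(times, kin.time, inter.axial_knee)
    # rigid passive compressive offsets are folded in here
    ftf_const = axial.copy()
    for mc in muscles:
        if mc.knee_cos is not None and mc.rigid:
            ftf_const += mc.knee_cos * mc.kappa_pas

    return CollocationProblem(grid, muscles, demands, actuators, cfg, cur,
                              ftf_const=ftf_const, leg_factor=2.0)


# ---------------------------------------------------------------------------
# Solution container and solve()
# ---------------------------------------------------------------------------


@dataclass
class RedundancySolution:
    """Converged redundancy solution on the collocation grid."""

    times: np.ndarray
    muscle_names: list[str]
    actuator_names: list[str]
    dof_names: list[str]
    excitations: np.ndarray  # (nm, N)
    activations: np.ndarray
    controls: np.ndarray  # (na, N), dimensionless in [-1, 1]
    aux_states: np.ndarray  # (nc, N) normalized fiber lengths
    aux_rates: np.ndarray  # (nc, N)
    force_active: np.ndarray  # (nm, N) along-tendon active fiber force, N
    force_passive: np.ndarray
    force_total: np.ndarray
    reserve_torques: dict[str, np.ndarray]  # dof -> N*m series
    residual_forces: dict[str, np.ndarray]
    objective: float
    moment_residuals: np.ndarray  # (nd, N), N*m (unscaled)
    iterations: int
    status: str
    grid: CollocationGrid = None
    cfg: ObjectiveConfig = None
    knee_cos: dict[str, np.ndarray] = field(default_factory=dict)
    x_raw: np.ndarray = None  # decision vector, usable as a warm start


def solve(problem: CollocationProblem, cfg: ObjectiveConfig | None = None,
          x0: np.ndarray | None = None, max_iter: int = 400,
          verbose: bool = False) -> RedundancySolution:
    """Solve the transcribed problem; deterministic for a fixed initial guess.

    Raises :class:`ConvergenceError` (carrying the last iterate and its
    residuals) if the interior-point continuation fails.
    """
    cfg = cfg or problem.cfg
    if x0 is None:
        x0 = problem.initial_guess()
    # gradient-based objective scaling (tolerances apply to the scaled problem)
    problem.obj_scale = 1.0
    _, g0, _, _, _ = problem.eval_full(np.clip(x0, problem.lb, problem.ub))
    gmax = float(np.max(np.abs(g0)))
    problem.obj_scale = min(1.0, 100.0 / gmax) if gmax > 0 else 1.0
    res = solve_ip(problem.eval_full, problem.eval_fc, x0, problem.lb, problem.ub,
                   tol_stat=cfg.convergence_tol, tol_con=cfg.constraint_tol,
                   max_iter=max_iter, verbose=verbose)
    return extract_solution(problem, res.x, iterations=res.iterations, status=res.status)


def extract_solution(problem: CollocationProblem, x: np.ndarray,
                     iterations: int = 0, status: str = "converged") -> RedundancySolution:
    E, A, U, Z, VZ = problem.unpack(x)
    cur = problem.curves
    nm, N = problem.nm, problem.N
    fa = np.zeros((nm, N))
    fp_ = np.zeros((nm, N))
    knee_cos = {}
    for i, mc in enumerate(problem.muscles):
        if mc.rigid:
            fa[i] = A[i] * mc.kappa_act
            fp_[i] = mc.kappa_pas
        else:
            s_idx = problem.comp.index(i)
            z = Z[s_idx]
            cosa = pennation_cos(z, math.asin(mc.penn_sin))
            vn = VZ[s_idx] / cur.v_max
            fa[i] = A[i] * cur.fl(z) * cur.fv(vn) * mc.f_max * cosa
            fp_[i] = (cur.fp(z) + cur.fiber_damping * vn) * mc.f_max * cosa
        if mc.knee_cos is not None:
            knee_cos[mc.name] = mc.knee_cos

    c = problem.constraints(x)
    karr = np.arange(N)
    mom_res = np.empty((problem.nd, N))
    for j in range(problem.nd):
        mom_res[j] = c[problem.row_moment + karr * problem.nd + j] * problem.row_scale[j]

    reserves, residuals = {}, {}
    for m, ac in enumerate(problem.actuators):
        series = U[m] * ac.capacity
        if ac.dof.startswith("pelvis"):
            residuals[ac.dof] = series
        else:
            reserves[ac.dof] = series

    return RedundancySolution(
        times=problem.times.copy(),
        muscle_names=[mc.name for mc in problem.muscles],
        actuator_names=[ac.name for ac in problem.actuators],
        dof_names=list(problem.dof_names),
        excitations=E.copy(), activations=A.copy(), controls=U.copy(),
        aux_states=Z.copy(), aux_rates=VZ.copy(),
        force_active=fa, force_passive=fp_, force_total=fa + fp_,
        reserve_torques=reserves, residual_forces=residuals,
        objective=problem.objective(x),
        moment_residuals=mom_res,
        iterations=iterations, status=status, grid=problem.grid, cfg=problem.cfg,
        knee_cos=knee_cos, x_raw=x.copy(),
    )


# ---------------------------------------------------------------------------
# Objective arithmetic (stand-alone, used for closed-form checks)
# ---------------------------------------------------------------------------


def objective_value(excitations, controls, aux_rates, f_tf_legs, cfg: ObjectiveConfig,
                    times) -> float:
    """Trapezoid-quadrature objective for explicit trajectories.

    ``excitations`` (nm, N), ``controls`` (na, N), ``aux_rates`` (nc, N),
    ``f_tf_legs`` a sequence of per-leg F_tf series (each (N,)).
    """
    cfg.validate()
    t = np.asarray(times, dtype=float)

    def integ(series2d):
        if series2d is None or len(series2d) == 0:
            return 0.0
        arr = np.atleast_2d(np.asarray(series2d, dtype=float))
        return float(sum(np.trapezoid(row**2, t) for row in arr))

    J = cfg.w1 * (integ(excitations) + integ(controls)) + cfg.w2 * integ(aux_rates)
    if cfg.mode == "J2":
        J += cfg.w3 * sum(float(np.trapezoid(np.asarray(f) ** 2, t)) for f in f_tf_legs)
    return J


# ---------------------------------------------------------------------------
# Static-optimization oracle (tests only)
# ---------------------------------------------------------------------------


class InfeasibleNodeError(RuntimeError):
    def __init__(self, node, message):
        super().__init__(message)
        self.node = node


def static_optimization_oracle(model: MusculoskeletalModel, trial, moments: NetMoments,
                               side: str = "r", times=None,
                               include_reserves: bool = False) -> np.ndarray:
    """Independent per-node oracle: minimize sum(a^2) under moment balance
    with all tendons forced rigid and activation dynamics ignored.

    Returns (n_muscles, n_times) activations; raises
    :class:`InfeasibleNodeError` when a node's demand exceeds capacity.
    """
    kin = trial.kin
    if times is None:
        times = kin.time
    times = np.asarray(times, dtype=float)
    leg_dofs = [f"hip_flexion_{side}", f"knee_flexion_{side}", f"ankle_dorsiflexion_{side}"]
    q = {d: kin.angle(d, times) for d in leg_dofs}
    qd = {d: kin.velocity(d, times) for d in leg_dofs}
    cur = model.hill_curves
    mtus = model.mtus_for_leg(side)
    nm = len(mtus)
    N = len(times)

    ka = np.empty((nm, N))
    kp = np.empty((nm, N))
    arms = []
    for i, mtu in enumerate(mtus):
        am = {d: np.asarray(moment_arm(mtu, d, q[d])) for d in mtu.moment_arm_coeffs if d in q}
        arms.append(am)
        l_mtu = np.asarray(mtu_length(mtu, q, model.reference_posture))
        v_mtu = np.zeros_like(l_mtu)
        for d in am:
            v_mtu -= am[d] * qd[d]
        s2 = math.sin(mtu.pennation_opt) ** 2
        proj = np.maximum((l_mtu - mtu.l_slack) / mtu.l_opt, 0.05)
        z = np.sqrt(proj**2 + s2)
        cosa = proj / z
        vn = np.clip(v_mtu * cosa / (mtu.l_opt * cur.v_max), -0.95, 0.95)
        ka[i] = cur.fl(z) * cur.fv(vn) * mtu.f_max * cosa
        kp[i] = (cur.fp(z) + cur.fiber_damping * vn) * mtu.f_max * cosa

    caps = []
    if include_reserves:
        caps = [(ac.dof, ac.capacity) for ac in model.actuators
                if ac.kind == "reserve_torque" and ac.dof in leg_dofs]
    nu = len(caps)

    demand = np.vstack([np.interp(times, moments.time, moments[d]) for d in leg_dofs])
    A = np.zeros((nm, N))
    prev = np.full(nm + nu, 0.05)
    for k in range(N):
        Aeq = np.zeros((len(leg_dofs), nm + nu))
        beq = demand[:, k].copy()
        for j, d in enumerate(leg_dofs):
            for i in range(nm):
                if d in arms[i]:
                    Aeq[j, i] = arms[i][d][k] * ka[i, k]
                    beq[j] -= arms[i][d][k] * kp[i, k]
            for m, (dd, cap) in enumerate(caps):
                if dd == d:
                    Aeq[j, nm + m] = cap
        Aeq /= CollocationProblem.MOMENT_SCALE
        beq /= CollocationProblem.MOMENT_SCALE

        res = minimize(
            lambda v: (float(np.sum(v[:nm] ** 2) + np.sum(v[nm:] ** 2)),
                       np.concatenate([2 * v[:nm], 2 * v[nm:]])),
            prev, jac=True, method="SLSQP",
            bounds=[(0.0, 1.0)] * nm + [(-1.0, 1.0)] * nu,
            constraints=[{"type": "eq", "fun": lambda v, A_=Aeq, b_=beq: A_ @ v - b_,
                          "jac": lambda v, A_=Aeq: A_}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        viol = float(np.max(np.abs(Aeq @ res.x - beq))) if res.x is not None else np.inf
        if not res.success and viol > 1e-6:
            raise InfeasibleNodeError(
                k, f"static optimization infeasible at node {k} "
                   f"(t={times[k]:.4f}s, violation {viol:.2e})")
        A[:, k] = np.clip(res.x[:nm], 0.0, 1.0)
        prev = res.x
    return A
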