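"""Direct-collocation transcription of the gait optimal-control problem.

Separated Hermite-Simpson collocation: states and controls live on mesh nodes
*and* interval midpoints (M = 2N+1 sample points for N intervals).  Each
interval contributes a Hermite interpolation defect and a Simpson quadrature
defect, and every sample point carries the full set of path constraints, so
the NLP sees the dynamics and the contact complementarity structure at twice
the resolution of the node grid.

Decision vector layout (normalized units throughout)::

    w = [ X.ravel(): M x 16 states,
          U.ravel(): M x  7 force-rate controls,
          footholds: 4 ]

States per point: x, y, theta, vx, vy, thetadot, F (7 channels), z (3 running
integrals of the leading-contact forces).  Forces are states and force rates
are the only controls, so ground reaction forces are C0 by construction and
endpoint force conditions are simple bounds.

The positive/negative limb-power slacks p, q and the relaxation variables
s_a, s_b, s_c of the mathematical formulation are not carried as decision
variables: the solver works with an epsilon-smoothed |F*ldot| objective
residual and weighted constraint residuals (an exact-penalty/multiplier
treatment of the same complementarity conditions), and the slacks are
recovered exactly from the converged trajectory (p = max(F*ldot, 0),
q = max(-F*ldot, 0), s = 0), where they satisfy complementarity identically.

The cost and every constraint enter a Gauss-Newton solver as residual blocks
with analytic sparse Jacobians assembled from
:func:`quadrugait.dynamics.channel_geometry` partials; structure (rows, cols,
gather maps) is precomputed once per mesh so each evaluation is a vectorized
fill.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from . import dynamics
from .constraints import EPS_CLEARANCE
from .dynamics import (
    FOOT_PARAM_OF_CHANNEL,
    GIRDLE_SIGN,
    LEADING,
    LEFT_CHANNELS,
    N_CHANNELS,
    TRAILING,
)
from .morphology import GaitTask, Morphology
from .trajectory import Trajectory, channel_feet

__all__ = ["Transcription", "NX", "NU", "CU_FDOT", "SX_F", "SX_Z"]

NX = 16  # states per point
NU = 7  # controls per point (force rates)

SX_F = 6  # first force-channel state index
SX_Z = 13  # first running-integral state index
CU_FDOT = 0

_SIDE_SIGN = np.array([+1 if c in LEFT_CHANNELS else -1 for c in range(N_CHANNELS)], float)


class Transcription:
    """One fixed-mesh NLP for a given morphology, task and interval count."""

    def __init__(self, morphology: Morphology, task: GaitTask, n_segments: int):
        if n_segments < 2:
            raise ValueError("need at least 2 mesh intervals")
        self.morph = morphology
        self.task = task
        self.N = int(n_segments)
        self.M = 2 * self.N + 1
        self.h = 1.0 / self.N
        self.t = np.linspace(0.0, 1.0, self.M)  # nodes and midpoints interleaved

        self.D_prime = task.D_prime
        self.T2 = task.T_hat ** 2
        self.I_prime = morphology.I_prime
        self.lmax_ch = np.where(
            GIRDLE_SIGN > 0, morphology.lFmax_prime, morphology.lHmax_prime
        )

        M = self.M
        self.n_state_vars = NX * M
        self.n_control_vars = NU * M
        self.CSTART = self.n_state_vars
        self.FSTART = self.n_state_vars + self.n_control_vars
        self.n_vars = self.FSTART + 4

        # Simpson quadrature weights over the sample points
        w = np.zeros(M)
        for i in range(self.N):
            w[2 * i] += self.h / 6.0
            w[2 * i + 1] += 4.0 * self.h / 6.0
            w[2 * i + 2] += self.h / 6.0
        self.quad_w = w

        self.eps_work = 1e-3  # |power| smoothing, set per homotopy stage
        self._cache_key = None
        self._cache = None
        self._build_structure()

    # ------------------------------------------------------------------ layout
    def xcol(self, point, k):
        return point * NX + k

    def ucol(self, point, k):
        return self.CSTART + point * NU + k

    def fcol(self, j):
        return self.FSTART + j

    def unpack(self, w):
        X = w[: self.n_state_vars].reshape(self.M, NX)
        U = w[self.n_state_vars : self.FSTART].reshape(self.M, NU)
        feet4 = w[self.FSTART :]
        return X, U, feet4

    def pack(self, X, U, feet4):
        return np.concatenate([X.ravel(), U.ravel(), np.asarray(feet4, float)])

    def trajectory(self, w) -> Trajectory:
        """Trajectory with the power slacks recovered from the converged forces."""
        X, U, feet4 = self.unpack(w)
        feet4 = np.array(feet4, float)
        traj = Trajectory(
            t=self.t.copy(),
            body=X[:, :6].copy(),
            F=X[:, SX_F : SX_F + 7].copy(),
            z=X[:, SX_Z : SX_Z + 3].copy(),
            Fdot=U[:, CU_FDOT : CU_FDOT + 7].copy(),
            p=np.zeros((self.M, 7)),
            q=np.zeros((self.M, 7)),
            s_a=np.zeros((self.M, 7)),
            s_b=np.zeros((self.M, 3)),
            s_c=np.zeros((self.M, 7)),
            footholds=feet4,
            D_prime=self.D_prime,
            morphology=self.morph,
        )
        power = traj.limb_powers()
        traj.p = np.maximum(power, 0.0)
        traj.q = np.maximum(-power, 0.0)
        return traj

    # ------------------------------------------------------- shared evaluation
    def _compute(self, w):
        """Geometry, dynamics values and partials at all sample points (cached)."""
        key = hash(w.tobytes())
        if key == self._cache_key:
            return self._cache
        X, U, feet4 = self.unpack(w)
        feet = channel_feet(feet4, self.D_prime)  # (7,)
        x, y, th, vx, vy, om = X[:, :6].T
        F = X[:, SX_F : SX_F + 7]
        g = dynamics.channel_geometry(
            x, y, th, vx, vy, om, np.broadcast_to(feet, (self.M, N_CHANNELS)),
            self.morph, derivs=True,
        )
        # state derivative f(X, U) at every point
        f = np.empty((self.M, NX))
        f[:, 0] = vx
        f[:, 1] = vy
        f[:, 2] = om
        f[:, 3] = self.T2 * np.sum(F * g["ux"], axis=1)
        f[:, 4] = self.T2 * (-1.0 + np.sum(F * g["uy"], axis=1))
        f[:, 5] = (self.T2 / self.I_prime) * np.sum(F * g["crossu"], axis=1)
        f[:, 6:13] = U[:, CU_FDOT : CU_FDOT + 7]
        f[:, 13:16] = F[:, list(LEADING)]

        out = {"X": X, "U": U, "feet4": feet4, "feet": feet, "g": g, "f": f, "F": F}
        self._cache_key, self._cache = key, out
        return out

    # ------------------------------------------------------------- structure
    def _build_structure(self):
        """Precompute sparsity (rows, cols) and gather maps for all Jacobians."""
        N, M = self.N, self.M

        # ---- dynamics jacobian pattern: per-point (row k, column-kind) entries
        # value array computed in _dyn_jac_values in this exact order
        pat_rows, pat_kind, pat_sub = [], [], []

        def add(k, kind, sub):
            pat_rows.append(k)
            pat_kind.append(kind)
            pat_sub.append(sub)

        add(0, "xs", 3)
        add(1, "xs", 4)
        add(2, "xs", 5)
        for k in (3, 4, 5):
            for sub in (0, 1, 2):
                add(k, "xs", sub)
            for c in range(7):
                add(k, "xs", SX_F + c)
            for j in range(4):
                add(k, "foot", j)
        for c in range(7):
            add(6 + c, "us", CU_FDOT + c)
        for jj, c in enumerate(LEADING):
            add(13 + jj, "xs", SX_F + c)
        self._dyn_pat_rows = np.array(pat_rows)
        self._dyn_pat_kind = pat_kind
        self._dyn_pat_sub = np.array(pat_sub)
        self.n_dyn_pat = len(pat_rows)

        # ---- equality constraints ---------------------------------------
        self.EQ_HS1 = 0
        self.EQ_HS2 = N * NX
        self.EQ_ORD = 2 * N * NX
        self.EQ_PER = self.EQ_ORD + 3 * M
        self.EQ_LR = self.EQ_PER + 8
        self.n_eq = self.EQ_LR + 2

        rows, cols, const = [], [], []
        g_rows, g_cols, g_point, g_pat, g_coef = [], [], [], [], []

        def col_of(point, kind, sub):
            if kind == "xs":
                return self.xcol(point, sub)
            if kind == "us":
                return self.ucol(point, sub)
            return self.fcol(sub)

        h = self.h
        for i in range(N):
            a, m, b = 2 * i, 2 * i + 1, 2 * i + 2
            for k in range(NX):
                r1 = self.EQ_HS1 + i * NX + k
                r2 = self.EQ_HS2 + i * NX + k
                rows += [r1, r1, r1, r2, r2]
                cols += [self.xcol(m, k), self.xcol(a, k), self.xcol(b, k),
                         self.xcol(b, k), self.xcol(a, k)]
                const += [1.0, -0.5, -0.5, 1.0, -1.0]
            # dynamics contributions
            for point, c1, c2 in ((a, -h / 8.0, -h / 6.0),
                                  (b, +h / 8.0, -h / 6.0),
                                  (m, 0.0, -4.0 * h / 6.0)):
                for e in range(self.n_dyn_pat):
                    k = self._dyn_pat_rows[e]
                    cc = col_of(point, self._dyn_pat_kind[e], self._dyn_pat_sub[e])
                    if point != m:  # HS1 has no midpoint dynamics term
                        g_rows.append(self.EQ_HS1 + i * NX + k)
                        g_cols.append(cc)
                        g_point.append(point)
                        g_pat.append(e)
                        g_coef.append(c1)
                    g_rows.append(self.EQ_HS2 + i * NX + k)
                    g_cols.append(cc)
                    g_point.append(point)
                    g_pat.append(e)
                    g_coef.append(c2)

        # ordering rows: F_T * z = 0 (trailing silent once leading has loaded)
        od_rows, od_cols = [], []
        for P in range(M):
            for j, cT in enumerate(TRAILING):
                r = self.EQ_ORD + P * 3 + j
                od_rows += [r, r]
                od_cols += [self.xcol(P, SX_F + cT), self.xcol(P, SX_Z + j)]
        self._od_rows = np.array(od_rows)
        self._od_cols = np.array(od_cols)

        # periodicity (linear, constant jacobian)
        last = M - 1
        for kk in range(5):  # y, th, vx, vy, om periodic
            r = self.EQ_PER + kk
            rows += [r, r]
            cols += [self.xcol(last, 1 + kk), self.xcol(0, 1 + kk)]
            const += [1.0, -1.0]
        for jj, (cT, cL) in enumerate(zip(TRAILING, LEADING)):
            r = self.EQ_PER + 5 + jj
            rows += [r, r]
            cols += [self.xcol(last, SX_F + cL), self.xcol(0, SX_F + cT)]
            const += [1.0, -1.0]

        # left-right impulse rows (vertical, fore-aft): per point, per row:
        # 3 body partials + 7 force partials + 4 foot partials
        lr_rows, lr_cols = [], []
        for P in range(M):
            for r_off in (0, 1):
                r = self.EQ_LR + r_off
                lr_rows += [r] * 14
                lr_cols += [self.xcol(P, 0), self.xcol(P, 1), self.xcol(P, 2)]
                lr_cols += [self.xcol(P, SX_F + c) for c in range(7)]
                lr_cols += [self.fcol(j) for j in range(4)]
        self._lr_rows = np.array(lr_rows)
        self._lr_cols = np.array(lr_cols)

        self._eq_const_rows = np.array(rows)
        self._eq_const_cols = np.array(cols)
        self._eq_const_vals = np.array(const)
        self._eq_dyn_rows = np.array(g_rows)
        self._eq_dyn_cols = np.array(g_cols)
        self._eq_dyn_point = np.array(g_point)
        self._eq_dyn_pat = np.array(g_pat)
        self._eq_dyn_coef = np.array(g_coef)

        # ---- inequality constraints --------------------------------------
        # [length-force (7M); ventral (7M); clearance (2M)], all >= 0
        self.IQ_LF = 0
        self.IQ_VE = 7 * M
        self.IQ_CL = 14 * M
        self.n_ineq = 16 * M

        lf_rows, lf_cols, ve_rows, ve_cols = [], [], [], []
        for P in range(M):
            for c in range(7):
                r = self.IQ_LF + P * 7 + c
                lf_rows += [r] * 5
                lf_cols += [self.xcol(P, 0), self.xcol(P, 1), self.xcol(P, 2),
                            self.xcol(P, SX_F + c),
                            self.fcol(FOOT_PARAM_OF_CHANNEL[c])]
                r = self.IQ_VE + P * 7 + c
                ve_rows += [r] * 5
                ve_cols += [self.xcol(P, 0), self.xcol(P, 1), self.xcol(P, 2),
                            self.xcol(P, SX_F + c),
                            self.fcol(FOOT_PARAM_OF_CHANNEL[c])]
        cl_rows, cl_cols = [], []
        for P in range(M):
            for r_off in (0, 1):
                r = self.IQ_CL + P * 2 + r_off
                cl_rows += [r, r]
                cl_cols += [self.xcol(P, 1), self.xcol(P, 2)]
        self._lf_rows, self._lf_cols = np.array(lf_rows), np.array(lf_cols)
        self._ve_rows, self._ve_cols = np.array(ve_rows), np.array(ve_cols)
        self._cl_rows, self._cl_cols = np.array(cl_rows), np.array(cl_cols)

        # ---- objective residual blocks ------------------------------------
        # work rows: one per (point, channel); 8 partials each
        self.n_obj = 14 * M
        self.OBJ_WORK = 0
        self.OBJ_RATE = 7 * M
        wk_rows, wk_cols = [], []
        rt_rows, rt_cols = [], []
        for P in range(M):
            for c in range(7):
                r = self.OBJ_WORK + P * 7 + c
                wk_rows += [r] * 8
                wk_cols += [self.xcol(P, 0), self.xcol(P, 1), self.xcol(P, 2),
                            self.xcol(P, 3), self.xcol(P, 4), self.xcol(P, 5),
                            self.xcol(P, SX_F + c),
                            self.fcol(FOOT_PARAM_OF_CHANNEL[c])]
                rt_rows.append(self.OBJ_RATE + P * 7 + c)
                rt_cols.append(self.ucol(P, CU_FDOT + c))
        self._wk_rows, self._wk_cols = np.array(wk_rows), np.array(wk_cols)
        self._rt_rows, self._rt_cols = np.array(rt_rows), np.array(rt_cols)

    # ------------------------------------------------------------ dyn values
    def _dyn_jac_values(self, d):
        """(M, n_dyn_pat) array matching the dynamics jacobian pattern order."""
        g, F = d["g"], d["F"]
        vals = np.empty((self.M, self.n_dyn_pat))
        vals[:, 0:3] = 1.0
        i = 3
        T2 = self.T2
        for base in ("ux", "uy", "crossu"):
            scale = T2 if base != "crossu" else T2 / self.I_prime
            for var in ("x", "y", "th"):
                vals[:, i] = scale * np.sum(F * g[f"d{base}_d{var}"], axis=1)
                i += 1
            for c in range(7):
                vals[:, i] = scale * g[base][:, c]
                i += 1
            dfoot = F * g[f"d{base}_df"]
            for j in range(4):
                sel = FOOT_PARAM_OF_CHANNEL == j
                vals[:, i] = scale * dfoot[:, sel].sum(axis=1)
                i += 1
        vals[:, i : i + 7] = 1.0  # dFdot
        i += 7
        vals[:, i : i + 3] = 1.0  # dz/dF_leading
        return vals

    # ------------------------------------------------------------- equalities
    def eq_fun(self, w):
        d = self._compute(w)
        X, f = d["X"], d["f"]
        h = self.h
        out = np.empty(self.n_eq)

        Xa, Xm, Xb = X[0:-1:2], X[1::2], X[2::2]
        fa, fm, fb = f[0:-1:2], f[1::2], f[2::2]
        out[self.EQ_HS1 : self.EQ_HS2] = (
            Xm - 0.5 * (Xa + Xb) - (h / 8.0) * (fa - fb)
        ).ravel()
        out[self.EQ_HS2 : self.EQ_ORD] = (
            Xb - Xa - (h / 6.0) * (fa + 4.0 * fm + fb)
        ).ravel()

        g = d["g"]
        F = d["F"]
        z = X[:, SX_Z : SX_Z + 3]
        out[self.EQ_ORD : self.EQ_PER] = (F[:, list(TRAILING)] * z).ravel()

        last = self.M - 1
        out[self.EQ_PER : self.EQ_PER + 5] = X[last, 1:6] - X[0, 1:6]
        out[self.EQ_PER + 5 : self.EQ_PER + 8] = (
            F[last, list(LEADING)] - F[0, list(TRAILING)]
        )

        Fx = F * g["ux"]
        Fy = F * g["uy"]
        wq = self.quad_w
        out[self.EQ_LR] = np.sum(wq * (Fy * _SIDE_SIGN).sum(axis=1))
        out[self.EQ_LR + 1] = np.sum(wq * (Fx * _SIDE_SIGN).sum(axis=1))
        return out

    def eq_jac(self, w):
        d = self._compute(w)
        dyn = self._dyn_jac_values(d)
        g, F, X = d["g"], d["F"], d["X"]
        M = self.M

        data_dyn = self._eq_dyn_coef * dyn[self._eq_dyn_point, self._eq_dyn_pat]

        z = X[:, SX_Z : SX_Z + 3]
        od = np.empty((M, 3, 2))
        od[:, :, 0] = z
        od[:, :, 1] = F[:, list(TRAILING)]

        wq = self.quad_w[:, None]
        lr = np.empty((M, 2, 14))
        sF = _SIDE_SIGN * F
        for r_off, base in ((0, "uy"), (1, "ux")):
            for k, var in enumerate(("x", "y", "th")):
                lr[:, r_off, k] = (sF * g[f"d{base}_d{var}"]).sum(axis=1) * wq[:, 0]
            lr[:, r_off, 3:10] = _SIDE_SIGN * g[base] * wq
            dfoot = sF * g[f"d{base}_df"]
            for j in range(4):
                sel = FOOT_PARAM_OF_CHANNEL == j
                lr[:, r_off, 10 + j] = dfoot[:, sel].sum(axis=1) * wq[:, 0]

        rows = np.concatenate([self._eq_const_rows, self._eq_dyn_rows,
                               self._od_rows, self._lr_rows])
        cols = np.concatenate([self._eq_const_cols, self._eq_dyn_cols,
                               self._od_cols, self._lr_cols])
        data = np.concatenate([self._eq_const_vals, data_dyn,
                               od.ravel(), lr.ravel()])
        return sparse.coo_matrix((data, (rows, cols)),
                                 shape=(self.n_eq, self.n_vars)).tocsr()

    # ----------------------------------------------------------- inequalities
    def ineq_fun(self, w):
        d = self._compute(w)
        X, g, F = d["X"], d["g"], d["F"]
        out = np.empty(self.n_ineq)
        out[self.IQ_LF : self.IQ_VE] = ((self.lmax_ch - g["l"]) * F).ravel()
        out[self.IQ_VE : self.IQ_CL] = (GIRDLE_SIGN * F * g["crossu"]).ravel()
        y, th = X[:, 1], X[:, 2]
        mF, mH = self.morph.mF_prime, self.morph.mH_prime
        cl = np.stack([y + mH * np.sin(th) - EPS_CLEARANCE,
                       y - mF * np.sin(th) - EPS_CLEARANCE], axis=1)
        out[self.IQ_CL :] = cl.ravel()
        return out

    def ineq_jac(self, w):
        d = self._compute(w)
        X, g, F = d["X"], d["g"], d["F"]
        M = self.M
        lf = np.empty((M, 7, 5))
        for k, var in enumerate(("x", "y", "th")):
            lf[:, :, k] = -F * g[f"dl_d{var}"]
        lf[:, :, 3] = self.lmax_ch - g["l"]
        lf[:, :, 4] = -F * g["dl_df"]

        ve = np.empty((M, 7, 5))
        for k, var in enumerate(("x", "y", "th")):
            ve[:, :, k] = GIRDLE_SIGN * F * g[f"dcrossu_d{var}"]
        ve[:, :, 3] = GIRDLE_SIGN * g["crossu"]
        ve[:, :, 4] = GIRDLE_SIGN * F * g["dcrossu_df"]

        cth = np.cos(X[:, 2])
        cl = np.empty((M, 2, 2))
        cl[:, 0, 0] = 1.0
        cl[:, 0, 1] = self.morph.mH_prime * cth
        cl[:, 1, 0] = 1.0
        cl[:, 1, 1] = -self.morph.mF_prime * cth

        rows = np.concatenate([self._lf_rows, self._ve_rows, self._cl_rows])
        cols = np.concatenate([self._lf_cols, self._ve_cols, self._cl_cols])
        data = np.concatenate([lf.ravel(), ve.ravel(), cl.ravel()])
        return sparse.coo_matrix((data, (rows, cols)),
                                 shape=(self.n_ineq, self.n_vars)).tocsr()

    # ------------------------------------------------------ objective residuals
    # J_tot = sum(obj_res(w)**2) approximates (J_w + J_r)/D' with |F*ldot|
    # smoothed as sqrt((F*ldot)^2 + eps_work^2).
    def obj_res(self, w):
        d = self._compute(w)
        g, F, U = d["g"], d["F"], d["U"]
        out = np.empty(self.n_obj)
        wq = self.quad_w[:, None] / self.D_prime
        P = F * g["ldot"]
        out[self.OBJ_WORK : self.OBJ_RATE] = (
            np.sqrt(wq) * (P * P + self.eps_work ** 2) ** 0.25
        ).ravel()
        c1 = self.task.c1_prime
        out[self.OBJ_RATE :] = (np.sqrt(c1 * wq) * U[:, CU_FDOT : CU_FDOT + 7]).ravel()
        return out

    def obj_jac(self, w):
        d = self._compute(w)
        g, F = d["g"], d["F"]
        M = self.M
        wq = self.quad_w[:, None] / self.D_prime
        P = F * g["ldot"]
        # d/dP of sqrt(wq)*(P^2+eps^2)^(1/4)
        drdP = np.sqrt(wq) * 0.5 * P * (P * P + self.eps_work ** 2) ** -0.75
        wk = np.empty((M, 7, 8))
        for k, var in enumerate(("x", "y", "th")):
            wk[:, :, k] = drdP * F * g[f"dldot_d{var}"]
        wk[:, :, 3] = drdP * F * g["dldot_dvx"]
        wk[:, :, 4] = drdP * F * g["dldot_dvy"]
        wk[:, :, 5] = drdP * F * g["dldot_dom"]
        wk[:, :, 6] = drdP * g["ldot"]
        wk[:, :, 7] = drdP * F * g["dldot_df"]

        c1 = self.task.c1_prime
        rt = np.broadcast_to(np.sqrt(c1 * wq), (M, 7)).ravel()

        rows = np.concatenate([self._wk_rows, self._rt_rows])
        cols = np.concatenate([self._wk_cols, self._rt_cols])
        data = np.concatenate([wk.ravel(), rt])
        return sparse.coo_matrix((data, (rows, cols)),
                                 shape=(self.n_obj, self.n_vars)).tocsr()

    def smoothed_cot(self, w) -> float:
        """Objective value of the LSQ form: smoothed (J_w + J_r)/D'."""
        r = self.obj_res(w)
        return float(r @ r)

    # ------------------------------------------------------------------ bounds
    def variable_bounds(self, bounds) -> tuple[np.ndarray, np.ndarray]:
        """Box bounds for the full decision vector, with endpoint pinning.

        ``bounds`` is a :class:`quadrugait.solver.VariableBounds`.  Endpoint
        conditions that are simple bounds (x'(0)=0, x'(1)=D', zero endpoint
        forces for leading/trailing/reference channels, z(0)=0) are pinned
        here rather than added as constraints.
        """
        M, D = self.M, self.D_prime
        lb = np.empty(self.n_vars)
        ub = np.empty(self.n_vars)

        xlo, xhi, ulo, uhi, flo, fhi = _point_bounds(bounds, D)
        lb[: self.n_state_vars] = np.tile(xlo, M)
        ub[: self.n_state_vars] = np.tile(xhi, M)
        lb[self.CSTART : self.FSTART] = np.tile(ulo, M)
        ub[self.CSTART : self.FSTART] = np.tile(uhi, M)
        lb[self.FSTART :] = flo
        ub[self.FSTART :] = fhi

        last = M - 1
        # x'(0) = 0, x'(1) = D'
        lb[self.xcol(0, 0)] = ub[self.xcol(0, 0)] = 0.0
        lb[self.xcol(last, 0)] = ub[self.xcol(last, 0)] = D
        # endpoint forces: leading start at 0, trailing end at 0, reference both
        for c in LEADING:
            lb[self.xcol(0, SX_F + c)] = ub[self.xcol(0, SX_F + c)] = 0.0
        for c in TRAILING:
            lb[self.xcol(last, SX_F + c)] = ub[self.xcol(last, SX_F + c)] = 0.0
        lb[self.xcol(0, SX_F + 0)] = ub[self.xcol(0, SX_F + 0)] = 0.0
        lb[self.xcol(last, SX_F + 0)] = ub[self.xcol(last, SX_F + 0)] = 0.0
        # running integrals start at zero
        for j in range(3):
            lb[self.xcol(0, SX_Z + j)] = ub[self.xcol(0, SX_Z + j)] = 0.0
        return lb, ub


def _point_bounds(bounds, D_prime: float):
    """Per-kind (lo, hi) arrays for one point's states/controls and the feet."""
    xlo, xhi = np.empty(NX), np.empty(NX)
    xlo[0], xhi[0] = -0.5, D_prime + 0.5
    xlo[1], xhi[1] = bounds.y
    xlo[2], xhi[2] = bounds.theta
    xlo[3], xhi[3] = bounds.vx[0], bounds.vx[1] + D_prime
    xlo[4], xhi[4] = bounds.vy
    xlo[5], xhi[5] = bounds.thetadot
    xlo[SX_F : SX_F + 7], xhi[SX_F : SX_F + 7] = bounds.F
    xlo[SX_Z : SX_Z + 3], xhi[SX_Z : SX_Z + 3] = bounds.z
    ulo = np.full(NU, bounds.Fdot[0])
    uhi = np.full(NU, bounds.Fdot[1])
    flo = np.full(4, bounds.foot[0])
    fhi = np.full(4, bounds.foot[1] + D_prime)
    return xlo, xhi, ulo, uhi, flo, fhi
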