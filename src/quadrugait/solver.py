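"""Homotopy solution of the gait NLP: random starts, penalty stages, validation.

The transcribed problem is disjunctive: which limbs load, and when, is
encoded in complementarity-flavoured constraints, so a single cold solve from
a random guess is unreliable.  Each guess is therefore driven through a
four-stage homotopy in which (a) the |F*ldot| work integrand is smoothed with
a shrinking epsilon, (b) constraint enforcement tightens through an
augmented-Lagrangian ladder, and (c) the mesh refines whenever the estimated
discretization error exceeds the mesh tolerance, with the trajectory
down-sampled onto the coarse seeding grid between stages.

Each stage solves a sequence of sparse nonlinear least-squares problems
(Gauss-Newton with a trust region, LSMR inner iterations) over the residual
vector [objective residuals; sqrt(mu/2)(c + lam/mu); sqrt(mu/2) max(0,
eta/mu - g)], updating the multipliers lam, eta between solves — a classical
multiplier-penalty scheme that tolerates the degenerate geometry of the
contact constraints far better than methods needing constraint
qualifications.

A solution is *valid* when its mesh error and its worst exact-constraint
violation at the grid points are below tolerance; the pseudo-global optimum
of a multistart is the valid solution with the lowest unaugmented cost of
transport.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.integrate import solve_ivp

from . import constraints as C
from . import dynamics
from .morphology import GaitTask, Morphology
from .objective import CostBreakdown, cost_breakdown
from .trajectory import Trajectory, channel_feet
from .transcription import (
    CU_FDOT,
    NU,
    NX,
    SX_F,
    SX_Z,
    Transcription,
    _point_bounds,
)

__all__ = [
    "VariableBounds",
    "HomotopyStage",
    "SolverConfig",
    "Solution",
    "MultistartResult",
    "InitialGuess",
    "random_initial_guess",
    "estimate_mesh_error",
    "solve_homotopy",
    "validate",
    "multistart",
]


@dataclass(frozen=True)
class VariableBounds:
    """Box bounds per variable kind, in normalized units.

    Generous relative to the expected magnitudes (trunk height and limb
    lengths are O(1) lB, forces a few mg): bounds exist to enable uniform
    random initialization and keep the NLP scaled, not to shape solutions.
    ``vx`` and ``foot`` upper bounds are widened by D' per task.
    """

    y: tuple = (C.EPS_CLEARANCE, 2.0)
    theta: tuple = (-np.pi / 3, np.pi / 3)
    vx: tuple = (-3.0, 3.0)  # upper bound gets +D' added
    vy: tuple = (-5.0, 5.0)
    thetadot: tuple = (-10.0, 10.0)
    F: tuple = (0.0, 10.0)
    z: tuple = (0.0, 5.0)
    Fdot: tuple = (-120.0, 120.0)
    foot: tuple = (-2.0, 2.0)  # upper bound gets +D' added


@dataclass(frozen=True)
class HomotopyStage:
    """Smoothing, enforcement weight and mesh budget of one homotopy stage."""

    eps_work: float  # |power| smoothing width (mg*lB/T)
    mu0: float  # initial augmented-Lagrangian penalty weight
    tol_feas: float  # stage feasibility target (normalized residual)
    mesh_iterations: int
    max_outer: int = 6  # multiplier updates within the stage


DEFAULT_STAGES = (
    HomotopyStage(eps_work=3e-2, mu0=1e2, tol_feas=1e-3, mesh_iterations=1, max_outer=6),
    HomotopyStage(eps_work=1e-2, mu0=3e2, tol_feas=1e-4, mesh_iterations=1, max_outer=5),
    HomotopyStage(eps_work=1e-3, mu0=1e3, tol_feas=1e-5, mesh_iterations=2, max_outer=4),
    HomotopyStage(eps_work=2e-4, mu0=3e3, tol_feas=1e-5, mesh_iterations=5, max_outer=4),
)


@dataclass(frozen=True)
class SolverConfig:
    """Tunables of the transcription, homotopy and multistart."""

    n_segments_initial: int = 15
    n_segments_max: int = 30
    mesh_growth: float = 1.5
    stages: tuple[HomotopyStage, ...] = DEFAULT_STAGES
    mesh_tolerance: float = 1e-4
    violation_tolerance: float = 1e-3
    n_starts: int = 20
    polish_top: int | None = 6  # screen all starts, polish only the best k
    screen_stages: int = 2  # homotopy stages run during screening
    seed: int = 0
    n_guess_points: int = 16
    max_nfev_first: int = 400  # Gauss-Newton evaluations, first solve of a guess
    max_nfev: int = 100  # per subsequent multiplier update
    lsmr_maxiter: int = 200
    mu_factor: float = 5.0
    mu_max: float = 1e7
    bounds: VariableBounds = field(default_factory=VariableBounds)

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("need at least one homotopy stage")
        if self.mesh_tolerance <= 0 or self.violation_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class InitialGuess:
    """Decision-variable guess on a coarse time grid."""

    t: np.ndarray  # (G,)
    X: np.ndarray  # (G, NX)
    U: np.ndarray  # (G, NU)
    feet4: np.ndarray  # (4,)
    seed: int | None = None


@dataclass
class Solution:
    """Converged (or failed) trajectory with costs and diagnostics."""

    trajectory: Trajectory
    costs: CostBreakdown
    mesh_error: float
    violations: dict[str, float]
    max_violation: float
    valid: bool
    converged: bool
    status: list[dict]
    seed: int | None = None
    guess_index: int | None = None
    stages_run: int = 0
    wall_time: float = 0.0

    @property
    def J_tot(self) -> float:
        return self.costs.J_tot


@dataclass
class MultistartResult:
    solutions: list[Solution]
    best: Solution | None
    status: str

    @property
    def valid_solutions(self) -> list[Solution]:
        return [s for s in self.solutions if s.valid]


def random_initial_guess(bounds: VariableBounds, task: GaitTask, seed: int,
                         n_points: int = 16) -> InitialGuess:
    """Uniform random guess within bounds on a coarse grid.

    Every variable is drawn from a uniform distribution between its box
    bounds, except the horizontal position x', which ramps linearly from 0 to
    D' — the only structure the optimizer is given.  The same seed always
    produces the same guess.
    """
    xlo, xhi, ulo, uhi, flo, fhi = _point_bounds(bounds, task.D_prime)
    if not all(np.all(np.isfinite(a)) for a in (xlo, xhi, ulo, uhi, flo, fhi)):
        raise ValueError("random initialization requires finite bounds")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    X = rng.uniform(xlo, xhi, size=(n_points, NX))
    U = rng.uniform(ulo, uhi, size=(n_points, NU))
    X[:, 0] = task.D_prime * t  # linear fore-aft ramp
    feet4 = rng.uniform(flo, fhi)
    return InitialGuess(t=t, X=X, U=U, feet4=feet4, seed=seed)


def _interp_guess(guess: InitialGuess, t_new: np.ndarray):
    X = np.column_stack([np.interp(t_new, guess.t, guess.X[:, k]) for k in range(NX)])
    U = np.column_stack([np.interp(t_new, guess.t, guess.U[:, k]) for k in range(NU)])
    return X, U


def _simulate_guess(tr: Transcription, w: np.ndarray, lb, ub,
                    bounds: VariableBounds) -> np.ndarray:
    """Replace the guessed trunk states by a clipped forward simulation.

    Integrating the guess's force-rate controls from its (clipped) initial
    state makes the dynamics defects small everywhere except where the state
    hits its box, which shrinks the basin problem for the first Gauss-Newton
    solve without adding any information beyond the random guess itself.
    """
    X, U, feet4 = tr.unpack(np.clip(w, lb, ub))
    X = X.copy()
    feet = channel_feet(feet4, tr.D_prime)
    dt = tr.t[1] - tr.t[0]
    # clip against the generic per-point box, not the pinned endpoint bounds
    xlo, xhi, _, _, _, _ = _point_bounds(bounds, tr.D_prime)
    lead = list(dynamics.LEADING)
    for P in range(tr.M - 1):
        x, y, th, vx, vy, om = X[P, :6]
        F = X[P, SX_F : SX_F + 7]
        ax, ay, al = dynamics.accelerations(
            x, y, th, vx, vy, om, F, feet, tr.morph, tr.task.T_hat)
        nxt = X[P].copy()
        nxt[0] = x + vx * dt
        nxt[1] = y + vy * dt
        nxt[2] = th + om * dt
        nxt[3] = vx + ax * dt
        nxt[4] = vy + ay * dt
        nxt[5] = om + al * dt
        nxt[SX_F : SX_F + 7] = F + U[P, CU_FDOT : CU_FDOT + 7] * dt
        nxt[SX_Z : SX_Z + 3] = X[P, SX_Z : SX_Z + 3] + F[lead] * dt
        X[P + 1] = np.clip(nxt, xlo, xhi)
    return np.clip(tr.pack(X, U, feet4), lb, ub)


def estimate_mesh_error(tr: Transcription, w: np.ndarray,
                        rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Per-interval re-simulation error of the collocation solution.

    Each mesh interval is re-integrated with a high-accuracy RK method from
    its left node, holding the force-rate controls to their Hermite-Simpson
    quadratic interpolants; the error is the largest relative discrepancy
    with the collocated state at the right node.  Integrating
    interval-locally avoids amplifying error through the stride-scale
    instability of the dynamics.
    """
    X, U, feet4 = tr.unpack(w)
    N, h = tr.N, tr.h
    feet = channel_feet(feet4, tr.D_prime)
    Xa, Xb = X[0:-1:2], X[2::2]
    Fd_a = U[0:-1:2, CU_FDOT : CU_FDOT + 7]
    Fd_m = U[1::2, CU_FDOT : CU_FDOT + 7]
    Fd_b = U[2::2, CU_FDOT : CU_FDOT + 7]
    feet_all = np.broadcast_to(feet, (N, 7))
    lead = list(dynamics.LEADING)

    def rhs(sigma, yflat):
        Y = yflat.reshape(N, NX)
        L0 = 2.0 * (sigma - 0.5) * (sigma - 1.0)
        L1 = 4.0 * sigma * (1.0 - sigma)
        L2 = 2.0 * sigma * (sigma - 0.5)
        Fd = L0 * Fd_a + L1 * Fd_m + L2 * Fd_b
        x, y, th, vx, vy, om = Y[:, :6].T
        F = Y[:, SX_F : SX_F + 7]
        ax, ay, al = dynamics.accelerations(x, y, th, vx, vy, om, F, feet_all,
                                            tr.morph, tr.task.T_hat)
        f = np.empty_like(Y)
        f[:, 0], f[:, 1], f[:, 2] = vx, vy, om
        f[:, 3], f[:, 4], f[:, 5] = ax, ay, al
        f[:, 6:13] = Fd
        f[:, 13:16] = F[:, lead]
        return (h * f).ravel()

    sol = solve_ivp(rhs, (0.0, 1.0), Xa.ravel(), rtol=rtol, atol=atol)
    if not sol.success:
        return np.inf
    Y1 = sol.y[:, -1].reshape(N, NX)
    rel = np.abs(Y1 - Xb) / (1.0 + np.abs(Xb))
    return float(rel.max())


@dataclass
class _NlpResult:
    x: np.ndarray
    fun: float
    constr_violation: float
    niter: int
    status: int


def _solve_stage_nlp(tr: Transcription, w0: np.ndarray, stage: HomotopyStage,
                     config: SolverConfig, first_solve: bool) -> _NlpResult:
    """Gauss-Newton multiplier-penalty solution of one stage on one mesh."""
    tr.eps_work = stage.eps_work
    lb, ub = tr.variable_bounds(config.bounds)
    pin = lb == ub
    lbp, ubp = lb.copy(), ub.copy()
    lbp[pin] -= 1e-10  # strict inequality required by the trust-region solver
    ubp[pin] += 1e-10
    w = np.clip(w0, lbp, ubp)

    lam = np.zeros(tr.n_eq)
    eta = np.zeros(tr.n_ineq)
    mu = stage.mu0

    def residuals(wv):
        c = tr.eq_fun(wv)
        g = tr.ineq_fun(wv)
        s = np.sqrt(0.5 * mu)
        return np.concatenate([
            tr.obj_res(wv),
            s * (c + lam / mu),
            s * np.maximum(0.0, eta / mu - g),
        ])

    def jac(wv):
        g = tr.ineq_fun(wv)
        s = np.sqrt(0.5 * mu)
        active = (eta / mu - g) > 0.0
        Ji = sparse.diags(-s * active.astype(float)) @ tr.ineq_jac(wv)
        return sparse.vstack([tr.obj_jac(wv), s * tr.eq_jac(wv), Ji]).tocsr()

    def infeas(wv):
        v = float(np.max(np.abs(tr.eq_fun(wv))))
        return max(v, float(np.max(np.maximum(0.0, -tr.ineq_fun(wv)))))

    total_nfev = 0
    status = 0
    prev = np.inf
    for outer in range(stage.max_outer):
        nfev = config.max_nfev_first if (first_solve and outer == 0) else config.max_nfev
        res = optimize.least_squares(
            residuals, w, jac=jac, bounds=(lbp, ubp), method="trf",
            tr_solver="lsmr", tr_options={"maxiter": config.lsmr_maxiter},
            x_scale="jac", max_nfev=nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        w = res.x
        total_nfev += res.nfev
        v = infeas(w)
        if v <= stage.tol_feas:
            status = 1
            break
        lam = lam + mu * tr.eq_fun(w)
        eta = np.maximum(0.0, eta - mu * tr.ineq_fun(w))
        if v > 0.25 * prev:
            mu = min(mu * config.mu_factor, config.mu_max)
        prev = min(prev, v)

    w[pin] = lb[pin]
    return _NlpResult(x=w, fun=tr.smoothed_cot(w), constr_violation=infeas(w),
                      niter=total_nfev, status=status)


def _resample_w(tr_old: Transcription, w, tr_new: Transcription):
    X, U, feet4 = tr_old.unpack(w)
    g = InitialGuess(t=tr_old.t, X=X, U=U, feet4=feet4)
    Xn, Un = _interp_guess(g, tr_new.t)
    return tr_new.pack(Xn, Un, feet4)


def _run_stages(guess: InitialGuess, morph: Morphology, task: GaitTask,
                config: SolverConfig, stages, records: list[dict],
                cold: bool = True):
    """Run a sequence of homotopy stages; return (w, transcription, guess')."""
    current = guess
    w = None
    tr = None
    first = True
    for stage in stages:
        tr = Transcription(morph, task, config.n_segments_initial)
        X, U = _interp_guess(current, tr.t)
        w = tr.pack(X, U, current.feet4)
        if first and cold:
            lb, ub = tr.variable_bounds(config.bounds)
            w = _simulate_guess(tr, w, lb, ub, config.bounds)
        is_last_stage = stage is stages[-1]
        for it in range(stage.mesh_iterations):
            res = _solve_stage_nlp(tr, w, stage, config, first_solve=first)
            first = False
            w = res.x
            can_refine = it < stage.mesh_iterations - 1 and tr.N < config.n_segments_max
            if is_last_stage or can_refine:
                mesh_err = estimate_mesh_error(tr, w)
            else:
                mesh_err = np.nan
            records.append({
                "stage": stage, "n_segments": tr.N, "nfev": res.niter,
                "nlp_status": res.status,
                "constr_violation": float(res.constr_violation),
                "J_smooth": float(res.fun), "mesh_error": mesh_err,
            })
            if mesh_err <= config.mesh_tolerance or it == stage.mesh_iterations - 1:
                break
            n_new = min(int(np.ceil(tr.N * config.mesh_growth)), config.n_segments_max)
            if n_new == tr.N:
                break
            tr_new = Transcription(morph, task, n_new)
            w = _resample_w(tr, w, tr_new)
            tr = tr_new
        # down-sample onto the coarse guess grid before the next stage
        X, U, feet4 = tr.unpack(w)
        tg = np.linspace(0.0, 1.0, config.n_guess_points)
        Xg = np.column_stack([np.interp(tg, tr.t, X[:, k]) for k in range(NX)])
        Ug = np.column_stack([np.interp(tg, tr.t, U[:, k]) for k in range(NU)])
        current = InitialGuess(t=tg, X=Xg, U=Ug, feet4=feet4, seed=guess.seed)
    return w, tr, current


def _build_solution(tr: Transcription, w, config: SolverConfig, records,
                    seed=None, guess_index=None, stages_run=0, wall_time=0.0
                    ) -> Solution:
    traj = tr.trajectory(w)
    last = records[-1] if records else {}
    costs = cost_breakdown(traj, tr.task.c1_prime)
    mesh_err = last.get("mesh_error", np.inf)
    viols = {k: float(np.max(v)) for k, v in
             C.exact_violations(traj, tr.lmax_ch).items()}
    max_v = max(viols.values())
    converged = bool(records) and records[-1]["nlp_status"] == 1
    sol = Solution(
        trajectory=traj, costs=costs, mesh_error=mesh_err, violations=viols,
        max_violation=max_v, valid=False, converged=converged,
        status=[{k: v for k, v in r.items() if k != "stage"} for r in records],
        seed=seed, guess_index=guess_index, stages_run=stages_run,
        wall_time=wall_time,
    )
    sol.valid = validate(sol, config)
    return sol


def validate(solution: Solution, config: SolverConfig) -> bool:
    """True iff mesh error and worst exact-constraint violation are in tolerance."""
    return bool(
        solution.mesh_error <= config.mesh_tolerance
        and solution.max_violation <= config.violation_tolerance
    )


def solve_homotopy(guess: InitialGuess, morph: Morphology, task: GaitTask,
                   config: SolverConfig | None = None) -> Solution:
    """Drive one initial guess through the full smoothing/penalty/mesh homotopy."""
    config = config or SolverConfig()
    if task.D_prime <= 0:
        raise ValueError("task stride length must be positive")
    t0 = time.perf_counter()
    records: list[dict] = []
    w, tr, _ = _run_stages(guess, morph, task, config, list(config.stages), records)
    return _build_solution(tr, w, config, records, seed=guess.seed,
                           stages_run=len(config.stages),
                           wall_time=time.perf_counter() - t0)


def multistart(morph: Morphology, task: GaitTask,
               config: SolverConfig | None = None,
               n_starts: int | None = None, seed: int | None = None,
               progress: bool = False) -> MultistartResult:
    """Seeded multistart over random initial guesses; returns all solutions.

    With ``polish_top`` set, every guess is first screened through the first
    two homotopy stages (cheap, coarse) and only the most promising few by
    smoothed objective are driven through the remaining stages; otherwise
    each guess runs the full homotopy.  Per-guess seeds are
    ``seed + guess_index``, so a run is reproducible from its base seed.
    """
    config = config or SolverConfig()
    n_starts = n_starts if n_starts is not None else config.n_starts
    base_seed = seed if seed is not None else config.seed
    stages = list(config.stages)
    k = max(1, min(config.screen_stages, len(stages) - 1))
    screen_stages, polish_stages = stages[:k], stages[k:]
    do_screen = (config.polish_top is not None and len(stages) > k
                 and n_starts > config.polish_top)

    solutions: list[Solution] = []
    candidates = []  # (screen score, records, resampled guess, idx, wall)
    for i in range(n_starts):
        g = random_initial_guess(config.bounds, task, base_seed + i,
                                 config.n_guess_points)
        t0 = time.perf_counter()
        records: list[dict] = []
        if do_screen:
            w, tr, resampled = _run_stages(g, morph, task, config,
                                           screen_stages, records)
            # rank by smoothed objective, discouraging infeasible screens
            score = records[-1]["J_smooth"] + 10.0 * records[-1]["constr_violation"]
            candidates.append((score, records, resampled, i,
                               time.perf_counter() - t0))
            if progress:
                print(f"  start {i + 1}/{n_starts} screened: "
                      f"J~{records[-1]['J_smooth']:.3f} "
                      f"viol={records[-1]['constr_violation']:.1e}", flush=True)
        else:
            w, tr, _ = _run_stages(g, morph, task, config, stages, records)
            solutions.append(_build_solution(
                tr, w, config, records, seed=g.seed, guess_index=i,
                stages_run=len(stages), wall_time=time.perf_counter() - t0))
            if progress:
                s = solutions[-1]
                print(f"  start {i + 1}/{n_starts}: J_tot={s.J_tot:.4f} "
                      f"valid={s.valid}", flush=True)

    if do_screen:
        candidates.sort(key=lambda c: c[0])
        for score, records, resampled, i, t_screen in candidates[: config.polish_top]:
            t0 = time.perf_counter()
            w, tr, _ = _run_stages(resampled, morph, task, config,
                                   polish_stages, records, cold=False)
            solutions.append(_build_solution(
                tr, w, config, records, seed=base_seed + i, guess_index=i,
                stages_run=len(stages),
                wall_time=t_screen + time.perf_counter() - t0))
            if progress:
                s = solutions[-1]
                print(f"  polished guess {i}: J_tot={s.J_tot:.4f} "
                      f"valid={s.valid} mesh={s.mesh_error:.1e} "
                      f"viol={s.max_violation:.1e}", flush=True)

    valid = [s for s in solutions if s.valid]
    if valid:
        best = min(valid, key=lambda s: s.J_tot)
        status = "ok"
    else:
        best = None
        status = "no-valid-solution"
    return MultistartResult(solutions=solutions, best=best, status=status)
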