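"""Synthetic trajectories with known gait structure, and independent oracles.

Fixtures let every analysis stage be tested without running an optimization:
forces are raised-cosine stance humps with prescribed touchdown phases and
duty factors, so duty factors, phase lags, impulses and work are known in
closed form.  The dynamics oracle integrates the equations of motion with an
independently coded Newton-Euler evaluation (explicit 3-vector cross
products) to cross-check the vectorized kernels and the collocation
machinery.  Fixtures make no claim of energetic optimality.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import LEADING, LIMB_CHANNELS, N_CHANNELS, quarter_offsets
from .morphology import Morphology
from .trajectory import Trajectory

__all__ = [
    "make_gait_fixture",
    "make_trot_fixture",
    "make_walk_fixture",
    "make_pronk_fixture",
    "accelerations_oracle",
    "integrate_dynamics_oracle",
]


def _raised_cosine(phase_in_stance: np.ndarray, DF: float, peak: float) -> np.ndarray:
    """Smooth stance hump: peak*(1-cos(2 pi s/DF))/2 for s in [0, DF)."""
    s = phase_in_stance
    out = np.where((s >= 0.0) & (s < DF),
                   0.5 * peak * (1.0 - np.cos(2.0 * np.pi * s / DF)), 0.0)
    return out


def _raised_cosine_rate(phase_in_stance: np.ndarray, DF: float, peak: float) -> np.ndarray:
    s = phase_in_stance
    return np.where((s >= 0.0) & (s < DF),
                    0.5 * peak * (2.0 * np.pi / DF) * np.sin(2.0 * np.pi * s / DF),
                    0.0)


def make_gait_fixture(
    touchdowns: dict[str, float],
    DF: float | dict[str, float],
    morph: Morphology,
    D_prime: float,
    n_samples: int = 401,
    y0: float = 0.8,
) -> Trajectory:
    """Analytic stride with raised-cosine limb forces at prescribed phases.

    Each limb's stance starts at its touchdown phase and lasts its duty
    factor; stance portions reaching past t' = 1 wrap into the limb's
    trailing channel (so force continuity and endpoint conditions hold by
    construction).  Stance-mean vertical load is shared per girdle (mF' to
    the forelimbs, mH' to the hind), and each foot is placed under its
    girdle's mid-stance position so forces are near-vertical.  The trunk
    translates at constant speed and height — the fixture targets the
    analysis layer, not dynamic consistency.
    """
    if isinstance(DF, float):
        DF = {limb: DF for limb in touchdowns}
    for limb, df in DF.items():
        if not 0.0 < df < 1.0:
            raise ValueError(f"duty factor for {limb} must be in (0,1), got {df}")
    t = np.linspace(0.0, 1.0, n_samples)
    M = len(t)
    body = np.zeros((M, 6))
    body[:, 0] = D_prime * t
    body[:, 1] = y0
    body[:, 3] = D_prime

    F = np.zeros((M, N_CHANNELS))
    Fdot = np.zeros((M, N_CHANNELS))
    footholds = np.zeros(4)
    limb_order = ("LH", "RH", "LF", "RF")
    for j, limb in enumerate(limb_order):
        t_on = touchdowns[limb] % 1.0
        df = DF[limb]
        chans = LIMB_CHANNELS[limb]
        # per-limb peak so that the stride-mean vertical force matches the
        # girdle's share of body weight: mean = peak*df/2 = share/2
        share = morph.mF_prime if limb in ("LF", "RF") else morph.mH_prime
        peak = share / df
        phase = (t - t_on) % 1.0
        force = _raised_cosine(phase, df, peak)
        rate = _raised_cosine_rate(phase, df, peak)
        wraps = t_on + df > 1.0
        if len(chans) == 1:
            if wraps:
                raise ValueError("reference limb (LH) stance must not wrap t'=1")
            F[:, chans[0]] = force
            Fdot[:, chans[0]] = rate
        else:
            cT, cL = chans
            if wraps:
                head = t >= t_on  # pre-wrap part of stance -> leading contact
                F[head, cL] = force[head]
                Fdot[head, cL] = rate[head]
                tail = t < (t_on + df - 1.0)
                F[tail, cT] = force[tail]
                Fdot[tail, cT] = rate[tail]
            else:
                F[:, cT] = force
                Fdot[:, cT] = rate
        # foot under the girdle attachment at mid-stance
        t_mid = (t_on + 0.5 * df) % 1.0
        rho = morph.mH_prime if limb in ("LF", "RF") else -morph.mF_prime
        foot = D_prime * t_mid + rho
        if wraps and t_mid < t_on:
            foot += D_prime  # mid-stance is past the wrap
        footholds[j] = foot if not (len(chans) > 1 and wraps) else foot - D_prime

    z = np.zeros((M, 3))
    for jj, cL in enumerate(LEADING):
        z[:, jj] = np.concatenate(
            [[0.0], np.cumsum(0.5 * (F[1:, cL] + F[:-1, cL]) * np.diff(t))])

    traj = Trajectory(
        t=t, body=body, F=F, z=z, Fdot=Fdot,
        p=np.zeros((M, 7)), q=np.zeros((M, 7)),
        s_a=np.zeros((M, 7)), s_b=np.zeros((M, 3)), s_c=np.zeros((M, 7)),
        footholds=footholds, D_prime=D_prime, morphology=morph,
    )
    power = traj.limb_powers()
    traj.p = np.maximum(power, 0.0)
    traj.q = np.maximum(-power, 0.0)
    return traj


def make_trot_fixture(DF: float = 0.4, phase: float = 0.5, morph: Morphology | None = None,
                      D_prime: float = 2.0, t0: float = 0.05,
                      n_samples: int = 401) -> Trajectory:
    """Two-beat trot: diagonal pairs (LH+RF, RH+LF) land half a stride apart."""
    morph = morph or Morphology(0.6, 0.55, 0.9, 0.8)
    touchdowns = {"LH": t0, "RF": t0, "RH": (t0 + phase) % 1.0,
                  "LF": (t0 + phase) % 1.0}
    return make_gait_fixture(touchdowns, DF, morph, D_prime, n_samples)


def make_walk_fixture(DF: float = 0.6, PL: float = 0.25,
                      morph: Morphology | None = None, D_prime: float = 1.2,
                      t0: float = 0.05, n_samples: int = 401) -> Trajectory:
    """Four-beat lateral-sequence walk with pair lag PL and hind lag 0.5."""
    morph = morph or Morphology(0.6, 0.55, 0.9, 0.8)
    touchdowns = {"LH": t0, "RH": (t0 + 0.5) % 1.0, "LF": (t0 + PL) % 1.0,
                  "RF": (t0 + PL + 0.5) % 1.0}
    return make_gait_fixture(touchdowns, DF, morph, D_prime, n_samples)


def make_pronk_fixture(DF: float = 0.3, morph: Morphology | None = None,
                       D_prime: float = 1.5, t0: float = 0.1,
                       n_samples: int = 401) -> Trajectory:
    """All four limbs land simultaneously."""
    morph = morph or Morphology(0.6, 0.55, 0.9, 0.8)
    touchdowns = {limb: t0 for limb in ("LH", "RH", "LF", "RF")}
    return make_gait_fixture(touchdowns, DF, morph, D_prime, n_samples)


def accelerations_oracle(x, y, th, vx, vy, om, F, feet, morph: Morphology,
                         T_hat: float):
    """Independently coded Newton-Euler accelerations (3-vector cross products).

    Evaluates the same equations of motion as the vectorized kernels but via
    explicit per-channel force vectors and ``np.cross``; used purely as a
    test oracle.
    """
    r_F, r_H = quarter_offsets(th, morph.mF_prime)
    com = np.array([x, y, 0.0])
    total = np.array([0.0, -1.0, 0.0])
    torque = np.zeros(3)
    for c in range(N_CHANNELS):
        r = r_F if c in (3, 4, 5, 6) else r_H
        attach = com + r
        lvec = attach - np.array([feet[c], 0.0, 0.0])
        ln = np.linalg.norm(lvec)
        fvec = F[c] * lvec / ln
        total = total + fvec
        torque = torque + np.cross(r, fvec)
    T2 = T_hat ** 2
    return total[0] * T2, total[1] * T2, torque[2] / morph.I_prime * T2


def integrate_dynamics_oracle(force_funcs, feet, body0, morph: Morphology,
                              T_hat: float, t_eval=None, rtol=1e-10, atol=1e-12):
    """High-accuracy integration of the trunk dynamics under given forces.

    ``force_funcs`` maps t' to the 7 channel forces; ``feet`` are fixed
    per-channel contact positions.  Returns (t, states) with states columns
    (x, y, th, vx, vy, om).
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, 1.0, 101)

    def rhs(tt, s):
        x, y, th, vx, vy, om = s
        F = np.asarray(force_funcs(tt), float)
        ax, ay, al = accelerations_oracle(x, y, th, vx, vy, om, F, feet, morph, T_hat)
        return [vx, vy, om, ax, ay, al]

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), list(body0), t_eval=t_eval,
                    rtol=rtol, atol=atol, method="DOP853")
    return sol.t, sol.y.T
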