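"""Path, endpoint and integral constraint residuals, exact and relaxed.

Contact is never prescribed: limbs may only push (F' >= 0), only while shorter
than their standing length, only through the trailing contact before the
leading one, and only with ventrally oriented torques.  Each disjunctive
condition is a complementarity constraint; the relaxed forms add nonnegative
relaxation variables ``s`` that a homotopy on penalty weights drives to zero.
Every relaxed residual reduces to its exact counterpart at ``s = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import (
    GIRDLE_SIGN,
    LEADING,
    LEFT_CHANNELS,
    RIGHT_CHANNELS,
    TRAILING,
)
from .trajectory import Trajectory

__all__ = [
    "EPS_CLEARANCE",
    "length_force_residual",
    "ordering_residual",
    "clearance_residual",
    "ventral_residual",
    "periodicity_residuals",
    "lr_impulse_residual",
    "slack_complementarity",
    "exact_violations",
    "constraint_report",
]

#: strict torso-above-ground inequality implemented as >= EPS_CLEARANCE (lB)
EPS_CLEARANCE = 1e-3


def length_force_residual(l_prime, F_prime, limax_prime, s_a=0.0):
    """(l'_imax - l')*F' + s_a, feasible when >= 0.

    Forces may only act while the limb is shorter than its standing length.
    """
    return (np.asarray(limax_prime) - np.asarray(l_prime)) * np.asarray(F_prime) + s_a


def ordering_residual(F_T_prime, leading_integral, s_b=0.0):
    """F_T' * int_0^t F_L' dt - s_b, feasible when == 0.

    Once the leading contact has carried any impulse, the trailing channel of
    the same limb must stay silent.  The nonnegative relaxation ``s_b``
    absorbs the product so a linear penalty on ``s_b`` acts directly on the
    complementarity violation.
    """
    return np.asarray(F_T_prime) * np.asarray(leading_integral) - s_b


def clearance_residual(y_prime, theta, mF_prime):
    """Heights of the fore and hind point masses above ground.

    Returns ``(fore, hind)``; feasibility is ``> 0``, implemented downstream
    as ``>= EPS_CLEARANCE``.
    """
    y_prime = np.asarray(y_prime, float)
    theta = np.asarray(theta, float)
    mH_prime = 1.0 - mF_prime
    fore = y_prime + mH_prime * np.sin(theta)
    hind = y_prime - mF_prime * np.sin(theta)
    return fore, hind


def ventral_residual(torque_z, girdle_sign, s_c=0.0):
    """Ventral-orientation residual: sign(girdle)*torque + s_c >= 0.

    Forelimb forces must torque the trunk nose-up (+z), hindlimb forces
    nose-down, which keeps limbs pointing under the body.  ``torque_z`` is the
    z-component of r_i' x F' for the channel; ``girdle_sign`` is +1 for fore
    and -1 for hind channels.
    """
    return np.asarray(girdle_sign) * np.asarray(torque_z) + s_c


def slack_complementarity(p_prime, q_prime):
    """Product p'*q'; zero iff the power decomposition is complementary."""
    p = np.asarray(p_prime, float)
    q = np.asarray(q_prime, float)
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("power slacks must be non-negative")
    return p * q


def periodicity_residuals(traj: Trajectory) -> dict[str, np.ndarray]:
    """Endpoint residuals of a steady stride (all zero when satisfied).

    Kinematics (y', th, vx', vy', om) are periodic; leading forces at t'=1
    continue as the trailing forces at t'=0; x' progresses from 0 to D';
    leading forces start at zero and trailing forces end at zero; the
    reference limb starts and ends the stride in swing.
    """
    b0, b1 = traj.body[0], traj.body[-1]
    F0, F1 = traj.F[0], traj.F[-1]
    return {
        "kinematic": b1[1:] - b0[1:],  # y, th, vx, vy, om
        "force_continuity": F1[list(LEADING)] - F0[list(TRAILING)],
        "progress": np.array([b0[0] - 0.0, b1[0] - traj.D_prime]),
        "endpoint_forces": np.concatenate(
            [F0[list(LEADING)], F1[list(TRAILING)], [F0[0], F1[0]]]
        ),
        "integral_start": traj.z[0],
    }


def lr_impulse_residual(traj: Trajectory) -> np.ndarray:
    """Stride (vertical, fore-aft) impulse difference, left minus right sides.

    A surrogate for 3D roll/yaw balance: with constant lateral moment arms an
    unequal left/right impulse would roll or yaw the animal.
    """
    Fx, Fy = traj.force_vectors()
    lv = np.trapezoid(Fy[:, list(LEFT_CHANNELS)].sum(axis=1), traj.t)
    rv = np.trapezoid(Fy[:, list(RIGHT_CHANNELS)].sum(axis=1), traj.t)
    lh = np.trapezoid(Fx[:, list(LEFT_CHANNELS)].sum(axis=1), traj.t)
    rh = np.trapezoid(Fx[:, list(RIGHT_CHANNELS)].sum(axis=1), traj.t)
    return np.array([lv - rv, lh - rh])


def exact_violations(traj: Trajectory, lmax_by_channel: np.ndarray) -> dict[str, np.ndarray]:
    """Pointwise violations of the *exact* (unrelaxed) path constraints.

    Returns per-family arrays of nonnegative violation magnitudes evaluated at
    the trajectory's grid points; used by solution validation and reporting.
    """
    g = traj.geometry()
    l, ldot, crossu = g["l"], g["ldot"], g["crossu"]
    F = traj.F
    out: dict[str, np.ndarray] = {}
    out["force_nonneg"] = np.maximum(0.0, -F)
    out["length_force"] = np.maximum(0.0, -length_force_residual(l, F, lmax_by_channel))
    out["ordering"] = np.abs(F[:, list(TRAILING)] * traj.z)
    fore, hind = clearance_residual(traj.body[:, 1], traj.body[:, 2], traj.morphology.mF_prime)
    out["clearance"] = np.maximum(0.0, -np.stack([fore, hind], axis=1))
    torque = F * crossu
    out["ventral"] = np.maximum(0.0, -(GIRDLE_SIGN * torque))
    out["power_identity"] = np.abs(F * ldot - traj.p + traj.q)
    out["complementarity"] = slack_complementarity(traj.p, traj.q)
    per = periodicity_residuals(traj)
    out["periodicity"] = np.abs(
        np.concatenate([per["kinematic"], per["force_continuity"], per["progress"],
                        per["endpoint_forces"], per["integral_start"]])
    )
    out["lr_impulse"] = np.abs(lr_impulse_residual(traj))
    return out


def constraint_report(traj: Trajectory, lmax_by_channel: np.ndarray) -> pd.DataFrame:
    """Max/mean exact-constraint violation per family at grid points."""
    rows = []
    for family, v in exact_violations(traj, lmax_by_channel).items():
        v = np.asarray(v, float)
        rows.append({"family": family, "max": float(v.max()), "mean": float(v.mean())})
    return pd.DataFrame(rows)
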