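"""Rigid-trunk two-point-mass mechanics: limb geometry, axial forces, dynamics.

The body is a rigid trunk of unit (normalized) length carrying point masses
``mF'`` (shoulders) and ``mH'`` (hips).  Limbs are massless and purely axial:
each force channel pushes along the line from its fixed footfall position to
its girdle attachment point.  Three limbs act through a trailing and a leading
contact; the left hind is the reference limb with a single contact, giving
seven force channels in total:

====== ======= ======= ========== =================
index  limb    girdle  contact    footfall
====== ======= ======= ========== =================
0      LH      hind    reference  f_LH
1      RH      hind    trailing   f_RH
2      RH      hind    leading    f_RH + D'
3      LF      fore    trailing   f_LF
4      LF      fore    leading    f_LF + D'
5      RF      fore    trailing   f_RF
6      RF      fore    leading    f_RF + D'
====== ======= ======= ========== =================

All quantities here are normalized (lengths/lB, time/T, force/mg); the
dimensionless time constant ``T_hat`` carries gravity into the equations of
motion.  Kernels are vectorized over leading axes and also return the analytic
partial derivatives the collocation transcription needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import Morphology

__all__ = [
    "CHANNELS",
    "N_CHANNELS",
    "LEADING",
    "TRAILING",
    "REFERENCE",
    "LEFT_CHANNELS",
    "RIGHT_CHANNELS",
    "LIMB_CHANNELS",
    "FOOT_PARAM_OF_CHANNEL",
    "IS_LEADING",
    "channel_rho",
    "quarter_offsets",
    "limb_vector",
    "channel_geometry",
    "accelerations",
    "limb_power",
]


@dataclass(frozen=True)
class Channel:
    index: int
    limb: str  # "LH", "RH", "LF", "RF"
    girdle: str  # "F" or "H"
    side: str  # "L" or "R"
    contact: str  # "ref", "T", "L"


CHANNELS = (
    Channel(0, "LH", "H", "L", "ref"),
    Channel(1, "RH", "H", "R", "T"),
    Channel(2, "RH", "H", "R", "L"),
    Channel(3, "LF", "F", "L", "T"),
    Channel(4, "LF", "F", "L", "L"),
    Channel(5, "RF", "F", "R", "T"),
    Channel(6, "RF", "F", "R", "L"),
)
N_CHANNELS = 7

REFERENCE = 0
TRAILING = (1, 3, 5)
LEADING = (2, 4, 6)  # paired with TRAILING in order

LEFT_CHANNELS = (0, 3, 4)
RIGHT_CHANNELS = (1, 2, 5, 6)

#: channels of each limb, used when merging contacts per limb
LIMB_CHANNELS = {"LH": (0,), "RH": (1, 2), "LF": (3, 4), "RF": (5, 6)}

#: which of the four footfall parameters (f_LH, f_RH, f_LF, f_RF) each channel uses
FOOT_PARAM_OF_CHANNEL = np.array([0, 1, 1, 2, 2, 3, 3])
IS_LEADING = np.array([0, 0, 1, 0, 1, 0, 1], dtype=float)

#: +1 if the channel loads the forequarters, -1 for the hindquarters
GIRDLE_SIGN = np.array([-1, -1, -1, +1, +1, +1, +1], dtype=float)


def channel_rho(morph: Morphology) -> np.ndarray:
    """Signed trunk offset of each channel's attachment: +mH' fore, -mF' hind."""
    return np.where(GIRDLE_SIGN > 0, morph.mH_prime, -morph.mF_prime)


def quarter_offsets(theta, mF_prime: float):
    """Vectors from the COM to the fore and hind point masses (units lB).

    ``r_F' = mH'(cos th, sin th, 0)`` and ``r_H' = -mF'(cos th, sin th, 0)``;
    their norms sum to 1 (the trunk length).
    """
    theta = np.asarray(theta, dtype=float)
    mH_prime = 1.0 - mF_prime
    c, s = np.cos(theta), np.sin(theta)
    zero = np.zeros_like(c)
    r_F = np.stack([mH_prime * c, mH_prime * s, zero], axis=-1)
    r_H = np.stack([-mF_prime * c, -mF_prime * s, zero], axis=-1)
    return r_F, r_H


def limb_vector(x_prime, r_i_prime, f_prime):
    """Limb length vector ``l' = x' + r_i' - f' x_hat`` (planar, units lB)."""
    x_prime = np.asarray(x_prime, dtype=float)
    r_i_prime = np.asarray(r_i_prime, dtype=float)
    out = x_prime + r_i_prime
    out = np.array(out, dtype=float)
    out[..., 0] -= f_prime
    return out


def limb_power(F_prime, ldot_prime):
    """Signed axial limb power ``F' * ldot'`` (units mg*lB/T)."""
    return np.asarray(F_prime, dtype=float) * np.asarray(ldot_prime, dtype=float)


def channel_geometry(x, y, th, vx, vy, om, feet, morph: Morphology, derivs: bool = True):
    """Per-channel limb geometry, rates and analytic partials.

    Parameters
    ----------
    x, y, th, vx, vy, om : arrays, shape (...,)
        Trunk state in normalized units.
    feet : array, shape (..., 7)
        Per-channel footfall positions (leading offsets already applied).
    derivs : bool
        Also return partial derivatives wrt (x, y, th, vx, vy, om, foot).

    Returns
    -------
    dict of arrays with shape (..., 7): ``l``, ``ux``, ``uy``, ``ldot``,
    ``crossu`` (torque about the COM per unit axial force) and, if requested,
    their partials ``d<name>_d<var>``.
    """
    x, y, th = np.asarray(x, float), np.asarray(y, float), np.asarray(th, float)
    vx, vy, om = np.asarray(vx, float), np.asarray(vy, float), np.asarray(om, float)
    feet = np.asarray(feet, float)
    rho = channel_rho(morph)  # (7,)

    c = np.cos(th)[..., None]
    s = np.sin(th)[..., None]
    Lx = x[..., None] + rho * c - feet
    Ly = y[..., None] + rho * s
    l = np.hypot(Lx, Ly)
    ux = Lx / l
    uy = Ly / l

    Vx = vx[..., None] - rho * s * om[..., None]
    Vy = vy[..., None] + rho * c * om[..., None]
    ldot = ux * Vx + uy * Vy
    crossu = rho * (c * uy - s * ux)

    out = {"l": l, "ux": ux, "uy": uy, "ldot": ldot, "crossu": crossu}
    if not derivs:
        return out

    # unit-vector partials wrt the limb vector components
    dux_dLx = (1.0 - ux * ux) / l
    dux_dLy = -ux * uy / l
    duy_dLy = (1.0 - uy * uy) / l
    duy_dLx = dux_dLy

    dLx_dth = -rho * s
    dLy_dth = rho * c
    dVx_dth = -rho * c * om[..., None]
    dVy_dth = -rho * s * om[..., None]

    # d(ldot)/dL = (V - ldot*u)/l
    Ax = (Vx - ldot * ux) / l
    Ay = (Vy - ldot * uy) / l

    out.update(
        dl_dx=ux,
        dl_dy=uy,
        dl_dth=ux * dLx_dth + uy * dLy_dth,
        dl_df=-ux,
        dux_dx=dux_dLx,
        dux_dy=dux_dLy,
        dux_dth=dux_dLx * dLx_dth + dux_dLy * dLy_dth,
        dux_df=-dux_dLx,
        duy_dx=duy_dLx,
        duy_dy=duy_dLy,
        duy_dth=duy_dLx * dLx_dth + duy_dLy * dLy_dth,
        duy_df=-duy_dLx,
        dldot_dx=Ax,
        dldot_dy=Ay,
        dldot_dth=Ax * dLx_dth + Ay * dLy_dth + ux * dVx_dth + uy * dVy_dth,
        dldot_df=-Ax,
        dldot_dvx=ux,
        dldot_dvy=uy,
        dldot_dom=-ux * rho * s + uy * rho * c,
    )
    # crossu = rho*(c*uy - s*ux)
    out.update(
        dcrossu_dx=rho * (c * out["duy_dx"] - s * out["dux_dx"]),
        dcrossu_dy=rho * (c * out["duy_dy"] - s * out["dux_dy"]),
        dcrossu_dth=rho * (-s * uy - c * ux + c * out["duy_dth"] - s * out["dux_dth"]),
        dcrossu_df=rho * (c * out["duy_df"] - s * out["dux_df"]),
    )
    return out


def accelerations(x, y, th, vx, vy, om, F, feet, morph: Morphology, T_hat: float):
    """Normalized COM and pitch accelerations (the equations of motion).

    ``xddot' = (-y_hat + sum_c F'_c u_c) * T_hat**2`` and
    ``thddot = (sum_c (r_c x F'_c u_c)_z / I') * T_hat**2``.

    Parameters are normalized; ``F`` and ``feet`` have a trailing axis of 7.
    Returns ``(ax, ay, alpha)`` with the leading shape of the state arrays.
    """
    if not np.isfinite(T_hat) or T_hat <= 0:
        raise ValueError("T_hat must be positive")
    morph.I_prime  # raises if degenerate via Morphology invariants
    g = channel_geometry(x, y, th, vx, vy, om, feet, morph, derivs=False)
    F = np.asarray(F, float)
    T2 = T_hat * T_hat
    ax = T2 * np.sum(F * g["ux"], axis=-1)
    ay = T2 * (-1.0 + np.sum(F * g["uy"], axis=-1))
    alpha = (T2 / morph.I_prime) * np.sum(F * g["crossu"], axis=-1)
    return ax, ay, alpha
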