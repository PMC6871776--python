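"""Body and task parameters, normalization, and closed-form derived quantities.

The model is a planar quadruped reduced to two point masses (fore- and
hindquarters) joined by a rigid, massless trunk of length ``lB``.  Massless
prismatic limbs connect each mass to the ground.  Everything downstream works
in normalized units: lengths in trunk lengths ``lB``, time in stride periods
``T``, masses in body mass ``m`` and forces in body weights ``mg``.  The
single dimensionless group that survives normalization of the dynamics is the
time constant ``T_hat = T*sqrt(g/lB)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Morphology",
    "GaitTask",
    "dimensionless_inertia",
    "froude_speed",
    "time_constant",
    "scale_force_rate",
    "mass_fractions_from_grf",
    "pendular_duty_factor",
    "malinois_stride_length",
    "DEFAULT_G",
]

DEFAULT_G = 9.81  # m/s^2, configurable everywhere it is used


def dimensionless_inertia(mF_prime: float) -> float:
    """Dimensionless pitch moment of inertia of the two-point-mass trunk.

    For point masses ``mF`` and ``mH = 1 - mF`` at the ends of a rigid trunk,
    the pitch inertia about the COM is ``I' = mF'*mH'`` (units ``m*lB**2``)
    and the dimensionless form is ``I_hat = 4*I' = 4*mF'*(1 - mF')``.
    ``I_hat < 1`` predicts trotting to be cheaper than a running walk.
    """
    if not 0.0 < mF_prime < 1.0:
        raise ValueError(f"mF_prime must lie in (0, 1), got {mF_prime}")
    return 4.0 * mF_prime * (1.0 - mF_prime)


def froude_speed(U: float, lHmax: float, g: float = DEFAULT_G) -> float:
    """Dimensionless speed ``U / sqrt(g*lHmax)``: square root of the Froude number.

    ``lHmax`` is the standing hindlimb length in metres.  ``U = 0`` is allowed.
    """
    if lHmax <= 0 or g <= 0:
        raise ValueError("leg length and g must be positive")
    if U < 0:
        raise ValueError("speed must be non-negative")
    return U / math.sqrt(g * lHmax)


def time_constant(T: float, lB: float, g: float = DEFAULT_G) -> float:
    """Dimensionless stride time constant ``T_hat = T*sqrt(g/lB)``."""
    if T <= 0 or lB <= 0 or g <= 0:
        raise ValueError("T, lB and g must be positive")
    return T * math.sqrt(g / lB)


def scale_force_rate(c1D_prime: float, T_hat_D: float, T_hat: float) -> float:
    """Scale the force-rate coefficient from the reference (Dalmatian) task.

    ``c1' = c1D' * (T_hat_D / T_hat)``: inverse proportionality to the task
    time constant, keeping the rate-penalty share of the cost roughly stable
    across scales.
    """
    if c1D_prime < 0:
        raise ValueError("c1D_prime must be non-negative")
    if T_hat_D <= 0 or T_hat <= 0:
        raise ValueError("time constants must be positive")
    return c1D_prime * (T_hat_D / T_hat)


def mass_fractions_from_grf(
    mean_fore_vertical_force: float,
    mean_hind_vertical_force: float,
    m: float,
    g: float = DEFAULT_G,
) -> tuple[float, float]:
    """Fore/hind mass fractions from stride-mean vertical GRFs of single limbs.

    During steady periodic gait the net torque about the COM vanishes, so the
    mass supported by each girdle follows from the stride-mean vertical force
    of one limb of that girdle: ``mF = 2*<y.F_Fm>/g`` and likewise for the
    hind.  Fractions are returned relative to ``m = mF + mH`` (which may
    deviate slightly from a reported body mass).  ``m`` and ``g`` are accepted
    for dimensional completeness; the fractions depend only on the force ratio.
    """
    if mean_fore_vertical_force < 0 or mean_hind_vertical_force < 0:
        raise ValueError("stride-mean vertical forces must be non-negative")
    if g <= 0 or m <= 0:
        raise ValueError("m and g must be positive")
    mF = 2.0 * mean_fore_vertical_force / g
    mH = 2.0 * mean_hind_vertical_force / g
    tot = mF + mH
    if tot <= 0 or mean_fore_vertical_force == 0 or mean_hind_vertical_force == 0:
        raise ValueError("degenerate GRFs: both girdles must carry load")
    return mF / tot, mH / tot


def pendular_duty_factor(T_n: float, T: float) -> float:
    """Duty factor if swing lasts half the leg's natural pendulum period.

    ``DF = 1 - T_n/(2T)``; valid for ``0 < T_n <= 2T``.
    """
    if T_n <= 0 or T <= 0:
        raise ValueError("periods must be positive")
    if T_n > 2.0 * T:
        raise ValueError("T_n > 2T gives a negative duty factor")
    return 1.0 - T_n / (2.0 * T)


def malinois_stride_length(U_H_prime: float) -> float:
    """Normalized stride length from the Belgian Malinois regression.

    ``D' = 1.04 + 1.36*U_H'`` with speed as the root-Froude number.
    """
    if U_H_prime < 0:
        raise ValueError("U_H_prime must be non-negative")
    return 1.04 + 1.36 * U_H_prime


@dataclass(frozen=True)
class Morphology:
    """Five-parameter body description of the two-point-mass quadruped.

    Parameters
    ----------
    mF_prime : float
        Forequarter mass fraction (of total mass m), in (0, 1).
    lB : float
        Shoulder-to-hip length in metres.
    lHmax_prime, lFmax_prime : float
        Standing hind/fore limb lengths in units of lB, each in (0, 2).
    g : float
        Gravitational acceleration, m/s^2.
    """

    mF_prime: float
    lB: float
    lHmax_prime: float
    lFmax_prime: float
    g: float = DEFAULT_G

    def __post_init__(self) -> None:
        if not 0.0 < self.mF_prime < 1.0:
            raise ValueError(f"mF_prime must be in (0, 1), got {self.mF_prime}")
        if self.lB <= 0:
            raise ValueError("lB must be positive")
        for name in ("lHmax_prime", "lFmax_prime"):
            v = getattr(self, name)
            if not 0.0 < v < 2.0:
                raise ValueError(f"{name} must be in (0, 2), got {v}")
        if self.g <= 0:
            raise ValueError("g must be positive")

    @property
    def mH_prime(self) -> float:
        return 1.0 - self.mF_prime

    @property
    def I_prime(self) -> float:
        """Normalized pitch inertia m*lB^2 of the two point masses."""
        return self.mF_prime * self.mH_prime

    @property
    def I_hat(self) -> float:
        return dimensionless_inertia(self.mF_prime)

    @property
    def lHmax(self) -> float:
        """Standing hindlimb length in metres."""
        return self.lHmax_prime * self.lB

    @property
    def lFmax(self) -> float:
        return self.lFmax_prime * self.lB


# Reference (Dalmatian) scaling constants for the force-rate coefficient.
# U = U_H' * sqrt(g*lH), T = D/U, T_hat = T*sqrt(g/lB); evaluated for the
# Dalmatian parameter set (mF'=0.61, lH'=0.89, lB=0.61 m, U_H'=0.39, D'=1.21).
DALMATIAN_C1D_PRIME = 3e-3


def _dalmatian_T_hat(g: float = DEFAULT_G) -> float:
    lB = 0.61
    lH = 0.89 * lB
    U = 0.39 * math.sqrt(g * lH)
    D = 1.21 * lB
    return time_constant(D / U, lB, g)


@dataclass(frozen=True)
class GaitTask:
    """One locomotion task: speed, stride length and normalization constants.

    Prefer the :meth:`from_speed` constructor, which derives the stride
    period, the dimensionless time constant and the scaled force-rate
    coefficient from a morphology plus a Froude speed.
    """

    U: float
    D: float
    lB: float
    g: float = DEFAULT_G
    c1D_prime: float = DALMATIAN_C1D_PRIME
    T_hat_D: float = field(default=None)  # type: ignore[assignment]
    T_n: float | None = None

    def __post_init__(self) -> None:
        if self.U <= 0 or self.D <= 0 or self.lB <= 0 or self.g <= 0:
            raise ValueError("U, D, lB, g must be positive")
        if self.T_hat_D is None:
            object.__setattr__(self, "T_hat_D", _dalmatian_T_hat(self.g))

    @property
    def T(self) -> float:
        """Stride period in seconds, D/U."""
        return self.D / self.U

    @property
    def T_hat(self) -> float:
        return time_constant(self.T, self.lB, self.g)

    @property
    def D_prime(self) -> float:
        return self.D / self.lB

    @property
    def c1_prime(self) -> float:
        return scale_force_rate(self.c1D_prime, self.T_hat_D, self.T_hat)

    def U_H_prime(self, morphology: Morphology) -> float:
        return froude_speed(self.U, morphology.lHmax, self.g)

    @classmethod
    def from_speed(
        cls,
        morphology: Morphology,
        U_H_prime: float,
        D_prime: float | None = None,
        c1D_prime: float = DALMATIAN_C1D_PRIME,
        T_n: float | None = None,
    ) -> "GaitTask":
        """Build a task from a Froude speed (and optionally a stride length).

        When ``D_prime`` is omitted, the Belgian Malinois stride-length
        regression ``D' = 1.04 + 1.36*U_H'`` supplies it.
        """
        if U_H_prime <= 0:
            raise ValueError("U_H_prime must be positive")
        U = U_H_prime * math.sqrt(morphology.g * morphology.lHmax)
        if D_prime is None:
            D_prime = malinois_stride_length(U_H_prime)
        return cls(
            U=U,
            D=D_prime * morphology.lB,
            lB=morphology.lB,
            g=morphology.g,
            c1D_prime=c1D_prime,
            T_n=T_n,
        )
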