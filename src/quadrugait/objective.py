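"""Cost of transport: limb work, squared force-rate penalty, and penalties.

The energetic hypothesis is that steady gaits minimize (positive plus
negative) limb work per distance, with a secondary penalty on how quickly
forces change.  Work enters through the slack decomposition
``F'*ldot' = p' - q'`` with ``p', q' >= 0``, so the stride work is the
integral of ``sum(p' + q')`` whenever complementarity ``p'q' = 0`` holds.
The normalized cost of transport is ``(J_w + J_r)/D'`` (equivalently
``(J_w + J_r)/(mgD)`` in physical units); the penalty-augmented objective
adds the complementarity and relaxation penalty integrals used only while
solving, never for ranking solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "CostBreakdown",
    "work_cost",
    "force_rate_cost",
    "total_cot",
    "penalty_integral",
    "augmented_objective",
    "cost_breakdown",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Per-stride costs in normalized units (work in mg*lB, CoT dimensionless)."""

    J_w: float
    J_r: float
    J_tot: float
    J_aug: float

    @property
    def rate_fraction(self) -> float:
        """Share of the force-rate penalty in the unaugmented cost, J_r/(J_w+J_r)."""
        tot = self.J_w + self.J_r
        return self.J_r / tot if tot > 0 else 0.0


def work_cost(traj: Trajectory) -> float:
    """Stride work via the power slacks: integral of sum(p' + q')."""
    if np.any(traj.p < 0) or np.any(traj.q < 0):
        raise ValueError("power slacks must be non-negative")
    return float(np.trapezoid((traj.p + traj.q).sum(axis=1), traj.t))


def force_rate_cost(traj: Trajectory, c1_prime: float) -> float:
    """Squared force-rate penalty: integral of c1' * sum(Fdot'^2) over channels."""
    if c1_prime < 0:
        raise ValueError("c1_prime must be non-negative")
    return float(c1_prime * np.trapezoid((traj.Fdot ** 2).sum(axis=1), traj.t))


def total_cot(J_w: float, J_r: float, D_prime: float) -> float:
    """Normalized cost of transport (J_w + J_r)/D'."""
    if D_prime <= 0:
        raise ValueError("D_prime must be positive")
    return (J_w + J_r) / D_prime


def penalty_integral(traj: Trajectory, c2: float, c3a: float, c3b: float, c3c: float) -> float:
    """Integral of the complementarity and relaxation penalties (per Eq-level weights)."""
    if min(c2, c3a, c3b, c3c) < 0:
        raise ValueError("penalty weights must be non-negative")
    integrand = (
        c2 * (traj.p * traj.q).sum(axis=1)
        + c3a * traj.s_a.sum(axis=1)
        + c3b * traj.s_b.sum(axis=1)
        + c3c * traj.s_c.sum(axis=1)
    )
    return float(np.trapezoid(integrand, traj.t))


def augmented_objective(J_tot: float, traj: Trajectory, c2: float, c3a: float,
                        c3b: float, c3c: float) -> float:
    """Transport cost plus the normalized penalty integral (what the NLP minimizes)."""
    return J_tot + penalty_integral(traj, c2, c3a, c3b, c3c) / traj.D_prime


def cost_breakdown(traj: Trajectory, c1_prime: float, c2: float = 0.0, c3a: float = 0.0,
                   c3b: float = 0.0, c3c: float = 0.0) -> CostBreakdown:
    J_w = work_cost(traj)
    J_r = force_rate_cost(traj, c1_prime)
    J_tot = total_cot(J_w, J_r, traj.D_prime)
    J_aug = augmented_objective(J_tot, traj, c2, c3a, c3b, c3c)
    return CostBreakdown(J_w=J_w, J_r=J_r, J_tot=J_tot, J_aug=J_aug)
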