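"""In-memory representation of one stride trajectory on a time grid.

States: trunk pose/velocity (x', y', th, vx', vy', om), seven axial limb
forces F' (states, so ground reaction forces are C0 by construction) and the
three running integrals z of the leading-contact forces used by the
trailing-before-leading ordering constraint.  Controls: force rates Fdot',
positive/negative limb-power slacks p', q' and the complementarity relaxation
variables s_a, s_b, s_c.  Footfall positions are static parameters; leading
contacts sit exactly one stride length ahead of their trailing partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics
from .dynamics import CHANNELS, FOOT_PARAM_OF_CHANNEL, IS_LEADING, N_CHANNELS
from .morphology import Morphology

__all__ = ["Trajectory", "channel_feet"]


def channel_feet(footholds: np.ndarray, D_prime: float) -> np.ndarray:
    """Expand the 4 footfall parameters into 7 per-channel contact positions."""
    footholds = np.asarray(footholds, float)
    return footholds[..., FOOT_PARAM_OF_CHANNEL] + D_prime * IS_LEADING


@dataclass
class Trajectory:
    """Sampled stride trajectory in normalized units on ``t in [0, 1]``."""

    t: np.ndarray  # (M,)
    body: np.ndarray  # (M, 6): x, y, th, vx, vy, om
    F: np.ndarray  # (M, 7) axial forces, units mg
    z: np.ndarray  # (M, 3) running integrals of leading forces
    Fdot: np.ndarray  # (M, 7) force-rate controls
    p: np.ndarray  # (M, 7) positive limb power slack
    q: np.ndarray  # (M, 7) negative limb power slack
    s_a: np.ndarray  # (M, 7) length-force relaxation
    s_b: np.ndarray  # (M, 3) ordering relaxation
    s_c: np.ndarray  # (M, 7) ventral-torque relaxation
    footholds: np.ndarray  # (4,): f_LH, f_RH, f_LF, f_RF
    D_prime: float
    morphology: Morphology

    def __post_init__(self) -> None:
        M = len(self.t)
        for name in ("body", "F", "z", "Fdot", "p", "q", "s_a", "s_b", "s_c"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape[0] != M:
                raise ValueError(f"{name} has {arr.shape[0]} samples, expected {M}")
        self.t = np.asarray(self.t, float)
        self.footholds = np.asarray(self.footholds, float)

    # -- derived geometry ---------------------------------------------------
    @property
    def feet(self) -> np.ndarray:
        return channel_feet(self.footholds, self.D_prime)

    def geometry(self, derivs: bool = False) -> dict:
        x, y, th, vx, vy, om = self.body.T
        return dynamics.channel_geometry(
            x, y, th, vx, vy, om, np.broadcast_to(self.feet, (len(self.t), N_CHANNELS)),
            self.morphology, derivs=derivs,
        )

    def limb_lengths(self) -> np.ndarray:
        return self.geometry()["l"]

    def limb_length_rates(self) -> np.ndarray:
        return self.geometry()["ldot"]

    def limb_powers(self) -> np.ndarray:
        """Signed axial power F'*ldot' per channel (mg*lB/T)."""
        return self.F * self.geometry()["ldot"]

    def force_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.geometry()
        return self.F * g["ux"], self.F * g["uy"]

    def limb_force(self, limb: str) -> np.ndarray:
        """Total axial force of one limb (its channels summed)."""
        return self.F[:, list(dynamics.LIMB_CHANNELS[limb])].sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-sample table: states, the 7 force channels, lengths, powers."""
        cols = {"t": self.t}
        for k, name in enumerate(["x", "y", "theta", "vx", "vy", "thetadot"]):
            cols[name] = self.body[:, k]
        g = self.geometry()
        powers = self.F * g["ldot"]
        for ch in CHANNELS:
            tag = f"{ch.limb}_{ch.contact}"
            cols[f"F_{tag}"] = self.F[:, ch.index]
            cols[f"Fdot_{tag}"] = self.Fdot[:, ch.index]
            cols[f"l_{tag}"] = g["l"][:, ch.index]
            cols[f"power_{tag}"] = powers[:, ch.index]
            cols[f"p_{tag}"] = self.p[:, ch.index]
            cols[f"q_{tag}"] = self.q[:, ch.index]
        return pd.DataFrame(cols)
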