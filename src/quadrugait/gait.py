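"""Gait descriptors: contacts, duty factors, phase lags, Hildebrand classes.

A limb is in contact whenever its ground reaction force is nonzero, which
numerically means above a small threshold.  Footfall timing is summarized by
three stride-fraction lags — Hind Lag (left-hind to right-hind), Pair Lag
(left-hind to left-fore) and Fore Lag (left-fore to right-fore) — measured
after shifting the time origin to left-hind touchdown.  Because the model is
planar, mirror-swapping the forelimb labels changes neither dynamics nor
cost, so gaits are reported in a canonical form in which four-beat walks are
lateral-sequence and two-beat runs are trots; the symmetrical-gait bins on
the pair lag then follow Hildebrand's terminology (lateral couplets,
singlefoot, diagonal couplets, trot, pace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import LIMB_CHANNELS
from .morphology import GaitTask
from .trajectory import Trajectory

__all__ = [
    "CONTACT_THRESHOLD",
    "GaitSummary",
    "contact_intervals",
    "duty_factor",
    "phase_lags",
    "canonicalize_lags",
    "classify_hildebrand",
    "apparent_stiffness",
    "transition_speed",
    "summarize",
]

#: force level (mg) above which a limb counts as loaded
CONTACT_THRESHOLD = 1e-3

#: symmetry tolerance on |HL - 0.5| and |FL - 0.5|
SYMMETRY_TOL = 0.05

LIMBS = ("LH", "RH", "LF", "RF")


def contact_intervals(t: np.ndarray, force: np.ndarray,
                      threshold: float = CONTACT_THRESHOLD) -> list[tuple[float, float]]:
    """Maximal intervals of t' where the limb force exceeds the threshold.

    ``force`` is the limb's total force history (its trailing and leading
    channels already summed).  Crossing times are located by linear
    interpolation between samples; an interval wrapping across t' = 1 is
    returned as a single (on, off) pair with off < on.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(t, float)
    force = np.asarray(force, float)
    on = force > threshold
    if not on.any():
        return []
    if on.all():
        return [(0.0, 1.0)]
    # locate crossings
    edges_up, edges_down = [], []
    for i in range(len(t) - 1):
        if not on[i] and on[i + 1]:
            f0, f1 = force[i], force[i + 1]
            tc = t[i] + (threshold - f0) / (f1 - f0) * (t[i + 1] - t[i])
            edges_up.append(tc)
        elif on[i] and not on[i + 1]:
            f0, f1 = force[i], force[i + 1]
            tc = t[i] + (threshold - f0) / (f1 - f0) * (t[i + 1] - t[i])
            edges_down.append(tc)
    if on[0]:
        edges_up.insert(0, t[0])
    if on[-1]:
        edges_down.append(t[-1])
    intervals = list(zip(edges_up, edges_down))
    # wrap: contact alive at both stride ends is one interval across t'=1
    if on[0] and on[-1] and len(intervals) >= 2:
        first = intervals.pop(0)
        last = intervals.pop()
        intervals.append((last[0], first[1]))
    elif on[0] and on[-1] and len(intervals) == 1:
        return [(0.0, 1.0)]
    return intervals


def _interval_length(iv: tuple[float, float]) -> float:
    on, off = iv
    return off - on if off >= on else off - on + 1.0


def duty_factor(intervals: list[tuple[float, float]]) -> float:
    """Total contact time per stride (sums interval lengths, wrap-aware)."""
    if not intervals:
        return 0.0
    return float(min(sum(_interval_length(iv) for iv in intervals), 1.0))


def _touchdown(intervals: list[tuple[float, float]]) -> float | None:
    """Touchdown = start of the longest-lived contact's onset; None if airborne."""
    if not intervals:
        return None
    return float(max(intervals, key=_interval_length)[0])


def phase_lags(touchdowns: dict[str, float]) -> tuple[float, float, float]:
    """(HL, PL, FL) stride-fraction lags from per-limb touchdown times.

    HL = t(RH) - t(LH) mod 1; PL = t(LF) - t(LH) mod 1;
    FL = t(RF) - t(LF) mod 1.
    """
    for limb in LIMBS:
        if touchdowns.get(limb) is None:
            raise ValueError(f"limb {limb} has no touchdown; phase lags undefined")
    HL = (touchdowns["RH"] - touchdowns["LH"]) % 1.0
    PL = (touchdowns["LF"] - touchdowns["LH"]) % 1.0
    FL = (touchdowns["RF"] - touchdowns["LF"]) % 1.0
    return HL, PL, FL


def canonicalize_lags(HL: float, PL: float, FL: float
                      ) -> tuple[tuple[float, float, float], bool]:
    """Mirror-swap the forelimbs into the canonical reporting form.

    The planar model is indifferent to a left-right forelimb relabelling,
    which maps (HL, PL, FL) to (HL, (PL+FL) mod 1, 1-FL).  The swap putting
    the pair lag into the four-beat walking band (1/16, 7/16] is preferred;
    failing that, the one landing in a two-beat running band.  Returns the
    canonical lags and whether the labels were swapped.
    """

    def in_walk_band(pl):
        return 1.0 / 16.0 < pl <= 7.0 / 16.0

    original = (HL, PL, FL)
    swapped = (HL, (PL + FL) % 1.0, (1.0 - FL) % 1.0)
    if in_walk_band(original[1]):
        return original, False
    if in_walk_band(swapped[1]):
        return swapped, True
    # neither is a canonical walk: prefer the trot band over the pace band
    def run_rank(pl):
        if 7.0 / 16.0 < pl <= 9.0 / 16.0:
            return 0  # trot
        if pl <= 1.0 / 16.0 or pl > 15.0 / 16.0:
            return 1  # pace
        return 2
    return (original, False) if run_rank(original[1]) <= run_rank(swapped[1]) \
        else (swapped, True)


def classify_hildebrand(PL: float, HL: float, FL: float,
                        symmetry_tol: float = SYMMETRY_TOL) -> str:
    """Symmetrical-gait label from canonical phase lags.

    Symmetry requires HL and FL within ``symmetry_tol`` of 0.5; the pair lag
    then selects the bin: pace (<=1/16 or >15/16), lateral couplets
    (1/16, 3/16], singlefoot (3/16, 5/16], diagonal couplets (5/16, 7/16],
    trot (7/16, 9/16].
    """
    if abs(HL - 0.5) > symmetry_tol or abs(FL - 0.5) > symmetry_tol:
        return "asymmetric"
    if PL <= 1.0 / 16.0 or PL > 15.0 / 16.0:
        return "pace"
    if PL <= 3.0 / 16.0:
        return "walk, lateral couplets"
    if PL <= 5.0 / 16.0:
        return "walk, singlefoot"
    if PL <= 7.0 / 16.0:
        return "walk, diagonal couplets"
    if PL <= 9.0 / 16.0:
        return "trot"
    return "other symmetric"


def apparent_stiffness(force: np.ndarray, length: np.ndarray, limax_prime: float,
                       window: float = 0.05) -> float | None:
    """Apparent leg stiffness k' = -dF'/d(l'/l'_imax) near the resting length.

    Fitted by least squares over stance samples with |l' - l'_rest| within
    ``window * l'_imax``, where l'_rest is the length at stance onset.  A
    positive k' indicates spring-like behaviour (force rises as the leg
    shortens).  Returns None when undefined (no stance, or no length
    variation in the window).
    """
    force = np.asarray(force, float)
    length = np.asarray(length, float)
    stance = force > CONTACT_THRESHOLD
    if not stance.any():
        return None
    onset = int(np.argmax(stance))
    l_rest = length[onset]
    sel = stance & (np.abs(length - l_rest) <= window * limax_prime)
    if sel.sum() < 3:
        return None
    xi = length[sel] / limax_prime
    if np.ptp(xi) < 1e-12:
        return None
    slope = np.polyfit(xi, force[sel], 1)[0]
    return float(-slope)


def transition_speed(sweep) -> float | None:
    """Walk-to-run transition speed from a sweep of gait outcomes.

    ``sweep`` maps speed to either a gait label (model sweeps: the lowest
    speed whose pseudo-global gait is a trot) or to a walking relative
    frequency in [0, 1] (empirical tables: the first speed where the
    frequency has dropped below 0.5).  Returns None when no transition
    occurs in the range.
    """
    speeds = sorted(sweep)
    for u in speeds:
        v = sweep[u]
        if isinstance(v, str):
            if v in ("trot", "pace"):
                return float(u)
        else:
            if v < 0.5:
                return float(u)
    return None


@dataclass
class GaitSummary:
    """Descriptors of one solved stride."""

    intervals: dict[str, list[tuple[float, float]]]
    duty_factors: dict[str, float]
    DF_hind: float
    DF_fore: float
    DF_mean: float
    HL: float
    PL: float
    FL: float
    forelimbs_swapped: bool
    hildebrand: str
    symmetric: bool
    CoT: float | None = None
    rate_fraction: float | None = None
    stiffness: dict[str, float | None] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "DF_LH": self.duty_factors["LH"], "DF_RH": self.duty_factors["RH"],
            "DF_LF": self.duty_factors["LF"], "DF_RF": self.duty_factors["RF"],
            "DF_hind": self.DF_hind, "DF_fore": self.DF_fore,
            "DF_mean": self.DF_mean,
            "HL": self.HL, "PL": self.PL, "FL": self.FL,
            "hildebrand": self.hildebrand, "symmetric": self.symmetric,
            "CoT": self.CoT, "rate_fraction": self.rate_fraction,
        }
        for limb, k in self.stiffness.items():
            row[f"k_{limb}"] = k
        return row


def summarize(traj: Trajectory, task: GaitTask | None = None,
              threshold: float = CONTACT_THRESHOLD,
              symmetry_tol: float = SYMMETRY_TOL) -> GaitSummary:
    """Full gait description of a trajectory.

    Phase lags are canonicalized (forelimb mirror swap) and timed from
    left-hind touchdown; duty factors are per-limb contact fractions with
    trailing/leading channels merged.  When ``task`` is given, the cost of
    transport and its force-rate share are included.
    """
    intervals, dfs, tds = {}, {}, {}
    for limb in LIMBS:
        iv = contact_intervals(traj.t, traj.limb_force(limb), threshold)
        intervals[limb] = iv
        dfs[limb] = duty_factor(iv)
        tds[limb] = _touchdown(iv)

    HL, PL, FL = phase_lags(tds)
    (HL, PL, FL), swapped = canonicalize_lags(HL, PL, FL)
    label = classify_hildebrand(PL, HL, FL, symmetry_tol)
    symmetric = abs(HL - 0.5) <= symmetry_tol and abs(FL - 0.5) <= symmetry_tol

    lengths = traj.limb_lengths()
    stiffness = {}
    for limb in LIMBS:
        chans = list(LIMB_CHANNELS[limb])
        F = traj.F[:, chans].sum(axis=1)
        # active channel's length at each sample (the loaded contact's leg)
        if len(chans) == 1:
            L = lengths[:, chans[0]]
        else:
            lead_loaded = traj.F[:, chans[1]] > traj.F[:, chans[0]]
            L = np.where(lead_loaded, lengths[:, chans[1]], lengths[:, chans[0]])
        limax = traj.morphology.lFmax_prime if limb in ("LF", "RF") \
            else traj.morphology.lHmax_prime
        stiffness[limb] = apparent_stiffness(F, L, limax)

    CoT = rate_fraction = None
    if task is not None:
        from .objective import cost_breakdown

        cb = cost_breakdown(traj, task.c1_prime)
        CoT = cb.J_tot
        rate_fraction = cb.rate_fraction

    return GaitSummary(
        intervals=intervals,
        duty_factors=dfs,
        DF_hind=0.5 * (dfs["LH"] + dfs["RH"]),
        DF_fore=0.5 * (dfs["LF"] + dfs["RF"]),
        DF_mean=float(np.mean([dfs[limb] for limb in LIMBS])),
        HL=HL, PL=PL, FL=FL,
        forelimbs_swapped=swapped,
        hildebrand=label,
        symmetric=symmetric,
        CoT=CoT,
        rate_fraction=rate_fraction,
        stiffness=stiffness,
    )


def gait_diagram(summary: GaitSummary) -> pd.DataFrame:
    """Tidy (limb, on, off) table of contact intervals for plotting."""
    rows = []
    for limb, ivs in summary.intervals.items():
        for on, off in ivs:
            rows.append({"limb": limb, "on": on, "off": off})
    return pd.DataFrame(rows, columns=["limb", "on", "off"])
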