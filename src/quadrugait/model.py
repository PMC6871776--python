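"""Model/Results front end for gait discovery.

``QuadrupedGaitModel`` bundles a morphology and a locomotion task; ``fit()``
runs the seeded multistart trajectory optimization and returns
``GaitFitResults`` holding every local optimum, the pseudo-global pick, its
gait summary and a tabular overview — the ergonomics of a statistical model
object, for an optimization-based mechanistic model.
"""

from __future__ import annotations

import pandas as pd

from .gait import GaitSummary, summarize
from .morphology import GaitTask, Morphology
from .solver import MultistartResult, Solution, SolverConfig, multistart

__all__ = ["QuadrupedGaitModel", "GaitFitResults"]


class QuadrupedGaitModel:
    """Planar two-point-mass quadruped whose footfall sequence is optimized.

    Parameters
    ----------
    morphology : Morphology
        Body parameters (mass split, trunk and limb lengths).
    task : GaitTask
        Speed, stride length and the force-rate coefficient.
    config : SolverConfig, optional
        Transcription/homotopy/multistart tunables.

    Examples
    --------
    >>> morph = Morphology(mF_prime=0.61, lB=0.61,
    ...                    lHmax_prime=0.89, lFmax_prime=0.79)
    >>> task = GaitTask.from_speed(morph, U_H_prime=0.39, D_prime=1.21)
    >>> model = QuadrupedGaitModel(morph, task)
    >>> results = model.fit(n_starts=20, seed=0)     # doctest: +SKIP
    >>> print(results.summary())                     # doctest: +SKIP
    """

    def __init__(self, morphology: Morphology, task: GaitTask,
                 config: SolverConfig | None = None):
        self.morphology = morphology
        self.task = task
        self.config = config or SolverConfig()

    @classmethod
    def from_config(cls, path, overrides: dict | None = None) -> "QuadrupedGaitModel":
        """Build from a YAML config file or packaged preset name."""
        from .io import load_task_config

        morph, task, config = load_task_config(path, overrides)
        return cls(morph, task, config)

    def fit(self, n_starts: int | None = None, seed: int | None = None,
            progress: bool = False) -> "GaitFitResults":
        """Run the multistart homotopy and wrap the outcome."""
        res = multistart(self.morphology, self.task, self.config,
                         n_starts=n_starts, seed=seed, progress=progress)
        return GaitFitResults(self, res)


class GaitFitResults:
    """Solutions of one multistart fit, with the pseudo-global optimum."""

    def __init__(self, model: QuadrupedGaitModel, result: MultistartResult):
        self.model = model
        self.result = result
        self._summaries: dict[int, GaitSummary] = {}

    # -- access -------------------------------------------------------------
    @property
    def solutions(self) -> list[Solution]:
        return self.result.solutions

    @property
    def valid_solutions(self) -> list[Solution]:
        return self.result.valid_solutions

    @property
    def best(self) -> Solution | None:
        """Pseudo-global optimum: lowest-CoT valid solution."""
        return self.result.best

    @property
    def converged(self) -> bool:
        return self.result.best is not None

    def gait(self, solution: Solution | None = None) -> GaitSummary:
        """Gait summary (duty factors, lags, Hildebrand class) of a solution."""
        sol = solution if solution is not None else self.best
        if sol is None:
            raise ValueError("no valid solution to summarize")
        key = id(sol)
        if key not in self._summaries:
            self._summaries[key] = summarize(sol.trajectory, self.model.task)
        return self._summaries[key]

    # -- tables -------------------------------------------------------------
    def table(self) -> pd.DataFrame:
        """One row per solution: costs, validity, gait descriptors."""
        rows = []
        for sol in self.solutions:
            row = {
                "guess": sol.guess_index, "seed": sol.seed,
                "J_tot": sol.J_tot, "J_w": sol.costs.J_w, "J_r": sol.costs.J_r,
                "rate_fraction": sol.costs.rate_fraction,
                "valid": sol.valid, "converged": sol.converged,
                "mesh_error": sol.mesh_error, "max_violation": sol.max_violation,
                "wall_time": sol.wall_time,
            }
            try:
                row.update(self.gait(sol).to_row())
            except ValueError:
                pass
            rows.append(row)
        return pd.DataFrame(rows).sort_values("J_tot").reset_index(drop=True)

    def summary(self) -> str:
        """Readable fit report in the style of statistical results objects."""
        task, morph = self.model.task, self.model.morphology
        lines = [
            "Quadruped gait optimization results",
            "===================================",
            f"speed U'_H = {task.U_H_prime(morph):.3f}   stride D' = "
            f"{task.D_prime:.3f}   T_hat = {task.T_hat:.3f}   "
            f"c1' = {task.c1_prime:.2e}",
            f"starts: {len(self.solutions)} solved, "
            f"{len(self.valid_solutions)} valid",
        ]
        best = self.best
        if best is None:
            lines.append("no valid solution found")
            return "\n".join(lines)
        g = self.gait(best)
        lines += [
            "",
            f"pseudo-global optimum (guess {best.guess_index}):",
            f"  CoT = {best.J_tot:.4f}  (work {best.costs.J_w:.4f} + "
            f"rate {best.costs.J_r:.4f}; rate share "
            f"{100 * best.costs.rate_fraction:.1f}%)",
            f"  gait: {g.hildebrand}  (HL={g.HL:.3f}, PL={g.PL:.3f}, "
            f"FL={g.FL:.3f})",
            f"  duty factors: hind {g.DF_hind:.3f}, fore {g.DF_fore:.3f}, "
            f"mean {g.DF_mean:.3f}",
            f"  diagnostics: mesh error {best.mesh_error:.2e}, "
            f"max violation {best.max_violation:.2e}",
        ]
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------
    def plot_grf(self, solution: Solution | None = None, ax=None):
        """Limb-force traces of a solution (normalized, per limb)."""
        import matplotlib.pyplot as plt

        sol = solution if solution is not None else self.best
        if sol is None:
            raise ValueError("no valid solution to plot")
        if ax is None:
            _, ax = plt.subplots()
        traj = sol.trajectory
        for limb in ("LH", "RH", "LF", "RF"):
            ax.plot(traj.t, traj.limb_force(limb), label=limb)
        ax.set_xlabel("t'")
        ax.set_ylabel("axial force (mg)")
        ax.legend()
        return ax

    def plot_gait_diagram(self, solution: Solution | None = None, ax=None):
        """Hildebrand-style bar diagram of contact intervals."""
        import matplotlib.pyplot as plt

        sol = solution if solution is not None else self.best
        g = self.gait(sol)
        if ax is None:
            _, ax = plt.subplots()
        order = ("LH", "LF", "RF", "RH")
        for k, limb in enumerate(order):
            for on, off in g.intervals[limb]:
                if off >= on:
                    ax.barh(k, off - on, left=on, height=0.6)
                else:  # wraps
                    ax.barh(k, 1.0 - on, left=on, height=0.6)
                    ax.barh(k, off, left=0.0, height=0.6)
        ax.set_yticks(range(len(order)), order)
        ax.set_xlim(0, 1)
        ax.set_xlabel("t'")
        return ax
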