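"""Configuration parsing, result persistence and run manifests.

Configs are YAML with ``morphology``, ``task`` and ``solver`` blocks; four
packaged presets carry the dog parameter sets used for validation (a
Rhodesian-ridgeback mix, a Dalmatian, a Labrador retriever and the Belgian
Malinois whose stride length follows a speed regression).  Solutions persist
as an HDF5 file plus CSV sidecars (trajectory table and constraint report);
everything is stored in normalized units with the normalization constants as
attributes, so physical units can be recovered on export.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml

from .constraints import constraint_report
from .morphology import GaitTask, Morphology
from .objective import CostBreakdown
from .solver import MultistartResult, Solution, SolverConfig, VariableBounds
from .trajectory import Trajectory

__all__ = [
    "PRESETS",
    "load_task_config",
    "preset_path",
    "write_solution",
    "read_solution",
    "write_manifest",
]

_PRESET_DIR = Path(__file__).parent / "presets"
PRESETS = ("rhodesian_mix", "dalmatian", "labrador", "belgian_malinois")

_MORPH_KEYS = {"mF_prime", "lB", "lHmax_prime", "lFmax_prime", "g"}
_TASK_KEYS = {"U_H_prime", "D_prime", "c1D_prime", "T_n"}
_SOLVER_KEYS = {f.name for f in dataclasses.fields(SolverConfig)}
_BOUND_KEYS = {f.name for f in dataclasses.fields(VariableBounds)}


def preset_path(name: str) -> Path:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return _PRESET_DIR / f"{name}.yaml"


def load_task_config(path, overrides: dict | None = None
                     ) -> tuple[Morphology, GaitTask, SolverConfig]:
    """Parse a YAML task config into validated objects.

    ``overrides`` may supply or replace task-block entries (typically
    ``U_H_prime`` for the speed-sweep presets).  Unknown keys anywhere are
    rejected; omitted optional fields take the documented defaults.
    """
    path = Path(path)
    if not path.exists() and path.stem in PRESETS and not path.is_absolute():
        path = preset_path(path.stem)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    unknown_blocks = set(raw) - {"name", "morphology", "task", "solver"}
    if unknown_blocks:
        raise ValueError(f"unknown config blocks: {sorted(unknown_blocks)}")

    mdict = dict(raw.get("morphology") or {})
    if set(mdict) - _MORPH_KEYS:
        raise ValueError(f"unknown morphology keys: {sorted(set(mdict) - _MORPH_KEYS)}")
    morph = Morphology(**mdict)

    tdict = dict(raw.get("task") or {})
    tdict.update(overrides or {})
    if set(tdict) - _TASK_KEYS:
        raise ValueError(f"unknown task keys: {sorted(set(tdict) - _TASK_KEYS)}")
    if tdict.get("U_H_prime") is None:
        raise ValueError("task.U_H_prime is required (preset may expect an override)")
    kwargs = {k: v for k, v in tdict.items() if v is not None}
    task = GaitTask.from_speed(morph, **kwargs)

    sdict = dict(raw.get("solver") or {})
    bdict = sdict.pop("bounds", None)
    if set(sdict) - _SOLVER_KEYS:
        raise ValueError(f"unknown solver keys: {sorted(set(sdict) - _SOLVER_KEYS)}")
    if bdict:
        if set(bdict) - _BOUND_KEYS:
            raise ValueError(f"unknown bounds keys: {sorted(set(bdict) - _BOUND_KEYS)}")
        sdict["bounds"] = VariableBounds(**{k: tuple(v) for k, v in bdict.items()})
    config = SolverConfig(**sdict)
    return morph, task, config


_TRAJ_ARRAYS = ("t", "body", "F", "z", "Fdot", "p", "q", "s_a", "s_b", "s_c")
_SCHEMA_VERSION = 1


def write_solution(sol: Solution, directory) -> Path:
    """Persist one solution as HDF5 + CSV sidecars; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    traj = sol.trajectory
    with h5py.File(directory / "solution.h5", "w") as h5:
        h5.attrs["schema_version"] = _SCHEMA_VERSION
        g = h5.create_group("trajectory")
        for name in _TRAJ_ARRAYS:
            g.create_dataset(name, data=getattr(traj, name))
        g.create_dataset("footholds", data=traj.footholds)
        g.attrs["D_prime"] = traj.D_prime
        m = traj.morphology
        for k in ("mF_prime", "lB", "lHmax_prime", "lFmax_prime", "g"):
            h5.attrs[f"morphology/{k}"] = getattr(m, k)
        for k in ("J_w", "J_r", "J_tot", "J_aug"):
            h5.attrs[f"costs/{k}"] = getattr(sol.costs, k)
        h5.attrs["mesh_error"] = sol.mesh_error
        h5.attrs["max_violation"] = sol.max_violation
        h5.attrs["valid"] = sol.valid
        h5.attrs["converged"] = sol.converged
        if sol.seed is not None:
            h5.attrs["seed"] = sol.seed
        if sol.guess_index is not None:
            h5.attrs["guess_index"] = sol.guess_index
        h5.attrs["status_json"] = json.dumps(sol.status)
        h5.attrs["violations_json"] = json.dumps(sol.violations)
    traj.to_dataframe().to_csv(directory / "trajectory.csv", index=False)
    lmax = np.where([c in (3, 4, 5, 6) for c in range(7)],
                    m.lFmax_prime, m.lHmax_prime)
    constraint_report(traj, lmax).to_csv(directory / "constraint_report.csv",
                                         index=False)
    return directory


def read_solution(directory) -> Solution:
    """Reconstruct a Solution from :func:`write_solution` output."""
    directory = Path(directory)
    fn = directory / "solution.h5"
    try:
        with h5py.File(fn, "r") as h5:
            if int(h5.attrs.get("schema_version", -1)) != _SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported solution schema in {fn}: "
                    f"{h5.attrs.get('schema_version')!r}")
            morph = Morphology(
                mF_prime=float(h5.attrs["morphology/mF_prime"]),
                lB=float(h5.attrs["morphology/lB"]),
                lHmax_prime=float(h5.attrs["morphology/lHmax_prime"]),
                lFmax_prime=float(h5.attrs["morphology/lFmax_prime"]),
                g=float(h5.attrs["morphology/g"]),
            )
            g = h5["trajectory"]
            arrays = {name: np.asarray(g[name]) for name in _TRAJ_ARRAYS}
            traj = Trajectory(
                **arrays, footholds=np.asarray(g["footholds"]),
                D_prime=float(g.attrs["D_prime"]), morphology=morph,
            )
            costs = CostBreakdown(
                J_w=float(h5.attrs["costs/J_w"]), J_r=float(h5.attrs["costs/J_r"]),
                J_tot=float(h5.attrs["costs/J_tot"]), J_aug=float(h5.attrs["costs/J_aug"]),
            )
            return Solution(
                trajectory=traj, costs=costs,
                mesh_error=float(h5.attrs["mesh_error"]),
                violations=json.loads(h5.attrs["violations_json"]),
                max_violation=float(h5.attrs["max_violation"]),
                valid=bool(h5.attrs["valid"]), converged=bool(h5.attrs["converged"]),
                status=json.loads(h5.attrs["status_json"]),
                seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None,
                guess_index=(int(h5.attrs["guess_index"])
                             if "guess_index" in h5.attrs else None),
            )
    except OSError as exc:
        raise ValueError(f"cannot read solution file {fn}: {exc}") from exc


def write_manifest(result: MultistartResult, config: SolverConfig,
                   directory, extra: dict | None = None) -> Path:
    """JSON run manifest: config snapshot, per-guess seeds/outcomes, version."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "status": result.status,
        "solutions": [
            {
                "guess_index": s.guess_index, "seed": s.seed,
                "J_tot": s.J_tot, "valid": s.valid, "converged": s.converged,
                "mesh_error": s.mesh_error, "max_violation": s.max_violation,
                "wall_time": s.wall_time, "directory": f"solution_{s.guess_index:03d}",
            }
            for s in result.solutions
        ],
        "best_guess_index": (result.best.guess_index
                             if result.best is not None else None),
    }
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return path
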