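"""Static energy scans and equilibrium Langevin runs on reduced complexes.

The energy scan reproduces the step-0 evaluation protocol used when
comparing a force field against reference curves: the gas ligand is
rigidly translated along the out-of-plane axis to a series of bond
lengths and the total potential energy is recorded — no dynamics.

``run_langevin`` drives the :class:`~coordff.engine.Engine` on a complex
with its force field and optional distance biases, sampling distances,
the Fe–O²–O¹ angle (when O₂ is present) and the kinetic temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PotentialCurve
from .engine import CVBias, DistanceCV, Engine
from .forcefield import ForceField, ForceFieldConfig, build_forcefield
from .potentials import BiasSpec, LJPairParams
from .reduced_model import ReducedComplex, measure_angle

__all__ = ["Trajectory", "TrajectoryStats", "energy_scan", "run_langevin"]


@dataclass
class Trajectory:
    """Sampled observable streams from one run (times in ps)."""

    time_ps: np.ndarray
    data: dict[str, np.ndarray]
    frames: np.ndarray | None = None  # (n_frames, N, 3) if stored
    seed: int | None = None

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]


@dataclass
class TrajectoryStats:
    """Mean/sd of tracked observables and the mean kinetic temperature."""

    n_frames: int
    means: dict[str, float]
    sds: dict[str, float]
    kinetic_temperature: float


def _ligand_anchor(cx: ReducedComplex, ligand: str | None) -> tuple[str, int, list[int]]:
    if ligand is None:
        if len(cx.ligands) != 1:
            raise ValueError("specify the ligand to scan for a multi-ligand complex")
        ligand = next(iter(cx.ligands))
    if ligand not in cx.ligands:
        raise ValueError(f"complex has no {ligand} ligand")
    idx = cx.ligands[ligand]
    return ligand, idx[0], idx  # anchor = bond-forming atom (C of CO, O2 of O2)


def energy_scan(
    cx: ReducedComplex,
    params: dict | ForceField | None = None,
    r_grid: np.ndarray | None = None,
    ligand: str | None = None,
    return_flags: bool = False,
):
    """Potential energy versus Fe–ligand bond length.

    The whole ligand is rigidly translated along the out-of-plane axis so
    that the Fe–anchor distance equals each grid value; everything else is
    untouched.  Points where any pair distance falls below the overlap
    floor are flagged (energy set to NaN) rather than silently kept.
    """
    if r_grid is None:
        r_grid = np.arange(1.75, 2.95 + 1e-9, 0.1)
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("scan grid must be positive")
    ff = params if isinstance(params, ForceField) else build_forcefield(cx, params)
    _, anchor, lig_idx = _ligand_anchor(cx, ligand)
    n = cx.plane_normal
    p0 = cx.positions[anchor]
    z0 = float(p0 @ n)
    rho2 = float(p0 @ p0) - z0 * z0  # squared off-axis offset, invariant
    u = np.empty_like(r_grid)
    flags = np.zeros(r_grid.shape, dtype=bool)
    x = cx.positions.copy()
    for k, r in enumerate(r_grid):
        if r * r < rho2:
            flags[k] = True
            u[k] = np.nan
            continue
        dz = np.sqrt(r * r - rho2) - z0
        x[lig_idx] = cx.positions[lig_idx] + dz * n
        try:
            u[k] = ff.energy(x)
        except FloatingPointError:
            flags[k] = True
            u[k] = np.nan
    curve = PotentialCurve(r=r_grid, U=u, label="model")
    return (curve, flags) if return_flags else curve


def run_langevin(
    cx: ReducedComplex,
    params: dict | ForceField | None = None,
    biases: list[tuple[BiasSpec, tuple[int, int]]] | None = None,
    duration_ps: float = 20.0,
    dt_fs: float = 2.0,
    temperature: float = 300.0,
    friction_per_ps: float = 5.0,
    seed: int = 0,
    n_samples: int = 100,
    store_frames: bool = False,
) -> tuple[Trajectory, TrajectoryStats]:
    """Equilibrium Langevin run, sampling ``n_samples`` snapshots.

    Observables: every Fe–anchor distance (``d_Fe_CO``, ``d_Fe_O2``), the
    Fe–O²–O¹ angle (degrees) when O₂ is present, and the kinetic
    temperature.  Fully reproducible for a fixed seed.
    """
    ff = params if isinstance(params, ForceField) else build_forcefield(cx, params)
    terms: list = [ff]
    for spec, (i, j) in biases or []:
        terms.append(CVBias(spec, DistanceCV(i, j)))
    eng = Engine(
        cx.positions,
        cx.masses,
        cx.mobile_mask,
        terms,
        constraints=cx.constraints,
        dt_fs=dt_fs,
        temperature=temperature,
        friction_per_ps=friction_per_ps,
        seed=seed,
    )
    n_steps = max(1, int(round(duration_ps * 1000.0 / dt_fs)))
    record_every = max(1, n_steps // max(1, n_samples))

    recorders = {}
    fe = cx.fe_index
    for name, idx in cx.ligands.items():
        key = f"d_Fe_{name.replace('+', '_')}"
        recorders[key] = (lambda a: (lambda e: float(np.linalg.norm(e.x[a] - e.x[fe]))))(idx[0])
    if "O2" in cx.ligands:
        i_o2, i_o1 = cx.ligands["O2"]
        recorders["angle_FeO2O1"] = lambda e: measure_angle(e.x, fe, i_o2, i_o1)

    recs = eng.run(n_steps, record_every=record_every, recorders=recorders, store_frames=store_frames)
    time_ps = recs.pop("time_ps")
    frames = recs.pop("frames", None)
    traj = Trajectory(time_ps=time_ps, data=recs, frames=frames, seed=seed)
    kin = recs["kinetic_T"]
    obs = {k: v for k, v in recs.items() if k != "kinetic_T"}
    stats = TrajectoryStats(
        n_frames=len(time_ps),
        means={k: float(np.mean(v)) for k, v in obs.items()},
        sds={k: float(np.std(v)) for k, v in obs.items()},
        kinetic_temperature=float(np.mean(kin)),
    )
    return traj, stats
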