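"""Biased-sampling assays on the reduced complex: steered (SMD) rupture
of the Fe–CO bond under a restrained-O₂ environment, and well-tempered
metadynamics over the two bond-length collective variables with
free-energy-surface reconstruction and slice analysis.

Protocol constants follow the restrained-environment setup they model:
relaxation holds Fe–C(CO) under an upper wall (ceiling 1.89 Å, stiffness
150 kcal/mol/Å²) with a harmonic Fe–O² restraint of reference length 0;
SMD pulls the Fe–C distance with a moving harmonic (κ = 10 kcal/mol/Å²,
nominal rate 1 Å/ns); metadynamics deposits hills of initial height
8 kcal/mol and width 0.2 Å every 1 ps inside 5 Å / 150 kcal/mol/Å² walls
on both distances.  Desk runs scale the pulling rate and durations by a
single logged factor; peak rupture forces are rate-dependent, so
comparisons are always made at equal rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import CVBias, DistanceCV, Engine
from .forcefield import ForceField, ForceFieldConfig, build_forcefield
from .potentials import KB_KCAL, BiasKind, BiasSpec
from .reduced_model import GeometryConfig, ReducedComplex, build_complex

__all__ = [
    "RelaxedState",
    "ForceExtensionCurve",
    "SMDResult",
    "SMDSweepResult",
    "HillsLog",
    "WellTemperedMetadBias",
    "FreeEnergySurface",
    "SliceEnergy",
    "ApproachPattern",
    "relax_system",
    "run_smd",
    "smd_sweep",
    "run_wt_metad",
    "reconstruct_fes",
    "slice_effective_bond_energy",
    "approach_pattern",
]

RELAX_WALL_CEILING = 1.89
RELAX_WALL_KAPPA = 150.0
SMD_KAPPA = 10.0
SMD_RATE_A_PER_NS = 1.0
HILL_HEIGHT = 8.0
HILL_WIDTH = 0.2
HILL_EVERY_PS = 1.0
REBIND_WALL_CEILING = 5.0
REBIND_WALL_KAPPA = 150.0


# --------------------------------------------------------------------------
# relaxation + steered pulling
# --------------------------------------------------------------------------


@dataclass
class RelaxedState:
    """Equilibrated system ready for a steered pull."""

    cx: ReducedComplex  # positions updated in place
    velocities: np.ndarray
    o2_kappa: float
    seed: int


@dataclass
class ForceExtensionCurve:
    """One steered pull: spring force versus restraint extension."""

    extension: np.ndarray  # Å, moving-reference position minus start
    force: np.ndarray  # kcal/mol/Å, raw pulling-spring force
    force_smooth: np.ndarray  # same, smoothed for peak detection
    peak_force: float
    peak_index: int
    mean_fe_o2_bound: float | None  # time-mean Fe-O2 while CO is bound (pre-peak)
    replicate: int
    seed: int
    ruptured: bool


@dataclass
class SMDResult:
    curves: list[ForceExtensionCurve]
    o2_kappa: float
    rate_scale: float

    @property
    def peak_forces(self) -> np.ndarray:
        return np.array([c.peak_force for c in self.curves])

    @property
    def mean_peak_force(self) -> float:
        return float(self.peak_forces.mean())

    @property
    def sd_peak_force(self) -> float:
        return float(self.peak_forces.std(ddof=1)) if len(self.curves) > 1 else 0.0

    @property
    def mean_fe_o2(self) -> float | None:
        vals = [c.mean_fe_o2_bound for c in self.curves if c.mean_fe_o2_bound is not None]
        return float(np.mean(vals)) if vals else None


@dataclass
class SMDSweepResult:
    by_kappa: dict[float, SMDResult]
    seed: int

    def summary(self) -> dict[float, dict[str, float | None]]:
        return {
            k: {
                "mean_peak_force": r.mean_peak_force,
                "sd_peak_force": r.sd_peak_force,
                "mean_fe_o2": r.mean_fe_o2,
            }
            for k, r in self.by_kappa.items()
        }


def _o2_bias(cx: ReducedComplex, kappa: float) -> CVBias:
    i_o2 = cx.ligands["O2"][0]
    return CVBias(
        BiasSpec(BiasKind.HARMONIC, kappa=kappa, r0=0.0),
        DistanceCV(cx.fe_index, i_o2, "d_Fe_O2"),
    )


def relax_system(
    cx: ReducedComplex,
    params: dict | ForceField | None = None,
    o2_kappa: float = 0.0,
    duration_ps: float = 20.0,
    temperature: float = 300.0,
    seed: int = 0,
    dt_fs: float = 2.0,
    friction_per_ps: float = 5.0,
) -> RelaxedState:
    """Equilibrate under the relaxation biases.

    CO (when present) is kept in the bound region by the upper wall on the
    Fe–C distance; O₂ (when present and ``o2_kappa > 0``) is held by the
    zero-reference harmonic.  With ``o2_kappa = 0`` the O₂ is unrestrained
    (no wall is applied during relaxation).
    """
    if o2_kappa < 0:
        raise ValueError("o2_kappa must be non-negative")
    if o2_kappa > 0 and "O2" not in cx.ligands:
        raise ValueError("o2_kappa > 0 requires an O2 ligand")
    cx = cx.copy()
    ff = params if isinstance(params, ForceField) else build_forcefield(cx, params)
    terms: list = [ff]
    if "CO" in cx.ligands:
        terms.append(
            CVBias(
                BiasSpec(BiasKind.UPPER_WALL, kappa=RELAX_WALL_KAPPA, ceiling=RELAX_WALL_CEILING),
                DistanceCV(cx.fe_index, cx.ligands["CO"][0], "d_Fe_C"),
            )
        )
    if "O2" in cx.ligands and o2_kappa > 0:
        terms.append(_o2_bias(cx, o2_kappa))
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
    eng.run(n_steps)
    cx.positions = eng.x.copy()
    return RelaxedState(cx=cx, velocities=eng.v.copy(), o2_kappa=o2_kappa, seed=seed)


def _smooth(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or y.size < 3:
        return y.copy()
    w = min(w, y.size)
    kernel = np.ones(w) / w
    pad = np.concatenate([np.full(w - 1, y[0]), y])
    return np.convolve(pad, kernel, mode="valid")


def run_smd(
    state: RelaxedState,
    params: dict | ForceField | None = None,
    kappa_pull: float = SMD_KAPPA,
    rate_a_per_ns: float = SMD_RATE_A_PER_NS,
    rate_scale: float = 50.0,
    max_extension: float = 4.0,
    temperature: float = 300.0,
    dt_fs: float = 2.0,
    friction_per_ps: float = 5.0,
    record_every_ps: float = 0.05,
    smooth_ps: float = 1.0,
    replicate: int = 0,
) -> ForceExtensionCurve:
    """One steered pull of the Fe–C(CO) distance from a relaxed state.

    The moving harmonic starts at the instantaneous Fe–C distance and its
    reference grows at ``rate_a_per_ns * rate_scale`` Å/ns.  The recorded
    pulling force is the spring force κ·(r0(t) − d); the peak is taken
    from a ``smooth_ps`` running mean of the trace.  The Fe–O² distance
    (when O₂ is present) is averaged over the CO-bound (pre-peak) part.
    """
    cx = state.cx
    if "CO" not in cx.ligands:
        raise ValueError("SMD pulls the Fe-C(CO) distance; no CO ligand present")
    ff = params if isinstance(params, ForceField) else build_forcefield(cx, params)
    fe = cx.fe_index
    i_c = cx.ligands["CO"][0]
    d0 = float(np.linalg.norm(cx.positions[i_c] - cx.positions[fe]))
    rate_eff = rate_a_per_ns * rate_scale  # Å/ns
    pull_spec = BiasSpec(BiasKind.MOVING_HARMONIC, kappa=kappa_pull, r0=d0, rate=rate_eff)
    pull_cv = DistanceCV(fe, i_c, "d_Fe_C")
    terms: list = [ff, CVBias(pull_spec, pull_cv)]
    if "O2" in cx.ligands and state.o2_kappa > 0:
        terms.append(_o2_bias(cx, state.o2_kappa))
    eng = Engine(
        cx.positions,
        cx.masses,
        cx.mobile_mask,
        terms,
        constraints=cx.constraints,
        dt_fs=dt_fs,
        temperature=temperature,
        friction_per_ps=friction_per_ps,
        seed=state.seed + 104729,  # pull noise stream distinct from relaxation
    )
    eng.v = state.velocities.copy()
    duration_ps = max_extension / rate_eff * 1e3
    n_steps = int(round(duration_ps * 1000.0 / dt_fs))
    record_every = max(1, int(round(record_every_ps * 1000.0 / dt_fs)))

    recorders = {
        "d_Fe_C": lambda e: float(np.linalg.norm(e.x[i_c] - e.x[fe])),
        "r0": lambda e: pull_spec.reference(e.t_ns),
    }
    if "O2" in cx.ligands:
        i_o2 = cx.ligands["O2"][0]
        recorders["d_Fe_O2"] = lambda e: float(np.linalg.norm(e.x[i_o2] - e.x[fe]))
    recs = eng.run(n_steps, record_every=record_every, recorders=recorders)

    extension = recs["r0"] - d0
    force = pull_spec.kappa * (recs["r0"] - recs["d_Fe_C"])
    w = max(1, int(round(smooth_ps / record_every_ps)))
    force_smooth = _smooth(force, w)
    peak_index = int(np.argmax(force_smooth))
    peak_force = float(force_smooth[peak_index])
    # ruptured if the bond ran away from the spring reference by the end
    ruptured = bool(recs["d_Fe_C"][-1] > d0 + 0.6 * max_extension)
    mean_o2 = None
    if "d_Fe_O2" in recs and peak_index > 0:
        mean_o2 = float(np.mean(recs["d_Fe_O2"][: peak_index + 1]))
    return ForceExtensionCurve(
        extension=extension,
        force=force,
        force_smooth=force_smooth,
        peak_force=peak_force,
        peak_index=peak_index,
        mean_fe_o2_bound=mean_o2,
        replicate=replicate,
        seed=state.seed,
        ruptured=ruptured,
    )


def smd_sweep(
    o2_kappas=(0.0, 1.0, 3.0, 5.0, 10.0),
    n_rep: int = 5,
    seed: int = 0,
    params: dict | None = None,
    geometry: GeometryConfig | None = None,
    ff_config: ForceFieldConfig | None = None,
    rate_scale: float = 50.0,
    relax_ps: float = 20.0,
    temperature: float = 300.0,
    **smd_kwargs,
) -> SMDSweepResult:
    """Stiffness sweep: relax + pull, ``n_rep`` seeded replicates per O₂
    restraint stiffness.  Replicates use seeds seed, seed+1, ... seed+n−1.

    ``o2_kappa = 0`` is the control without an O₂ molecule around the
    bound CO (the no-O₂-environment reference).
    """
    out: dict[float, SMDResult] = {}
    for kappa in o2_kappas:
        ligand = "CO" if kappa == 0 else "CO+O2"
        curves = []
        for rep in range(n_rep):
            rep_seed = seed + rep
            cx = build_complex(ligand, geometry)
            ff = build_forcefield(cx, params, ff_config)
            state = relax_system(
                cx, ff, o2_kappa=kappa, duration_ps=relax_ps, temperature=temperature, seed=rep_seed
            )
            curves.append(
                run_smd(
                    state,
                    ff,
                    rate_scale=rate_scale,
                    temperature=temperature,
                    replicate=rep,
                    **smd_kwargs,
                )
            )
        out[float(kappa)] = SMDResult(curves=curves, o2_kappa=float(kappa), rate_scale=rate_scale)
    return SMDSweepResult(by_kappa=out, seed=seed)


# --------------------------------------------------------------------------
# well-tempered metadynamics
# --------------------------------------------------------------------------


@dataclass
class HillsLog:
    """Deposited Gaussian hills: times (ps), centers (n, k), heights
    (kcal/mol, decaying in well-tempered mode), one shared width (Å)."""

    times_ps: np.ndarray
    centers: np.ndarray
    heights: np.ndarray
    width: float
    gamma: float
    cv_names: list[str]

    @property
    def n_cvs(self) -> int:
        return self.centers.shape[1] if self.centers.ndim == 2 else 1


class WellTemperedMetadBias:
    """History-dependent Gaussian bias over one or two CVs.

    The deposited height decays as h = h0·exp(−V(s)/(kB·ΔT)) with
    ΔT = (γ−1)·T, so revisited regions receive ever-smaller hills and the
    accumulated bias converges to −(1 − 1/γ)·F(s).
    """

    def __init__(
        self,
        cvs: list,
        height0: float = HILL_HEIGHT,
        width: float = HILL_WIDTH,
        gamma: float = 10.0,
        temperature: float = 300.0,
    ):
        if gamma <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")
        if height0 <= 0 or width <= 0:
            raise ValueError("hill height and width must be positive")
        self.cvs = list(cvs)
        self.h0 = float(height0)
        self.w = float(width)
        self.gamma = float(gamma)
        self.kb_dT = KB_KCAL * temperature * (gamma - 1.0)
        self._centers: list[list[float]] = []
        self._heights: list[float] = []
        self._times: list[float] = []

    def _values(self, x: np.ndarray) -> np.ndarray:
        return np.array([cv.value(x) for cv in self.cvs])

    def bias_and_grad(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        if not self._centers:
            return 0.0, np.zeros_like(s)
        c = np.asarray(self._centers)
        h = np.asarray(self._heights)
        diff = s[None, :] - c
        g = np.exp(-np.sum(diff * diff, axis=1) / (2.0 * self.w * self.w))
        e = float(np.sum(h * g))
        dvds = -np.sum((h * g)[:, None] * diff, axis=0) / (self.w * self.w)
        return e, dvds

    def bias(self, s: np.ndarray) -> float:
        return self.bias_and_grad(np.asarray(s, float))[0]

    def energy_forces(self, x: np.ndarray, t_ns: float):
        s = self._values(x)
        e, dvds = self.bias_and_grad(s)
        forces = np.zeros_like(x)
        for k, cv in enumerate(self.cvs):
            cv.add_force(forces, x, -dvds[k])
        return e, forces

    def deposit(self, x: np.ndarray, t_ps: float) -> float:
        s = self._values(x)
        v = self.bias(s)
        h = self.h0 * math.exp(-v / self.kb_dT)
        self._centers.append(list(s))
        self._heights.append(h)
        self._times.append(t_ps)
        return h

    def log(self) -> HillsLog:
        if not self._centers:
            raise ValueError("no hills deposited")
        return HillsLog(
            times_ps=np.asarray(self._times),
            centers=np.asarray(self._centers),
            heights=np.asarray(self._heights),
            width=self.w,
            gamma=self.gamma,
            cv_names=[cv.name for cv in self.cvs],
        )


def run_wt_metad(
    cx: ReducedComplex,
    params: dict | ForceField | None = None,
    duration_ps: float = 500.0,
    hill_height: float = HILL_HEIGHT,
    hill_width: float = HILL_WIDTH,
    hill_every_ps: float = HILL_EVERY_PS,
    gamma: float = 10.0,
    wall_ceiling: float = REBIND_WALL_CEILING,
    wall_kappa: float = REBIND_WALL_KAPPA,
    temperature: float = 300.0,
    seed: int = 0,
    dt_fs: float = 2.0,
    friction_per_ps: float = 5.0,
    store_frames: bool = False,
    record_every_ps: float = 0.2,
) -> tuple[HillsLog, "object"]:
    """Well-tempered metadynamics over (Fe–C, Fe–O²) on the CO+O₂ complex.

    Both distances are confined by upper walls at ``wall_ceiling`` so the
    ligands rebind rapidly.  Returns the hills log and the sampled
    trajectory (dict of series; frames included when requested).
    """
    if "CO" not in cx.ligands or "O2" not in cx.ligands:
        raise ValueError("metadynamics requires both CO and O2 ligands, walled")
    cx = cx.copy()
    ff = params if isinstance(params, ForceField) else build_forcefield(cx, params)
    fe = cx.fe_index
    cv1 = DistanceCV(fe, cx.ligands["CO"][0], "d_Fe_C")
    cv2 = DistanceCV(fe, cx.ligands["O2"][0], "d_Fe_O2")
    metad = WellTemperedMetadBias(
        [cv1, cv2], height0=hill_height, width=hill_width, gamma=gamma, temperature=temperature
    )
    terms = [
        ff,
        CVBias(BiasSpec(BiasKind.UPPER_WALL, kappa=wall_kappa, ceiling=wall_ceiling), cv1),
        CVBias(BiasSpec(BiasKind.UPPER_WALL, kappa=wall_kappa, ceiling=wall_ceiling), cv2),
        metad,
    ]
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
    n_steps = int(round(duration_ps * 1000.0 / dt_fs))
    metad_every = max(1, int(round(hill_every_ps * 1000.0 / dt_fs)))
    record_every = max(1, int(round(record_every_ps * 1000.0 / dt_fs)))
    recs = eng.run(
        n_steps,
        record_every=record_every,
        recorders={"d_Fe_C": lambda e: cv1.value(e.x), "d_Fe_O2": lambda e: cv2.value(e.x)},
        metad=metad,
        metad_every=metad_every,
        store_frames=store_frames,
    )
    for key in ("d_Fe_C", "d_Fe_O2"):
        if np.any(recs[key] > wall_ceiling + 2.0):
            raise RuntimeError(f"CV {key} escaped far beyond the wall")
    return metad.log(), recs


@dataclass
class FreeEnergySurface:
    """Reconstructed free energy over (Fe–C, Fe–O²), minimum-shifted to 0."""

    x: np.ndarray  # Fe-C grid, Å
    y: np.ndarray  # Fe-O2 grid, Å
    F: np.ndarray  # (nx, ny) kcal/mol
    gamma: float

    def slice_at_fe_o2(self, value: float) -> tuple[np.ndarray, np.ndarray]:
        iy = int(np.argmin(np.abs(self.y - value)))
        return self.x, self.F[:, iy]


def _bias_on_points(hills: HillsLog, pts: np.ndarray) -> np.ndarray:
    c = hills.centers if hills.centers.ndim == 2 else hills.centers[:, None]
    diff = pts[:, None, :] - c[None, :, :]
    g = np.exp(-np.sum(diff * diff, axis=2) / (2.0 * hills.width**2))
    return g @ hills.heights


def reconstruct_fes(
    hills: HillsLog,
    gamma: float | None = None,
    x_grid: np.ndarray | None = None,
    y_grid: np.ndarray | None = None,
):
    """Free energy from the accumulated well-tempered bias.

    F(s) = −γ/(γ−1) · V_bias(s), minimum-shifted to zero.  For a 2-CV log
    returns a :class:`FreeEnergySurface`; for a 1-CV log returns
    ``(grid, F)`` arrays.
    """
    gamma = hills.gamma if gamma is None else gamma
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    scale = gamma / (gamma - 1.0)
    if hills.n_cvs == 1:
        grid = x_grid
        if grid is None:
            lo, hi = hills.centers.min(), hills.centers.max()
            grid = np.linspace(lo, hi, 201)
        v = _bias_on_points(hills, np.asarray(grid, float)[:, None])
        f = -scale * v
        return np.asarray(grid, float), f - f.min()
    if x_grid is None:
        x_grid = np.linspace(1.5, REBIND_WALL_CEILING, 71)
    if y_grid is None:
        y_grid = np.linspace(1.5, REBIND_WALL_CEILING, 71)
    xx, yy = np.meshgrid(x_grid, y_grid, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    v = _bias_on_points(hills, pts).reshape(xx.shape)
    f = -scale * v
    return FreeEnergySurface(x=np.asarray(x_grid), y=np.asarray(y_grid), F=f - f.min(), gamma=gamma)


@dataclass
class SliceEnergy:
    """Effective bond energy along one constant-Fe–O² slice."""

    value: float  # kcal/mol
    r_eq: float  # slice minimum location, Å
    flagged: bool  # True if the slice has no interior minimum


def slice_effective_bond_energy(fes: FreeEnergySurface, fixed_fe_o2: float) -> SliceEnergy:
    """Effective CO bond energy of the constant-Fe–O² slice.

    The maximum free energy between the slice's bond-length minimum and
    the outer grid edge, relative to that minimum.  Invariant under adding
    a constant to the surface.  A slice whose minimum sits on the outer
    edge has no bound state and is flagged.
    """
    if not (fes.y.min() - 1e-9 <= fixed_fe_o2 <= fes.y.max() + 1e-9):
        raise ValueError("fixed Fe-O2 distance outside the surface grid")
    x, prof = fes.slice_at_fe_o2(fixed_fe_o2)
    imin = int(np.argmin(prof))
    flagged = imin >= len(prof) - 1
    tail_max = float(np.max(prof[imin:]))
    return SliceEnergy(value=tail_max - float(prof[imin]), r_eq=float(x[imin]), flagged=flagged)


@dataclass
class ApproachPattern:
    """Per-frame O² distances to Fe and to the nearest heme nitrogen."""

    fe_distance: np.ndarray
    n_heme_distance: np.ndarray
    direct_fraction: float  # of frames with Fe dist < threshold, how many approach Fe first
    threshold: float


def approach_pattern(
    frames: np.ndarray, cx: ReducedComplex, threshold: float = 3.5
) -> ApproachPattern:
    """O₂ approach analysis: per frame, the O²–Fe distance and the minimum
    O²–N(heme) distance, plus the fraction of close frames (Fe distance <
    ``threshold``) in which O² is nearer to Fe than to any heme nitrogen
    (direct axial approach rather than sliding over the plane)."""
    if "O2" not in cx.ligands:
        raise ValueError("complex has no O2 ligand")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    i_o2 = cx.ligands["O2"][0]
    fe = cx.fe_index
    n_idx = [k for k, s in enumerate(cx.species) if s == "NH"]
    d_fe = np.linalg.norm(frames[:, i_o2] - frames[:, fe], axis=1)
    d_n = np.min(
        np.linalg.norm(frames[:, i_o2, None, :] - frames[:, n_idx, :], axis=2), axis=1
    )
    close = d_fe < threshold
    frac = float(np.mean(d_fe[close] < d_n[close])) if np.any(close) else float("nan")
    return ApproachPattern(
        fe_distance=d_fe, n_heme_distance=d_n, direct_fraction=frac, threshold=threshold
    )
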