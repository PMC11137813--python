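"""Minimal Langevin integrator with rigid-diatomic constraints.

Internal units: Å, fs, amu, kcal/mol.  The BAOAB splitting is used; rigid
bonds are enforced by exact pairwise projection after every drift (the
two-body analogue of SHAKE/RATTLE — exact for a diatomic, so the bond
length never drifts).  Biases act on scalar collective variables (pair
distances or single coordinates) through the chain rule.

Energy terms are duck-typed: anything with
``energy_forces(x, t_ns) -> (float, (N,3) array)`` can be added, which is
how the pair force field, CV biases, metadynamics bias and toy external
potentials all plug in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .potentials import KB_KCAL, BiasSpec, bias_energy_force

__all__ = [
    "ACC_CONV",
    "DistanceCV",
    "CoordinateCV",
    "CVBias",
    "CallableTerm",
    "Engine",
]

#: (kcal/mol/Å)/amu -> Å/fs² ; also converts kB T/m to (Å/fs)².
ACC_CONV = 4.184e-4


class DistanceCV:
    """Distance between two sites as a collective variable."""

    def __init__(self, i: int, j: int, name: str = ""):
        self.i, self.j = int(i), int(j)
        self.name = name or f"d({i},{j})"

    def value(self, x: np.ndarray) -> float:
        return float(np.linalg.norm(x[self.j] - x[self.i]))

    def add_force(self, forces: np.ndarray, x: np.ndarray, f_s: float) -> None:
        d = x[self.j] - x[self.i]
        u = d / np.linalg.norm(d)
        forces[self.j] += f_s * u
        forces[self.i] -= f_s * u


class CoordinateCV:
    """A single Cartesian coordinate of one site (toy landscapes)."""

    def __init__(self, i: int, axis: int = 0, name: str = ""):
        self.i, self.axis = int(i), int(axis)
        self.name = name or f"x[{i},{axis}]"

    def value(self, x: np.ndarray) -> float:
        return float(x[self.i, self.axis])

    def add_force(self, forces: np.ndarray, x: np.ndarray, f_s: float) -> None:
        forces[self.i, self.axis] += f_s


class CVBias:
    """A :class:`BiasSpec` applied to one collective variable."""

    def __init__(self, spec: BiasSpec, cv):
        self.spec = spec
        self.cv = cv

    def energy_forces(self, x: np.ndarray, t_ns: float):
        s = self.cv.value(x)
        e, f_s = bias_energy_force(self.spec, s, t_ns)
        forces = np.zeros_like(x)
        if f_s != 0.0:
            self.cv.add_force(forces, x, f_s)
        return e, forces


class CallableTerm:
    """Wrap ``fn(x) -> (energy, forces)`` as an energy term."""

    def __init__(self, fn):
        self.fn = fn

    def energy_forces(self, x: np.ndarray, t_ns: float):
        return self.fn(x)


class Engine:
    """BAOAB Langevin integrator over a set of energy terms.

    Parameters
    ----------
    positions, masses, mobile_mask:
        System state; immobile sites never move and carry no thermal noise.
    terms:
        Energy terms (force field, biases, ...), each with
        ``energy_forces(x, t_ns)``.
    constraints:
        Rigid bonds ``(i, j, length)``.
    dt_fs, temperature, friction_per_ps, seed:
        Integration settings.  ``temperature=0`` gives deterministic
        overdamped-free dynamics (no noise).
    """

    def __init__(
        self,
        positions: np.ndarray,
        masses: np.ndarray,
        mobile_mask: np.ndarray,
        terms: list,
        constraints: list[tuple[int, int, float]] = (),
        dt_fs: float = 2.0,
        temperature: float = 300.0,
        friction_per_ps: float = 5.0,
        seed: int = 0,
    ):
        self.x = np.array(positions, dtype=float)
        self.m = np.asarray(masses, dtype=float)
        self.mobile = np.asarray(mobile_mask, dtype=bool)
        self.terms = list(terms)
        self.constraints = list(constraints)
        self.dt = float(dt_fs)
        self.T = float(temperature)
        self.gamma = friction_per_ps * 1e-3  # fs^-1
        self.rng = np.random.default_rng(seed)
        self.t_fs = 0.0
        self.v = np.zeros_like(self.x)
        self.inv_m = np.where(self.mobile, 1.0 / self.m, 0.0)[:, None]
        c1 = math.exp(-self.gamma * self.dt)
        self._oc1 = c1
        sigma_v = np.sqrt(np.maximum(1.0 - c1 * c1, 0.0) * KB_KCAL * self.T * ACC_CONV / self.m)
        self._oc2 = np.where(self.mobile, sigma_v, 0.0)[:, None]
        # degrees of freedom of the thermostatted subsystem
        n_con = sum(1 for (i, j, _) in self.constraints if self.mobile[i] or self.mobile[j])
        self.ndof = 3 * int(self.mobile.sum()) - n_con
        self._f_cache = None

    # -- constraint projections (exact for a single bond) -----------------
    def _shake(self) -> None:
        for i, j, d0 in self.constraints:
            wi, wj = self.inv_m[i, 0], self.inv_m[j, 0]
            ws = wi + wj
            if ws == 0.0:
                continue
            d = self.x[j] - self.x[i]
            r = np.linalg.norm(d)
            u = d / r
            corr = r - d0
            self.x[i] += u * corr * (wi / ws)
            self.x[j] -= u * corr * (wj / ws)

    def _rattle(self) -> None:
        for i, j, d0 in self.constraints:
            wi, wj = self.inv_m[i, 0], self.inv_m[j, 0]
            ws = wi + wj
            if ws == 0.0:
                continue
            d = self.x[j] - self.x[i]
            u = d / np.linalg.norm(d)
            vrel = float((self.v[j] - self.v[i]) @ u)
            self.v[i] += u * vrel * (wi / ws)
            self.v[j] -= u * vrel * (wj / ws)

    # ---------------------------------------------------------------------
    @property
    def t_ns(self) -> float:
        return self.t_fs * 1e-6

    @property
    def t_ps(self) -> float:
        return self.t_fs * 1e-3

    def forces(self, x: np.ndarray | None = None, t_ns: float | None = None):
        x = self.x if x is None else x
        t_ns = self.t_ns if t_ns is None else t_ns
        e_tot = 0.0
        f_tot = np.zeros_like(x)
        for term in self.terms:
            e, f = term.energy_forces(x, t_ns)
            e_tot += e
            f_tot += f
        if not np.all(np.isfinite(f_tot)):
            raise FloatingPointError(f"non-finite force at t={self.t_ps:.3f} ps")
        return e_tot, f_tot

    def kinetic_temperature(self) -> float:
        ke = 0.5 * float(np.sum(self.m[:, None] * self.v * self.v)) / ACC_CONV
        if self.ndof <= 0:
            return 0.0
        return 2.0 * ke / (self.ndof * KB_KCAL)

    def minimize_step(self, n_steps: int = 200, step: float = 0.01) -> None:
        """Crude steepest-descent settle (used before dynamics if wanted)."""
        for _ in range(n_steps):
            _, f = self.forces()
            fm = f * (self.inv_m > 0)
            norm = np.max(np.abs(fm))
            if norm < 1e-8:
                break
            self.x += np.clip(fm * step, -0.05, 0.05)
            self._shake()

    def run(
        self,
        n_steps: int,
        record_every: int = 0,
        recorders: dict | None = None,
        metad=None,
        metad_every: int = 0,
        store_frames: bool = False,
    ) -> dict:
        """Integrate ``n_steps`` steps.

        ``recorders`` maps names to callables ``f(engine) -> float``
        sampled every ``record_every`` steps (plus kinetic temperature).
        ``metad`` (optional) gets ``deposit(x, t_ps)`` every
        ``metad_every`` steps.  Returns a dict of recorded series plus
        ``"time_ps"`` (and ``"frames"`` if requested).
        """
        recs: dict[str, list] = {name: [] for name in (recorders or {})}
        recs["time_ps"] = []
        recs["kinetic_T"] = []
        frames = [] if store_frames else None
        dt = self.dt
        half = 0.5 * dt
        _, f = self.forces()
        for step in range(n_steps):
            if metad is not None and metad_every and step % metad_every == 0:
                metad.deposit(self.x, self.t_ps)
                _, f = self.forces()
            # B
            self.v += half * f * self.inv_m * ACC_CONV
            self._rattle()
            # A
            self.x += half * self.v
            self._shake()
            # O
            if self.T > 0:
                self.v = self._oc1 * self.v + self._oc2 * self.rng.standard_normal(self.x.shape)
            else:
                self.v = self._oc1 * self.v
            self._rattle()
            # A
            self.x += half * self.v
            self._shake()
            # B
            _, f = self.forces()
            self.v += half * f * self.inv_m * ACC_CONV
            self._rattle()
            self.t_fs += dt
            if record_every and (step + 1) % record_every == 0:
                recs["time_ps"].append(self.t_ps)
                recs["kinetic_T"].append(self.kinetic_temperature())
                for name, fn in (recorders or {}).items():
                    recs[name].append(fn(self))
                if store_frames:
                    frames.append(self.x.copy())
        out = {k: np.asarray(v) for k, v in recs.items()}
        if store_frames:
            out["frames"] = np.asarray(frames)
        return out
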