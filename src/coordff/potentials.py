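"""Closed-form pair potentials, bias terms and the tabulated-force rule.

Energies are in kcal/mol, distances in Å, forces in kcal/mol/Å and time in
ns for bias schedules.  Pair-specific Lennard-Jones (LJ) terms model the
Fe(heme)-ligand coordination bond; the well depth ``epsilon`` is stored
*signed* (negative for an attractive pair, matching the printed parameter
tables), and every formula uses its magnitude.

Two LJ conventions are supported because parameter tables in the
coordination-chemistry literature print "ε, σ" without always stating the
functional form:

* ``sigma``  — U(r) = 4|ε| [(σ/r)^12 − (σ/r)^6]; minimum −|ε| at 2^(1/6) σ.
* ``rmin``   — U(r) = |ε| [(R/r)^12 − 2 (R/r)^6]; minimum −|ε| at R.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KB_KCAL",
    "KCAL_PER_MOL_ANGSTROM_TO_PN",
    "LJConvention",
    "LJPairParams",
    "BiasKind",
    "BiasSpec",
    "lj_energy",
    "lj_force",
    "lj_max_attractive_force",
    "finite_difference_force",
    "switching_factor",
    "switching_derivative",
    "bias_energy_force",
]

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041

#: Display-only conversion of forces: 1 kcal/mol/Å ≈ 69.48 pN.
KCAL_PER_MOL_ANGSTROM_TO_PN = 69.48


class LJConvention(str, enum.Enum):
    """Functional-form convention for a printed (ε, σ) pair."""

    SIGMA = "sigma"
    RMIN = "rmin"


@dataclass(frozen=True)
class LJPairParams:
    """Pair-specific LJ parameters for one atom pair.

    Parameters
    ----------
    epsilon:
        Well depth, kcal/mol, stored signed as printed (negative for an
        attractive coordination pair).  ``epsilon == 0`` encodes a zeroed
        (disabled) pair.
    sigma:
        Length parameter, Å.  Interpreted per ``convention``.
    convention:
        ``sigma`` (textbook form, default) or ``rmin`` (CHARMM NBFIX form).
    """

    epsilon: float
    sigma: float
    convention: LJConvention = LJConvention.SIGMA

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def eps_abs(self) -> float:
        return abs(self.epsilon)

    @property
    def r_min(self) -> float:
        """Location of the energy minimum, Å."""
        if self.convention is LJConvention.SIGMA:
            return 2.0 ** (1.0 / 6.0) * self.sigma
        return self.sigma

    @property
    def sigma_form(self) -> float:
        """The sigma-form length parameter regardless of convention."""
        if self.convention is LJConvention.SIGMA:
            return self.sigma
        return self.sigma / 2.0 ** (1.0 / 6.0)

    def is_active(self) -> bool:
        return self.epsilon != 0.0


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    return r


def lj_energy(params: LJPairParams, r):
    """LJ pair energy at separation ``r`` (scalar or array), kcal/mol."""
    r = _check_r(r)
    s = params.sigma_form / r
    s6 = s**6
    return 4.0 * params.eps_abs * (s6 * s6 - s6)


def lj_force(params: LJPairParams, r):
    """Analytic LJ pair force F = −dU/dr, kcal/mol/Å.

    Positive values push the pair apart (repulsion); the force vanishes at
    the minimum 2^(1/6) σ and its attractive magnitude peaks at
    (26/7)^(1/6) σ.
    """
    r = _check_r(r)
    sig = params.sigma_form
    s = sig / r
    s6 = s**6
    return 24.0 * params.eps_abs / sig * (2.0 * s6 * s6 - s6) * s


def lj_max_attractive_force(params: LJPairParams) -> float:
    """Magnitude of the maximum attractive force of the pair, kcal/mol/Å.

    Attained at r* = (26/7)^(1/6) σ (inflection of U).
    """
    r_star = (26.0 / 7.0) ** (1.0 / 6.0) * params.sigma_form
    return float(-lj_force(params, r_star))


def finite_difference_force(curve: "PotentialCurve") -> "PotentialCurve":
    """Tabulated force from adjacent energy differences.

    F_i = −(U_{i+1} − U_i)/Δr, assigned to the *left* grid point r_i: the
    returned curve drops the last grid point, so it has one fewer usable
    point than the energy table.  A single interval with a larger energy
    jump than its neighbours produces a local spike in F at that r — this
    is a property of the scheme, deliberately preserved.
    """
    from .curves import PotentialCurve

    if curve.U is None:
        raise ValueError("curve has no energies to differentiate")
    r = np.asarray(curve.r, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 grid points")
    dr = np.diff(r)
    if not np.allclose(dr, dr[0], rtol=1e-8, atol=1e-10):
        raise ValueError("finite-difference force requires a uniform grid")
    f = -(np.diff(curve.U)) / dr
    return PotentialCurve(r=r[:-1], U=np.asarray(curve.U)[:-1], F=f, label=curve.label)


def switching_factor(r, r_on: float = 8.0, r_off: float = 10.0):
    """CHARMM-style cubic-in-r² switching function, 1 below ``r_on`` and 0
    beyond ``r_off``, continuously differentiable in between."""
    if not 0 < r_on < r_off:
        raise ValueError(f"require 0 < r_on < r_off, got ({r_on}, {r_off})")
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    denom = (off2 - on2) ** 3
    mid = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / denom
    out = np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, mid))
    return out if out.ndim else float(out)


def switching_derivative(r, r_on: float = 8.0, r_off: float = 10.0):
    """dS/dr of :func:`switching_factor` (needed for switched forces)."""
    if not 0 < r_on < r_off:
        raise ValueError(f"require 0 < r_on < r_off, got ({r_on}, {r_off})")
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    denom = (off2 - on2) ** 3
    # d/dr [ (off2-r2)^2 (off2+2 r2-3 on2) ] = 12 r (off2-r2)(on2-r2)
    mid = 12.0 * r * (off2 - r2) * (on2 - r2) / denom
    out = np.where((r <= r_on) | (r >= r_off), 0.0, mid)
    return out if out.ndim else float(out)


class BiasKind(str, enum.Enum):
    HARMONIC = "harmonic"
    MOVING_HARMONIC = "moving-harmonic"
    UPPER_WALL = "upper-wall"
    LOWER_WALL = "lower-wall"


@dataclass(frozen=True)
class BiasSpec:
    """One bias term on a scalar collective variable (a distance, Å).

    ``kappa`` is the stiffness in kcal/mol/Å².  For a moving harmonic the
    reference length grows as r0(t) = r0 + rate·t with ``rate`` in Å/ns;
    walls are one-sided harmonics anchored at ``ceiling``.
    """

    kind: BiasKind
    kappa: float
    r0: float = 0.0
    rate: float | None = None
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.kind is BiasKind.MOVING_HARMONIC and self.rate is None:
            raise ValueError("moving-harmonic bias requires a rate")
        if self.kind is not BiasKind.MOVING_HARMONIC and self.rate is not None:
            raise ValueError("rate is defined only for moving-harmonic biases")
        if self.kind in (BiasKind.UPPER_WALL, BiasKind.LOWER_WALL) and self.ceiling is None:
            raise ValueError("wall bias requires a ceiling")

    def reference(self, t_ns: float = 0.0) -> float:
        """Instantaneous reference length of the bias, Å."""
        if self.kind is BiasKind.MOVING_HARMONIC:
            return self.r0 + self.rate * t_ns
        if self.kind in (BiasKind.UPPER_WALL, BiasKind.LOWER_WALL):
            return self.ceiling
        return self.r0


def bias_energy_force(spec: BiasSpec, x: float, t_ns: float = 0.0) -> tuple[float, float]:
    """Energy (kcal/mol) and force −dU/dx (kcal/mol/Å) of a bias at CV
    value ``x`` and time ``t_ns`` (ns; only the moving harmonic uses it)."""
    if t_ns < 0:
        raise ValueError("time must be non-negative")
    k = spec.kappa
    if spec.kind in (BiasKind.HARMONIC, BiasKind.MOVING_HARMONIC):
        d = x - spec.reference(t_ns)
        return 0.5 * k * d * d, -k * d
    d = x - spec.ceiling
    if spec.kind is BiasKind.UPPER_WALL:
        if d <= 0:
            return 0.0, 0.0
        return 0.5 * k * d * d, -k * d
    # lower wall
    if d >= 0:
        return 0.0, 0.0
    return 0.5 * k * d * d, -k * d
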