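"""Reduced heme–imidazole–gas-ligand model builder and synthetic
ground-truth curves.

The reduced complex is a deliberately coarse stand-in for the full
solvated protein: an iron site at the origin, four in-plane pyrrole
nitrogens, an imidazole nitrogen anchor below the plane, and one or two
rigid diatomic gas ligands (CO and/or O₂) above the plane — both on the
same side when both are present.  Only the degrees of freedom the
coordination parameters govern are mobile by default (the ligands); the
heme plane and imidazole are held fixed.

The synthetic ground-truth generator produces energy–distance tables from
closed-form pair parameters (plus an optional smooth background and seeded
Gaussian noise), standing in for quantum reference curves that are not
publicly deposited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PotentialCurve
from .potentials import LJPairParams, lj_energy

__all__ = [
    "SPECIES_MASSES",
    "GeometryConfig",
    "ReducedComplex",
    "build_complex",
    "synthesize_ground_truth_curve",
    "measure_angle",
]

#: Atomic masses, amu, by site label.
SPECIES_MASSES = {
    "FE": 55.845,
    "NH": 14.007,  # heme pyrrole nitrogen
    "NI": 14.007,  # imidazole anchor nitrogen
    "CC": 12.011,  # carbon of CO
    "OC": 15.999,  # oxygen of CO
    "O1": 15.999,  # distal oxygen of O2
    "O2": 15.999,  # proximal (bond-forming) oxygen of O2
}


@dataclass(frozen=True)
class GeometryConfig:
    """Internal coordinates of the reduced complex, Å and degrees.

    Defaults are plausible placeholders chosen from typical heme
    coordination geometry (Fe–N(pyrrole) ≈ 2.0 Å, Fe–N(imidazole) ≈ 2.1 Å,
    C≡O 1.128 Å, O=O 1.21 Å); the original optimized internal coordinates
    of the source complexes are not reproduced here.
    """

    fe_n_distance: float = 2.0
    imidazole_distance: float = 2.1
    co_bond: float = 1.128
    o2_bond: float = 1.21
    #: starting Fe–C distance for a lone CO ligand
    fe_c_start: float = 2.01
    #: starting Fe–O² distance for a lone O₂ ligand
    fe_o2_start: float = 2.13
    #: Fe–O²–O¹ tilt angle at construction, degrees
    o2_tilt_deg: float = 120.0
    #: O₂ placement when CO is also present: Fe–O² distance and polar angle
    fe_o2_start_paired: float = 3.1
    o2_polar_deg_paired: float = 55.0
    o2_azimuth_deg_paired: float = 45.0


@dataclass
class ReducedComplex:
    """Coordinates, species and minimal topology of the reduced system."""

    positions: np.ndarray  # (N, 3) Å
    species: list[str]
    masses: np.ndarray  # (N,) amu
    mobile_mask: np.ndarray  # (N,) bool
    plane_normal: np.ndarray  # unit vector, out-of-plane axis
    constraints: list[tuple[int, int, float]]  # rigid bonds (i, j, length)
    ligands: dict[str, list[int]]  # "CO" -> [i_C, i_O]; "O2" -> [i_O2, i_O1]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.mobile_mask = np.asarray(self.mobile_mask, dtype=bool)
        if self.species.count("FE") != 1:
            raise ValueError("reduced complex must contain exactly one Fe site")

    @property
    def n_sites(self) -> int:
        return len(self.species)

    @property
    def fe_index(self) -> int:
        return self.species.index("FE")

    def index_of(self, label: str) -> int:
        return self.species.index(label)

    def copy(self) -> "ReducedComplex":
        return ReducedComplex(
            positions=self.positions.copy(),
            species=list(self.species),
            masses=self.masses.copy(),
            mobile_mask=self.mobile_mask.copy(),
            plane_normal=self.plane_normal.copy(),
            constraints=list(self.constraints),
            ligands={k: list(v) for k, v in self.ligands.items()},
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def build_complex(ligand: str, config: GeometryConfig | None = None) -> ReducedComplex:
    """Construct the reduced complex for ``ligand`` in {"CO", "O2", "CO+O2"}.

    Fe sits at the origin, the heme nitrogens at equal in-plane distance
    along ±x/±y, the imidazole nitrogen on −z, and the ligand(s) on +z —
    on the same side of the plane when both are present.  The O₂ ligand is
    built with its Fe–O²–O¹ angle exactly at ``config.o2_tilt_deg`` and
    with Fe–O² ≤ Fe–O¹ (O² is the proximal, bond-forming atom).
    Deterministic for a given config.
    """
    cfg = config or GeometryConfig()
    if ligand not in ("CO", "O2", "CO+O2"):
        raise ValueError(f"unknown ligand choice {ligand!r}")

    species = ["FE", "NH", "NH", "NH", "NH", "NI"]
    rho = cfg.fe_n_distance
    pos = [
        [0.0, 0.0, 0.0],
        [rho, 0.0, 0.0],
        [0.0, rho, 0.0],
        [-rho, 0.0, 0.0],
        [0.0, -rho, 0.0],
        [0.0, 0.0, -cfg.imidazole_distance],
    ]
    constraints: list[tuple[int, int, float]] = []
    ligands: dict[str, list[int]] = {}

    def add_co():
        i_c = len(species)
        species.extend(["CC", "OC"])
        pos.append([0.0, 0.0, cfg.fe_c_start])
        pos.append([0.0, 0.0, cfg.fe_c_start + cfg.co_bond])
        constraints.append((i_c, i_c + 1, cfg.co_bond))
        ligands["CO"] = [i_c, i_c + 1]

    def add_o2(paired: bool):
        i_o2 = len(species)
        species.extend(["O2", "O1"])
        theta = np.deg2rad(cfg.o2_tilt_deg)
        if not paired:
            p2 = np.array([0.0, 0.0, cfg.fe_o2_start])
            # Fe-O2-O1 angle: O2->Fe points along -z; O1 tilts between two
            # heme nitrogens (azimuth 45 deg), the sterically relaxed pose
            c45 = np.sqrt(0.5)
            d = np.array([np.sin(theta) * c45, np.sin(theta) * c45, -np.cos(theta)])
        else:
            pol = np.deg2rad(cfg.o2_polar_deg_paired)
            az = np.deg2rad(cfg.o2_azimuth_deg_paired)
            p2 = cfg.fe_o2_start_paired * np.array(
                [np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az), np.cos(pol)]
            )
            e_r = _unit(p2)
            z = np.array([0.0, 0.0, 1.0])
            e_t = _unit(z - (z @ e_r) * e_r)  # tilt O1 upward, away from the plane
            d = -np.cos(theta) * e_r + np.sin(theta) * e_t
        p1 = p2 + cfg.o2_bond * d
        pos.append(p2.tolist())
        pos.append(p1.tolist())
        constraints.append((i_o2, i_o2 + 1, cfg.o2_bond))
        ligands["O2"] = [i_o2, i_o2 + 1]

    if ligand in ("CO", "CO+O2"):
        add_co()
    if ligand in ("O2", "CO+O2"):
        add_o2(paired=(ligand == "CO+O2"))

    positions = np.array(pos, dtype=float)
    masses = np.array([SPECIES_MASSES[s] for s in species])
    mobile = np.zeros(len(species), dtype=bool)
    for idx in ligands.values():
        mobile[idx] = True

    cx = ReducedComplex(
        positions=positions,
        species=species,
        masses=masses,
        mobile_mask=mobile,
        plane_normal=np.array([0.0, 0.0, 1.0]),
        constraints=constraints,
        ligands=ligands,
    )
    if "O2" in cx.ligands:
        i_o2, i_o1 = cx.ligands["O2"]
        d2 = np.linalg.norm(cx.positions[i_o2])
        d1 = np.linalg.norm(cx.positions[i_o1])
        if d2 > d1 + 1e-9:
            raise ValueError("construction violated Fe-O2 <= Fe-O1")
    return cx


def synthesize_ground_truth_curve(
    params: LJPairParams | list[LJPairParams],
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    background=None,
) -> PotentialCurve:
    """Synthetic ground-truth energy table U(r) on a distance grid.

    ``params`` may be a single pair or a list whose energies are summed at
    the same separation.  ``background`` is an optional smooth callable
    added to U; Gaussian noise of standard deviation ``noise_sd`` kcal/mol
    is added reproducibly from ``seed``.  Default grid: 1.75–2.95 Å at
    0.1 Å, the fitting window of the parametrization workflow.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if grid is None:
        grid = np.arange(1.75, 2.95 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    plist = params if isinstance(params, list) else [params]
    u = np.zeros_like(grid)
    for p in plist:
        u += lj_energy(p, grid)
    if background is not None:
        u = u + np.asarray(background(grid), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        u = u + rng.normal(0.0, noise_sd, size=grid.shape)
    return PotentialCurve(r=grid, U=u, label="ground-truth")


def measure_angle(
    positions: np.ndarray | ReducedComplex,
    i_fe: int | None = None,
    i_o2: int | None = None,
    i_o1: int | None = None,
) -> float:
    """Fe–O²–O¹ angle in degrees, vertex at O², in [0, 180].

    Accepts either a ReducedComplex (indices inferred from its O₂ ligand)
    or a raw (N, 3) position array with explicit indices.
    """
    if isinstance(positions, ReducedComplex):
        cx = positions
        if "O2" not in cx.ligands:
            raise ValueError("complex has no O2 ligand")
        i_fe = cx.fe_index
        i_o2, i_o1 = cx.ligands["O2"]
        positions = cx.positions
    positions = np.asarray(positions, dtype=float)
    a = positions[i_fe] - positions[i_o2]
    b = positions[i_o1] - positions[i_o2]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("coincident sites: angle undefined")
    c = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
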