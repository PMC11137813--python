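"""Nonbonded force field of the reduced complex.

Interaction content, deliberately minimal:

* pair-specific coordination LJ terms between Fe and the bond-forming /
  distal ligand atoms (the parameters the whole toolkit exists to produce);
* short-range purely repulsive (WCA, i.e. cut-and-shifted LJ) sterics
  between ligand atoms of different ligands, between ligand atoms and the
  heme/imidazole nitrogens, and between Fe and the CO oxygen — these
  transmit the CO–O₂ competition and keep ligands on the bonding side of
  the heme plane;
* CHARMM-style switching between ``r_on`` and ``r_off`` applied to every
  nonbonded pair (inconsequential at this system size but honoured).

No electrostatics, no bonded terms beyond the rigid diatomic constraints
held by the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potentials import (
    LJPairParams,
    switching_derivative,
    switching_factor,
)
from .reduced_model import ReducedComplex

__all__ = ["TABLE_PARAMS", "ForceFieldConfig", "ForceField", "build_forcefield"]

#: The published two-site parameter set used as the package's reference
#: coordination parameters (well depths signed negative, sigma-form Å).
TABLE_PARAMS: dict[tuple[str, str], LJPairParams] = {
    ("FE", "CC"): LJPairParams(-21.49, 1.79),
    ("FE", "O1"): LJPairParams(-4.37, 2.74),
    ("FE", "O2"): LJPairParams(-6.55, 1.90),
}


@dataclass(frozen=True)
class ForceFieldConfig:
    """Steric and cutoff settings.

    ``wca_sigma`` = 2.9 Å puts the heavy-atom steric contact at
    2^(1/6)·2.9 ≈ 3.26 Å, a standard C/N/O van-der-Waals contact;
    ``wca_epsilon`` = 0.05 kcal/mol is a typical heavy-atom well depth.
    """

    wca_epsilon: float = 0.05
    wca_sigma: float = 2.9
    r_on: float = 8.0
    r_off: float = 10.0
    #: hard floor under which a pair distance is treated as an overlap
    overlap_floor: float = 0.4


_LIGAND_SPECIES = ("CC", "OC", "O1", "O2")
_FRAME_SPECIES = ("NH", "NI")


class ForceField:
    """Vectorized pair-term evaluator bound to one complex topology."""

    def __init__(
        self,
        cx: ReducedComplex,
        pair_params: dict[tuple[str, str], LJPairParams] | None = None,
        config: ForceFieldConfig | None = None,
    ):
        self.config = config or ForceFieldConfig()
        self.pair_params = dict(TABLE_PARAMS if pair_params is None else pair_params)
        self.n_sites = cx.n_sites
        ii, jj, eps4, sig, wca = [], [], [], [], []

        by_species: dict[str, list[int]] = {}
        for k, s in enumerate(cx.species):
            by_species.setdefault(s, []).append(k)

        # coordination LJ pairs (epsilon == 0 encodes a zeroed pair)
        for (sa, sb), p in self.pair_params.items():
            if not p.is_active():
                continue
            for a in by_species.get(sa, []):
                for b in by_species.get(sb, []):
                    ii.append(a)
                    jj.append(b)
                    eps4.append(4.0 * p.eps_abs)
                    sig.append(p.sigma_form)
                    wca.append(False)

        def add_wca(a, b):
            ii.append(a)
            jj.append(b)
            eps4.append(4.0 * self.config.wca_epsilon)
            sig.append(self.config.wca_sigma)
            wca.append(True)

        ligand_sets = list(cx.ligands.values())
        # cross-ligand sterics
        for m in range(len(ligand_sets)):
            for n in range(m + 1, len(ligand_sets)):
                for a in ligand_sets[m]:
                    for b in ligand_sets[n]:
                        add_wca(a, b)
        # ligand vs heme/imidazole nitrogens
        frame_idx = [k for k, s in enumerate(cx.species) if s in _FRAME_SPECIES]
        for lig in ligand_sets:
            for a in lig:
                for b in frame_idx:
                    add_wca(a, b)
        # Fe core vs the CO oxygen (no coordination term of its own)
        if "CO" in cx.ligands:
            add_wca(cx.fe_index, cx.ligands["CO"][1])

        self.I = np.asarray(ii, dtype=int)
        self.J = np.asarray(jj, dtype=int)
        self.eps4 = np.asarray(eps4, dtype=float)
        self.sig = np.asarray(sig, dtype=float)
        self.wca = np.asarray(wca, dtype=bool)
        # WCA: cut and shifted at the LJ minimum -> purely repulsive
        self.rc = np.where(self.wca, 2.0 ** (1.0 / 6.0) * self.sig, np.inf)
        self.shift = np.where(self.wca, self.eps4 / 4.0, 0.0)

    def energy_forces(self, x: np.ndarray, t_ns: float = 0.0):
        """Total energy (kcal/mol) and per-site forces (kcal/mol/Å)."""
        d = x[self.J] - x[self.I]
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        if np.any(r < self.config.overlap_floor):
            raise FloatingPointError("site overlap below the hard floor")
        s2 = (self.sig * self.sig) / r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        u = self.eps4 * (s12 - s6) + self.shift
        f = 6.0 * self.eps4 * (2.0 * s12 - s6) / r  # radial force, + = repulsive
        cut = r >= self.rc
        u = np.where(cut, 0.0, u)
        f = np.where(cut, 0.0, f)
        # switching (identity below r_on)
        if np.any(r > self.config.r_on):
            s = switching_factor(r, self.config.r_on, self.config.r_off)
            ds = switching_derivative(r, self.config.r_on, self.config.r_off)
            f = s * f - ds * u
            u = s * u
        forces = np.zeros_like(x)
        fv = (f / r)[:, None] * d
        np.add.at(forces, self.J, fv)
        np.add.at(forces, self.I, -fv)
        return float(u.sum()), forces

    def energy(self, x: np.ndarray) -> float:
        return self.energy_forces(x)[0]


def build_forcefield(
    cx: ReducedComplex,
    pair_params: dict[tuple[str, str], LJPairParams] | None = None,
    config: ForceFieldConfig | None = None,
) -> ForceField:
    return ForceField(cx, pair_params, config)
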