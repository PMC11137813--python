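"""Readers and writers for every artifact the toolkit touches.

Formats: headered delimited curve tables (r, U, F with units in the
header), PDB coordinate files (fixed-width records, one MODEL per frame
for trajectories, via biotite), an NBFIX-style pair-parameter text
section, JSON run configurations validated against a schema, and a
human-readable bias-protocol emitter.  Every writer/reader pair is a
strict inverse on valid data.

Distances are Å throughout; PDB serials are 1-based while in-memory
arrays are 0-indexed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from pydantic import BaseModel, Field, ValidationError

from .curves import PotentialCurve
from .potentials import BiasSpec, LJConvention, LJPairParams
from .reduced_model import SPECIES_MASSES, ReducedComplex

__all__ = [
    "write_curve",
    "read_curve",
    "write_nbfix",
    "read_nbfix",
    "write_pdb",
    "read_pdb",
    "RunConfig",
    "read_config",
    "write_bias_protocol",
]

_CURVE_HEADER = {"r": "r[A]", "U": "U[kcal/mol]", "F": "F[kcal/mol/A]"}


def write_curve(curve: PotentialCurve, path) -> None:
    """Write a curve as delimited text with a units header."""
    cols = [("r", curve.r)]
    if curve.U is not None:
        cols.append(("U", curve.U))
    if curve.F is not None:
        cols.append(("F", curve.F))
    header = " ".join(_CURVE_HEADER[name] for name, _ in cols)
    if curve.label:
        header += f"  label={curve.label}"
    np.savetxt(path, np.column_stack([v for _, v in cols]), header=header, fmt="%.12g")


def read_curve(path) -> PotentialCurve:
    """Read a curve table written by :func:`write_curve`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}:1: missing units header")
    tokens = first[1:].split()
    label = ""
    names = []
    for tok in tokens:
        if tok.startswith("label="):
            label = tok[len("label=") :]
            continue
        matches = [k for k, v in _CURVE_HEADER.items() if v == tok]
        if not matches:
            raise ValueError(f"{path}:1: unrecognized column/unit {tok!r}")
        names.append(matches[0])
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != len(names):
        raise ValueError(f"{path}:2: expected {len(names)} columns, found {data.shape[1]}")
    kw = {name: data[:, k] for k, name in enumerate(names)}
    r = kw.pop("r", None)
    if r is None:
        raise ValueError(f"{path}:1: no distance column")
    return PotentialCurve(r=r, U=kw.get("U"), F=kw.get("F"), label=label)


def write_nbfix(
    pairs: list[tuple[tuple[str, str], LJPairParams]],
    path_or_stream,
    convention: str = "as-printed",
) -> None:
    """Emit an NBFIX-style pair-parameter section.

    ``convention="as-printed"`` writes ε (signed as stored) and the σ-form
    length parameter; ``convention="rmin"`` converts the length to
    R_min = 2^(1/6) σ.  A header comment records the convention so the
    reader can invert it.  Duplicate pair labels are an error.
    """
    if convention not in ("as-printed", "rmin"):
        raise ValueError(f"unknown convention {convention!r}")
    labels = [p[0] for p in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate pair labels")
    lines = [
        "* pair-specific LJ parameters (NBFIX-style)",
        f"* convention: {convention}"
        + (" (epsilon kcal/mol, sigma A)" if convention == "as-printed" else " (epsilon kcal/mol, Rmin A)"),
        "NBFIX",
    ]
    for (a, b), p in pairs:
        length = p.sigma_form if convention == "as-printed" else p.sigma_form * 2 ** (1 / 6)
        lines.append(f"{a:<6s} {b:<6s} {p.epsilon:>12.6f} {length:>12.6f}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        Path(path_or_stream).write_text(text)


def read_nbfix(path_or_stream) -> list[tuple[tuple[str, str], LJPairParams]]:
    """Parse an NBFIX-style section back to (labels, parameters)."""
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        text = Path(path_or_stream).read_text()
    convention = "as-printed"
    pairs = []
    in_section = False
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("*"):
            if "convention:" in line:
                convention = line.split("convention:")[1].split()[0].strip()
            continue
        if line == "NBFIX":
            in_section = True
            continue
        if line == "END":
            break
        if not in_section or not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"line {ln}: expected 'A B epsilon length'")
        a, b, eps, length = parts[0], parts[1], float(parts[2]), float(parts[3])
        sigma = float(length) if convention == "as-printed" else float(length) / 2 ** (1 / 6)
        pairs.append(((a, b), LJPairParams(eps, sigma)))
    return pairs


_ELEMENT = {"FE": "FE", "NH": "N", "NI": "N", "CC": "C", "OC": "O", "O1": "O", "O2": "O"}


def _to_atoms(cx: ReducedComplex, coord: np.ndarray) -> AtomArray:
    n = cx.n_sites
    arr = AtomArray(n)
    arr.coord = np.asarray(coord, dtype=np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.ones(n, dtype=int)
    arr.res_name = np.array(["HGL"] * n)
    arr.atom_name = np.array(cx.species)
    arr.element = np.array([_ELEMENT[s] for s in cx.species])
    arr.hetero = np.ones(n, dtype=bool)
    return arr


def write_pdb(cx: ReducedComplex, path, frames: np.ndarray | None = None) -> None:
    """Write the complex (or a trajectory, one MODEL per frame) as PDB."""
    f = PDBFile()
    if frames is None:
        f.set_structure(_to_atoms(cx, cx.positions))
    else:
        frames = np.asarray(frames, float)
        stack = AtomArrayStack(frames.shape[0], cx.n_sites)
        template = _to_atoms(cx, cx.positions)
        for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = frames.astype(np.float32)
        f.set_structure(stack)
    f.write(str(path))


def read_pdb(path) -> ReducedComplex | tuple[ReducedComplex, np.ndarray]:
    """Read a complex (and trajectory frames, if multi-MODEL) from PDB.

    Species are recovered from atom names; rigid-bond lengths are
    remeasured from the first model's geometry.  A file without an Fe
    record fails validation.
    """
    f = PDBFile.read(str(path))
    stack = f.get_structure()
    first = stack[0]
    species = [str(s) for s in first.atom_name]
    if "FE" not in species:
        raise ValueError("PDB is missing the required Fe site record")
    unknown = [s for s in species if s not in SPECIES_MASSES]
    if unknown:
        raise ValueError(f"unrecognized site labels in PDB: {unknown}")
    positions = np.asarray(first.coord, dtype=float)
    ligands: dict[str, list[int]] = {}
    if "CC" in species:
        ligands["CO"] = [species.index("CC"), species.index("OC")]
    if "O2" in species:
        ligands["O2"] = [species.index("O2"), species.index("O1")]
    constraints = []
    for idx in ligands.values():
        i, j = idx
        constraints.append((i, j, float(np.linalg.norm(positions[j] - positions[i]))))
    mobile = np.zeros(len(species), dtype=bool)
    for idx in ligands.values():
        mobile[idx] = True
    cx = ReducedComplex(
        positions=positions,
        species=species,
        masses=np.array([SPECIES_MASSES[s] for s in species]),
        mobile_mask=mobile,
        plane_normal=np.array([0.0, 0.0, 1.0]),
        constraints=constraints,
        ligands=ligands,
    )
    if stack.stack_depth() > 1:
        return cx, np.asarray(stack.coord, dtype=float)
    return cx


class RunConfig(BaseModel):
    """Validated JSON run configuration shared by all pipeline stages."""

    seed: int = 0
    temperature: float = Field(300.0, gt=0)
    o2_kappa: float = Field(0.0, ge=0)
    o2_kappas: list[float] = Field(default_factory=lambda: [0.0, 1.0, 3.0, 5.0, 10.0])
    n_replicates: int = Field(5, ge=1)
    rate_scale: float = Field(50.0, gt=0)
    relax_ps: float = Field(20.0, gt=0)
    n_database: int = Field(12000, gt=0)
    epochs: int = Field(2001, ge=1)
    learning_rate: float = Field(5e-4, gt=0)
    metad_duration_ps: float = Field(500.0, gt=0)
    metad_gamma: float = Field(10.0, gt=1)
    wca_epsilon: float = Field(0.05, ge=0)
    wca_sigma: float = Field(2.9, gt=0)

    model_config = {"extra": "forbid"}


def read_config(path) -> RunConfig:
    """Read and validate a JSON run configuration."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return RunConfig(**data)
    except ValidationError as err:
        raise ValueError(f"invalid run configuration {path}: {err}") from err


def write_bias_protocol(biases: list[tuple[str, BiasSpec]], path) -> None:
    """Human-readable protocol file listing the configured bias terms."""
    lines = ["# bias protocol (distances in A, stiffness kcal/mol/A^2, rates A/ns)"]
    for cv_name, spec in biases:
        fields = [f"cv={cv_name}", f"kind={spec.kind.value}", f"kappa={spec.kappa:g}"]
        if spec.kind.value in ("harmonic", "moving-harmonic"):
            fields.append(f"r0={spec.r0:g}")
        if spec.rate is not None:
            fields.append(f"rate={spec.rate:g}")
        if spec.ceiling is not None:
            fields.append(f"ceiling={spec.ceiling:g}")
        lines.append("  ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
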