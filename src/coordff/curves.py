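"""The tabulated potential/force curve container used throughout the
package: aligned grids of distance r (Å), energy U (kcal/mol) and force F
(kcal/mol/Å), with a provenance label (ground-truth | baseline |
coordination | model)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PotentialCurve"]


@dataclass
class PotentialCurve:
    r: np.ndarray
    U: np.ndarray | None = None
    F: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1 or self.r.size == 0:
            raise ValueError("r must be a non-empty 1-D grid")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        for name in ("U", "F"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.r.shape:
                    raise ValueError(f"{name} must match the r grid length")
                setattr(self, name, v)

    def window(self, r_lo: float, r_hi: float) -> "PotentialCurve":
        """Sub-curve restricted to r_lo ≤ r ≤ r_hi (inclusive)."""
        m = (self.r >= r_lo - 1e-12) & (self.r <= r_hi + 1e-12)
        return PotentialCurve(
            r=self.r[m],
            U=None if self.U is None else self.U[m],
            F=None if self.F is None else self.F[m],
            label=self.label,
        )

    def zero_baseline_like(self) -> "PotentialCurve":
        """A zero curve on the same grid (the default baseline)."""
        z = np.zeros_like(self.r)
        return PotentialCurve(r=self.r.copy(), U=z.copy(), F=z.copy(), label="baseline")
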