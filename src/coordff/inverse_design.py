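"""Two-site O₂ parameter construction by neural-network inverse design.

The proximal (O²) and distal (O¹) oxygens of the O₂ ligand carry distinct
pair parameters against Fe.  A database of candidate parameter quadruples
(ε₁, σ₁, ε₂, σ₂) is sampled uniformly inside the constrained region

    8 < ε₁+ε₂ < 12 kcal/mol,  0.3 < ε₁/ε₂ < 0.6,
    2.5 < σ₁ < 3 Å,           1.8 < σ₂ < 2.05 Å,

(ε magnitudes during sampling; the stored sign convention is applied at
the physics boundary).  Each record is reduced to three features:

* the equilibrium mean Fe–O²–O¹ angle of the FePI(O₂) complex at 300 K,
* the effective single-LJ parameters (ε_f, σ_f) fitted to the total
  energy-scan force curve over the standard window.

A feedforward network (3 → 64 → 64 → 64 → 4, ReLU, adam, learning rate
5e-4, 2001 epochs, MSE loss) learns features → parameters; feeding it the
features measured for a *target* interaction inverts them into a
parameter quadruple.

Featurization engines
---------------------
``mode="scan"`` (default, reduced cost): the angle feature is the
Boltzmann average of the rigid-rotor (r, θ) configuration integral of the
O₂ above the fixed heme — the same distribution the Langevin engine
samples — evaluated by quadrature; (ε_f, σ_f) come from a deterministic
energy scan.  ``mode="md"`` runs the actual 20 ps / 100-snapshot Langevin
protocol per record; it is the full-fidelity route and is cross-checked
against the quadrature in the test suite.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor

from .coordination_fit import fit_lj_to_force
from .curves import PotentialCurve
from .dynamics import energy_scan, run_langevin
from .forcefield import ForceFieldConfig, build_forcefield
from .potentials import KB_KCAL, LJPairParams, finite_difference_force, lj_energy
from .reduced_model import GeometryConfig, build_complex

__all__ = [
    "RANGES",
    "ParamRecord",
    "FeatureVector",
    "ReducedModelFeaturizer",
    "FNNModel",
    "sample_database",
    "featurize_record",
    "featurize_database",
    "train_fnn",
    "invert_features",
]

#: Sampling-region constraints (ε as magnitudes, kcal/mol; σ in Å).
RANGES = {
    "eps_sum": (8.0, 12.0),
    "eps_ratio": (0.3, 0.6),
    "sigma1": (2.5, 3.0),
    "sigma2": (1.8, 2.05),
}

FEATURE_NAMES = ["mean_angle", "eps_f", "sig_f"]
TARGET_NAMES = ["eps1", "sig1", "eps2", "sig2"]


@dataclass(frozen=True)
class FeatureVector:
    """The three features of one parameter quadruple."""

    mean_angle: float  # degrees, Fe-O2-O1 equilibrium mean
    eps_f: float  # kcal/mol, effective single-LJ depth (signed negative)
    sig_f: float  # Å, effective single-LJ length

    def __post_init__(self):
        if not 0.0 < self.mean_angle < 180.0:
            raise ValueError("mean angle must lie in (0, 180) degrees")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_angle, self.eps_f, self.sig_f])


@dataclass(frozen=True)
class ParamRecord:
    """One database row: parameter magnitudes, optionally featurized."""

    eps1: float
    sig1: float
    eps2: float
    sig2: float
    features: FeatureVector | None = None

    def in_ranges(self) -> bool:
        lo, hi = RANGES["eps_sum"]
        ok = lo < self.eps1 + self.eps2 < hi
        lo, hi = RANGES["eps_ratio"]
        ok &= lo < self.eps1 / self.eps2 < hi
        lo, hi = RANGES["sigma1"]
        ok &= lo < self.sig1 < hi
        lo, hi = RANGES["sigma2"]
        ok &= lo < self.sig2 < hi
        return bool(ok)

    def pair_params(self) -> dict:
        """Signed physics-side parameters for the two Fe–O pairs."""
        return {
            ("FE", "O1"): LJPairParams(-self.eps1, self.sig1),
            ("FE", "O2"): LJPairParams(-self.eps2, self.sig2),
        }


def sample_database(n_total: int = 12000, seed: int = 0) -> pd.DataFrame:
    """Uniform rejection sampling of the constrained parameter region.

    Returns a DataFrame with columns eps1, sig1, eps2, sig2 (magnitudes);
    every row satisfies all four range constraints.  Seeded and exactly
    reproducible.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rng = np.random.default_rng(seed)
    lo_s, hi_s = RANGES["eps_sum"]
    lo_q, hi_q = RANGES["eps_ratio"]
    rows = []
    # bounding box for (eps1, eps2): eps2 <= hi_s/(1+lo_q), eps1 <= hi_s*hi_q/(1+hi_q)
    e1_hi = hi_s * hi_q / (1.0 + hi_q)
    e2_hi = hi_s / (1.0 + lo_q)
    while len(rows) < n_total:
        m = (n_total - len(rows)) * 4 + 64
        e1 = rng.uniform(0.0, e1_hi, m)
        e2 = rng.uniform(0.0, e2_hi, m)
        s1 = rng.uniform(*RANGES["sigma1"], m)
        s2 = rng.uniform(*RANGES["sigma2"], m)
        s = e1 + e2
        q = np.divide(e1, e2, out=np.full(m, np.inf), where=e2 > 0)
        keep = (lo_s < s) & (s < hi_s) & (lo_q < q) & (q < hi_q)
        rows.extend(np.column_stack([e1, s1, e2, s2])[keep])
    arr = np.asarray(rows[:n_total])
    return pd.DataFrame(arr, columns=TARGET_NAMES)


class ReducedModelFeaturizer:
    """Computes the three features of a parameter quadruple on the
    reduced FePI(O₂) model.

    The steric background of the complex (everything except the two Fe–O
    coordination terms) is precomputed once; per record only the two LJ
    terms change.  See the module docstring for the two modes.
    """

    def __init__(
        self,
        geometry: GeometryConfig | None = None,
        ff_config: ForceFieldConfig | None = None,
        temperature: float = 300.0,
        scan_grid: np.ndarray | None = None,
        quad_r: tuple[float, float, int] = (1.70, 3.50, 91),
        quad_theta: tuple[float, float, int] = (5.0, 175.0, 86),
    ):
        self.geometry = geometry or GeometryConfig()
        self.ff_config = ff_config or ForceFieldConfig()
        self.temperature = temperature
        self.beta = 1.0 / (KB_KCAL * temperature)
        self.scan_grid = (
            np.arange(1.75, 2.95 + 1e-9, 0.1) if scan_grid is None else np.asarray(scan_grid)
        )
        self.o2_bond = self.geometry.o2_bond

        # steric-only background along the axial scan (both LJ pairs zeroed)
        cx0 = build_complex("O2", self.geometry)
        zeroed = {
            ("FE", "O1"): LJPairParams(0.0, 1.0),
            ("FE", "O2"): LJPairParams(0.0, 1.0),
        }
        ff0 = build_forcefield(cx0, zeroed, self.ff_config)
        self._w_scan = energy_scan(cx0, ff0, self.scan_grid).U

        # quadrature grids for the Boltzmann mean angle
        r = np.linspace(*quad_r)
        th = np.deg2rad(np.linspace(*quad_theta))
        self._q_r = r
        self._q_th_deg = np.rad2deg(th)
        # Fe-O1 distance for every (r, theta): law of cosines at the O2 vertex
        L = self.o2_bond
        self._q_d1 = np.sqrt(
            r[:, None] ** 2 + L * L - 2.0 * r[:, None] * L * np.cos(th)[None, :]
        )
        self._q_w_geom = (r * r)[:, None] * np.sin(th)[None, :]
        # proximal-atom steric background along the axis (covers the whole
        # quadrature range, not just the fit window)
        wide_grid = np.linspace(quad_r[0], quad_r[1], 60)
        wide = energy_scan(cx0, ff0, wide_grid).U
        self._q_wr = np.interp(r, wide_grid, wide)
        # distal-atom steric background on the (r, theta) grid: O2 on the
        # axis, O1 tilted between two heme nitrogens (azimuth 45 deg)
        c45 = np.sqrt(0.5)
        sin_t, cos_t = np.sin(th)[None, :], np.cos(th)[None, :]
        o1 = np.empty(self._q_d1.shape + (3,))
        o1[..., 0] = L * sin_t * c45
        o1[..., 1] = L * sin_t * c45
        o1[..., 2] = r[:, None] - L * cos_t
        frame_sites = [
            cx0.positions[k] for k, s in enumerate(cx0.species) if s in ("NH", "NI")
        ]
        eps_w, sig_w = self.ff_config.wca_epsilon, self.ff_config.wca_sigma
        rc = 2.0 ** (1.0 / 6.0) * sig_w
        w1 = np.zeros(self._q_d1.shape)
        if eps_w > 0:
            for site in frame_sites:
                d = np.linalg.norm(o1 - site[None, None, :], axis=-1)
                s6 = (sig_w / d) ** 6
                u = 4.0 * eps_w * (s6 * s6 - s6) + eps_w
                w1 += np.where(d < rc, u, 0.0)
        self._q_w1 = w1

    # -- features ----------------------------------------------------------
    def _config_energy(self, eps1, sig1, eps2, sig2) -> np.ndarray:
        """Energy of the rigid O2 on the (r, theta) quadrature grid."""
        p2 = LJPairParams(-abs(eps2), sig2)
        u = lj_energy(p2, self._q_r)[:, None] + self._q_wr[:, None] + self._q_w1
        if abs(eps1) > 0:
            u = u + lj_energy(LJPairParams(-abs(eps1), sig1), self._q_d1)
        return u

    def mean_angle(self, eps1: float, sig1: float, eps2: float, sig2: float) -> float:
        """Boltzmann-average Fe–O²–O¹ angle (degrees) by quadrature."""
        u = self._config_energy(eps1, sig1, eps2, sig2)
        u = u - u.min()
        w = self._q_w_geom * np.exp(-self.beta * u)
        return float(np.sum(w * self._q_th_deg[None, :]) / np.sum(w))

    def relaxed_tilt(self, eps1: float, sig1: float, eps2: float, sig2: float) -> float:
        """Minimum-energy Fe–O²–O¹ angle (degrees) — the tilt of the
        relaxed geometry that the energy scan rigidly translates."""
        u = self._config_energy(eps1, sig1, eps2, sig2)
        _, jt = np.unravel_index(int(np.argmin(u)), u.shape)
        return float(self._q_th_deg[jt])

    def scan_features(
        self, eps1: float, sig1: float, eps2: float, sig2: float, tilt_deg: float
    ) -> tuple[float, float, bool]:
        """(ε_f, σ_f, converged) from the energy scan at a fixed tilt."""
        geo = GeometryConfig(
            **{
                **self.geometry.__dict__,
                "o2_tilt_deg": float(np.clip(tilt_deg, 1.0, 179.0)),
            }
        )
        cx = build_complex("O2", geo)
        ff = build_forcefield(
            cx,
            {
                ("FE", "O1"): LJPairParams(-abs(eps1), sig1),
                ("FE", "O2"): LJPairParams(-abs(eps2), sig2),
            },
            self.ff_config,
        )
        u_curve = energy_scan(cx, ff, self.scan_grid)
        f_curve = finite_difference_force(u_curve)
        # single informed start: scan minimum locates the effective sigma
        s0 = max(1.0, u_curve.r[int(np.argmin(u_curve.U))] / 2.0 ** (1.0 / 6.0))
        res = fit_lj_to_force(f_curve, model="fd", sigma_starts=(s0, 2.2))
        return res.epsilon, res.sigma, res.converged

    def features(self, eps1, sig1, eps2, sig2) -> tuple[FeatureVector, bool]:
        ang = self.mean_angle(eps1, sig1, eps2, sig2)
        tilt = self.relaxed_tilt(eps1, sig1, eps2, sig2)
        ef, sf, ok = self.scan_features(eps1, sig1, eps2, sig2, tilt)
        return FeatureVector(mean_angle=ang, eps_f=ef, sig_f=sf), ok

    def features_md(
        self,
        eps1,
        sig1,
        eps2,
        sig2,
        seed: int = 0,
        duration_ps: float = 20.0,
        n_samples: int = 100,
    ) -> tuple[FeatureVector, bool]:
        """Full-fidelity route: the angle is the mean over a Langevin run
        (duration/snapshot protocol as configured), the scan features as in
        ``features`` but at that measured tilt."""
        cx = build_complex("O2", self.geometry)
        ff = build_forcefield(
            cx,
            {
                ("FE", "O1"): LJPairParams(-abs(eps1), sig1),
                ("FE", "O2"): LJPairParams(-abs(eps2), sig2),
            },
            self.ff_config,
        )
        _, stats = run_langevin(
            cx,
            ff,
            duration_ps=duration_ps,
            temperature=self.temperature,
            seed=seed,
            n_samples=n_samples,
        )
        ang = stats.means["angle_FeO2O1"]
        tilt = self.relaxed_tilt(eps1, sig1, eps2, sig2)
        ef, sf, ok = self.scan_features(eps1, sig1, eps2, sig2, tilt)
        return FeatureVector(mean_angle=ang, eps_f=ef, sig_f=sf), ok


def featurize_record(
    record: ParamRecord | tuple,
    featurizer: ReducedModelFeaturizer | None = None,
    mode: str = "scan",
    seed: int = 0,
) -> FeatureVector:
    """Features of a single parameter quadruple (magnitudes)."""
    fz = featurizer or ReducedModelFeaturizer()
    if isinstance(record, ParamRecord):
        vals = (record.eps1, record.sig1, record.eps2, record.sig2)
    else:
        vals = tuple(record)
    if mode == "scan":
        fv, ok = fz.features(*vals)
    elif mode == "md":
        fv, ok = fz.features_md(*vals, seed=seed)
    else:
        raise ValueError(f"unknown featurization mode {mode!r}")
    if not ok:
        raise RuntimeError("effective-LJ fit did not converge for this record")
    return fv


def featurize_database(
    df: pd.DataFrame,
    featurizer: ReducedModelFeaturizer | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Append the three feature columns to a sampled database.

    Records whose effective-LJ fit does not converge are excluded; the
    count of exclusions is stored in ``df.attrs['n_excluded']``.
    """
    fz = featurizer or ReducedModelFeaturizer()
    feats = np.empty((len(df), 3))
    keep = np.ones(len(df), dtype=bool)
    for k, row in enumerate(df.itertuples(index=False)):
        try:
            fv, ok = fz.features(row.eps1, row.sig1, row.eps2, row.sig2)
        except Exception:
            ok = False
        if not ok:
            keep[k] = False
            continue
        feats[k] = fv.as_array()
    out = df.loc[keep].reset_index(drop=True).copy()
    out[FEATURE_NAMES] = feats[keep]
    out.attrs["n_excluded"] = int((~keep).sum())
    if verbose and out.attrs["n_excluded"]:
        print(f"featurize_database: excluded {out.attrs['n_excluded']} non-converged records")
    return out


# --------------------------------------------------------------------------
# the feedforward network
# --------------------------------------------------------------------------


@dataclass
class FNNModel:
    """Trained network with its normalization statistics and diagnostics."""

    mlp: MLPRegressor
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    feature_min: np.ndarray
    feature_max: np.ndarray
    rmse_train: dict[str, float]
    rmse_test: dict[str, float]
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    target_names: list[str] = field(default_factory=lambda: list(TARGET_NAMES))

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.x_mean) / self.x_std
        y = self.mlp.predict(x)
        return y * self.y_std + self.y_mean

    def is_extrapolation(self, features: np.ndarray) -> bool:
        f = np.asarray(features, float).ravel()
        return bool(np.any(f < self.feature_min) or np.any(f > self.feature_max))

    def save(self, path) -> None:
        payload = {
            "architecture": list(self.mlp.hidden_layer_sizes),
            "activation": self.mlp.activation,
            "coefs": [w.tolist() for w in self.mlp.coefs_],
            "intercepts": [b.tolist() for b in self.mlp.intercepts_],
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "rmse_train": self.rmse_train,
            "rmse_test": self.rmse_test,
            "feature_names": self.feature_names,
            "target_names": self.target_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FNNModel":
        with open(path) as fh:
            p = json.load(fh)
        mlp = MLPRegressor(hidden_layer_sizes=tuple(p["architecture"]), activation=p["activation"])
        coefs = [np.asarray(w) for w in p["coefs"]]
        intercepts = [np.asarray(b) for b in p["intercepts"]]
        mlp.coefs_ = coefs
        mlp.intercepts_ = intercepts
        mlp.n_layers_ = len(coefs) + 1
        mlp.n_outputs_ = coefs[-1].shape[1]
        mlp.out_activation_ = "identity"
        mlp.n_features_in_ = coefs[0].shape[0]
        return cls(
            mlp=mlp,
            x_mean=np.asarray(p["x_mean"]),
            x_std=np.asarray(p["x_std"]),
            y_mean=np.asarray(p["y_mean"]),
            y_std=np.asarray(p["y_std"]),
            feature_min=np.asarray(p["feature_min"]),
            feature_max=np.asarray(p["feature_max"]),
            rmse_train=p["rmse_train"],
            rmse_test=p["rmse_test"],
            feature_names=p["feature_names"],
            target_names=p["target_names"],
        )


def train_fnn(
    df: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    epochs: int = 2001,
    learning_rate: float = 5e-4,
    hidden: tuple[int, ...] = (64, 64, 64),
    batch_size: int = 200,
) -> FNNModel:
    """Train the features → parameters network on a featurized database.

    80/20 split (9,600 / 2,400 at the full database size), z-scored
    features and targets, ReLU hidden layers, adam at the stated learning
    rate for the stated number of epochs, MSE loss.  Returns the model
    with per-output RMSEs (original units) on both partitions.
    """
    for col in FEATURE_NAMES:
        if col not in df.columns:
            raise ValueError("database is not featurized")
    x = df[FEATURE_NAMES].to_numpy()
    y = df[TARGET_NAMES].to_numpy()
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed % 2**31, shuffle=True
    )
    x_mean, x_std = x_tr.mean(axis=0), x_tr.std(axis=0)
    y_mean, y_std = y_tr.mean(axis=0), y_tr.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_std = np.where(y_std > 0, y_std, 1.0)
    xs, ys = (x_tr - x_mean) / x_std, (y_tr - y_mean) / y_std
    mlp = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(batch_size, len(xs)),
        learning_rate_init=learning_rate,
        max_iter=epochs,
        shuffle=True,
        random_state=seed % 2**31,
        tol=0.0,
        n_iter_no_change=epochs + 1,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(xs, ys)
    if not np.all(np.isfinite(mlp.loss_curve_)):
        raise RuntimeError("training loss diverged (NaN/inf)")

    def rmse(xa, ya):
        pred = mlp.predict((xa - x_mean) / x_std) * y_std + y_mean
        return {
            name: float(np.sqrt(np.mean((pred[:, k] - ya[:, k]) ** 2)))
            for k, name in enumerate(TARGET_NAMES)
        }

    return FNNModel(
        mlp=mlp,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        feature_min=x_tr.min(axis=0),
        feature_max=x_tr.max(axis=0),
        rmse_train=rmse(x_tr, y_tr),
        rmse_test=rmse(x_te, y_te),
    )


@dataclass
class InversionResult:
    """Parameter quadruple returned by the trained network."""

    eps1: float  # magnitudes, kcal/mol
    sig1: float
    eps2: float
    sig2: float
    extrapolated: bool

    def pair_params(self) -> dict:
        return {
            ("FE", "O1"): LJPairParams(-self.eps1, self.sig1),
            ("FE", "O2"): LJPairParams(-self.eps2, self.sig2),
        }


def invert_features(model: FNNModel, target: FeatureVector | np.ndarray) -> InversionResult:
    """Single forward pass mapping target features to (ε₁, σ₁, ε₂, σ₂).

    Flags extrapolation when the target lies outside the training feature
    hull (axis-aligned bounding box)."""
    f = target.as_array() if isinstance(target, FeatureVector) else np.asarray(target, float)
    if not np.all(np.isfinite(f)):
        raise ValueError("target features must be finite")
    y = model.predict(f).ravel()
    return InversionResult(
        eps1=float(y[0]),
        sig1=float(y[1]),
        eps2=float(y[2]),
        sig2=float(y[3]),
        extrapolated=model.is_extrapolation(f),
    )
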