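"""Steered pulling, well-tempered metadynamics and free-energy analysis."""

import numpy as np
import pytest

from coordff import (
    KB_KCAL,
    FreeEnergySurface,
    LJPairParams,
    WellTemperedMetadBias,
    approach_pattern,
    build_complex,
    build_forcefield,
    lj_energy,
    lj_max_attractive_force,
    reconstruct_fes,
    relax_system,
    run_smd,
    run_wt_metad,
    slice_effective_bond_energy,
)
from coordff.biased_sampling import HillsLog
from coordff.engine import CallableTerm, CoordinateCV, Engine
from coordff.forcefield import ForceFieldConfig
from coordff.reduced_model import GeometryConfig

NO_STERICS = ForceFieldConfig(wca_epsilon=0.0)


class TestRelax:
    def test_wall_penetration_bounded(self):
        """Fe-C never exceeds the relaxation ceiling by much more than the
        thermal penetration depth sqrt(2 kT / kappa)."""
        cx = build_complex("CO")
        ff = build_forcefield(cx)
        fe, i_c = cx.fe_index, cx.ligands["CO"][0]
        state = relax_system(cx, ff, duration_ps=20.0, seed=3)
        # rerun while tracking the distance
        from coordff import run_langevin
        from coordff.potentials import BiasKind, BiasSpec

        traj, _ = run_langevin(
            cx,
            ff,
            biases=[(BiasSpec(BiasKind.UPPER_WALL, kappa=150.0, ceiling=1.89), (fe, i_c))],
            duration_ps=20.0,
            seed=3,
            n_samples=400,
        )
        depth = np.sqrt(2.0 * KB_KCAL * 300.0 / 150.0)
        assert traj["d_Fe_CO"].max() < 1.89 + 4.0 * depth

    def test_unrestrained_o2_diffuses_away(self):
        """o2_kappa = 0: a weakly bound O2 escapes past 5 A (no wall)."""
        cx = build_complex("O2", GeometryConfig(fe_o2_start=3.4))
        weak = {
            ("FE", "O1"): LJPairParams(-0.2, 2.74),
            ("FE", "O2"): LJPairParams(-0.3, 1.90),
        }
        ff = build_forcefield(cx, weak)
        state = relax_system(cx, ff, o2_kappa=0.0, duration_ps=150.0, seed=2)
        i_o2 = cx.ligands["O2"][0]
        assert np.linalg.norm(state.cx.positions[i_o2]) > 5.0

    def test_identical_seeds_identical_states(self):
        cx = build_complex("CO+O2")
        a = relax_system(cx, None, o2_kappa=3.0, duration_ps=5.0, seed=8)
        b = relax_system(cx, None, o2_kappa=3.0, duration_ps=5.0, seed=8)
        assert np.array_equal(a.cx.positions, b.cx.positions)

    def test_kappa_validation(self):
        with pytest.raises(ValueError):
            relax_system(build_complex("CO+O2"), None, o2_kappa=-1.0)
        with pytest.raises(ValueError):
            relax_system(build_complex("CO"), None, o2_kappa=3.0)


class TestSMD:
    def test_stiff_spring_peak_matches_analytic_maximum(self):
        """T -> 0, slow pull, pure pair term: the measured peak force is the
        maximum attractive LJ force of the Fe-C pair."""
        cx = build_complex("CO")
        ff = build_forcefield(cx, None, NO_STERICS)
        state = relax_system(cx, ff, duration_ps=5.0, temperature=0.0, seed=1)
        curve = run_smd(state, ff, rate_scale=10.0, temperature=0.0, smooth_ps=0.2)
        analytic = lj_max_attractive_force(LJPairParams(-21.49, 1.79))
        assert curve.peak_force == pytest.approx(analytic, rel=0.02)
        assert curve.ruptured

    def test_brittle_rupture_without_rebinding(self):
        """After the peak the pulling force relaxes toward the spring-only
        baseline with no second comparable peak (brittle bond)."""
        cx = build_complex("CO")
        ff = build_forcefield(cx)
        state = relax_system(cx, ff, duration_ps=10.0, seed=4)
        curve = run_smd(state, ff, rate_scale=50.0)
        # skip two smoothing windows past the peak, then require decay
        post = curve.force_smooth[curve.peak_index + 40 :]
        assert post.size > 20
        assert post.max() < 0.3 * curve.peak_force
        assert curve.force_smooth[-1] < 0.2 * curve.peak_force

    def test_no_co_rejected(self):
        cx = build_complex("O2")
        state = relax_system(cx, None, o2_kappa=1.0, duration_ps=1.0, seed=1)
        with pytest.raises(ValueError):
            run_smd(state, None)


class TestMetadynamics:
    def test_first_hill_height_is_initial_height(self):
        cx = build_complex("CO+O2")
        hills, _ = run_wt_metad(cx, None, duration_ps=10.0, seed=3)
        assert hills.heights[0] == pytest.approx(8.0)

    def test_hill_heights_decay_at_revisited_points(self):
        """Depositing repeatedly at the same CV point: heights strictly
        decrease (well-tempered definition)."""
        cv = CoordinateCV(0, 0)
        bias = WellTemperedMetadBias([cv], height0=2.0, width=0.2, gamma=5.0)
        x = np.zeros((1, 3))
        hs = [bias.deposit(x, float(t)) for t in range(6)]
        assert all(hs[k + 1] < hs[k] for k in range(5))

    def test_flat_landscape_long_run_bias_is_flat(self):
        """On a flat potential (confined by walls) the accumulated
        well-tempered bias becomes uniform over the interior."""

        def pot(x):
            f = np.zeros_like(x)
            # flat in x within [-2, 2], harmonic walls outside
            if x[0, 0] > 2.0:
                f[0, 0] = -20.0 * (x[0, 0] - 2.0)
            elif x[0, 0] < -2.0:
                f[0, 0] = -20.0 * (x[0, 0] + 2.0)
            f[0, 1] = -10 * x[0, 1]
            f[0, 2] = -10 * x[0, 2]
            return 0.0, f

        cv = CoordinateCV(0, 0)
        metad = WellTemperedMetadBias([cv], height0=0.4, width=0.15, gamma=6.0)
        eng = Engine(
            np.zeros((1, 3)),
            np.array([15.999]),
            np.array([True]),
            [CallableTerm(pot), metad],
            seed=6,
        )
        eng.run(150000, metad=metad, metad_every=200)
        grid, F = reconstruct_fes(metad.log(), x_grid=np.linspace(-1.6, 1.6, 81))
        assert F.max() - F.min() < 1.0  # flat within tolerance

    def test_double_well_barrier_recovered(self):
        """Analytic 1-D double well (barrier 3 kcal/mol): the reconstructed
        free energy matches within 0.5 kcal/mol RMS over the sampled range."""
        a, b = 3.0, 1.0

        def pot(x):
            f = np.zeros_like(x)
            f[0, 0] = -4 * a * x[0, 0] * (x[0, 0] ** 2 - b * b)
            f[0, 1] = -10 * x[0, 1]
            f[0, 2] = -10 * x[0, 2]
            return a * (x[0, 0] ** 2 - b * b) ** 2, f

        cv = CoordinateCV(0, 0)
        metad = WellTemperedMetadBias([cv], height0=0.3, width=0.1, gamma=8.0)
        eng = Engine(
            np.array([[1.0, 0.0, 0.0]]),
            np.array([15.999]),
            np.array([True]),
            [CallableTerm(pot), metad],
            seed=4,
        )
        eng.run(200000, metad=metad, metad_every=250)  # 400 ps, 1 hill / 0.5 ps
        grid = np.linspace(-1.25, 1.25, 126)
        _, F = reconstruct_fes(metad.log(), x_grid=grid)
        ana = a * (grid**2 - b * b) ** 2
        ana -= ana.min()
        diff = F - ana
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff**2)) < 0.5

    def test_single_hill_fes_is_scaled_gaussian_well(self):
        hills = HillsLog(
            times_ps=np.array([0.0]),
            centers=np.array([[2.0, 2.0]]),
            heights=np.array([4.0]),
            width=0.2,
            gamma=10.0,
            cv_names=["a", "b"],
        )
        fes = reconstruct_fes(hills, x_grid=np.linspace(1.5, 2.5, 51), y_grid=np.linspace(1.5, 2.5, 51))
        # well of depth (gamma/(gamma-1)) * h at the center, zero far away
        imin = np.unravel_index(np.argmin(fes.F + 0), fes.F.shape)
        assert fes.x[imin[0]] == pytest.approx(2.0, abs=0.02)
        assert fes.F.max() == pytest.approx(10.0 / 9.0 * 4.0, rel=0.01)

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            WellTemperedMetadBias([CoordinateCV(0, 0)], gamma=1.0)
        hills = HillsLog(
            times_ps=np.array([0.0]),
            centers=np.array([[2.0]]),
            heights=np.array([4.0]),
            width=0.2,
            gamma=10.0,
            cv_names=["a"],
        )
        with pytest.raises(ValueError):
            reconstruct_fes(hills, gamma=0.5)


def _lj_slice_surface():
    """Synthetic surface: pure 1-D LJ free energy along Fe-C, flat in Fe-O2."""
    x = np.linspace(1.6, 5.0, 200)
    y = np.linspace(1.6, 5.0, 30)
    p = LJPairParams(-5.0, 1.9)
    fx = lj_energy(p, x)
    F = np.tile(fx[:, None], (1, len(y)))
    return FreeEnergySurface(x=x, y=y, F=F - F.min(), gamma=10.0)


class TestSlices:
    def test_pure_lj_slice_gives_well_depth(self):
        """No barrier beyond the well: the effective bond energy is the
        well depth relative to the outer grid edge."""
        fes = _lj_slice_surface()
        se = slice_effective_bond_energy(fes, 3.0)
        assert not se.flagged
        p = LJPairParams(-5.0, 1.9)
        depth_to_edge = float(lj_energy(p, 5.0) - lj_energy(p, 2.0 ** (1 / 6) * 1.9))
        assert se.value == pytest.approx(depth_to_edge, rel=0.01)
        assert se.r_eq == pytest.approx(2.0 ** (1.0 / 6.0) * 1.9, abs=0.02)

    def test_gauge_invariance(self):
        fes = _lj_slice_surface()
        shifted = FreeEnergySurface(x=fes.x, y=fes.y, F=fes.F + 7.3, gamma=fes.gamma)
        assert slice_effective_bond_energy(shifted, 3.0).value == pytest.approx(
            slice_effective_bond_energy(fes, 3.0).value
        )

    def test_monotonic_slice_flagged(self):
        x = np.linspace(1.6, 5.0, 100)
        y = np.linspace(1.6, 5.0, 10)
        F = np.tile(-x[:, None], (1, len(y)))  # downhill to the edge, no minimum
        fes = FreeEnergySurface(x=x, y=y, F=F - F.min(), gamma=10.0)
        assert slice_effective_bond_energy(fes, 3.0).flagged

    def test_outside_grid_rejected(self):
        fes = _lj_slice_surface()
        with pytest.raises(ValueError):
            slice_effective_bond_energy(fes, 9.0)


class TestApproachPattern:
    def test_axial_pose_is_direct(self):
        cx = build_complex("CO+O2")
        frames = cx.positions[None].copy()
        i_o2 = cx.ligands["O2"][0]
        frames[0, i_o2] = [0.0, 0.0, 2.5]  # directly above Fe
        ap = approach_pattern(frames, cx)
        assert ap.fe_distance[0] < ap.n_heme_distance[0]

    def test_pyrrole_pose_is_lateral(self):
        cx = build_complex("CO+O2")
        frames = cx.positions[None].copy()
        i_o2 = cx.ligands["O2"][0]
        frames[0, i_o2] = [2.0, 0.0, 1.0]  # above a pyrrole nitrogen
        ap = approach_pattern(frames, cx)
        assert ap.n_heme_distance[0] < ap.fe_distance[0]

    def test_sliding_path_flips_direct_approach_once(self):
        """O2 sliding from the periphery to the axial site: the
        closer-to-Fe classification flips exactly once."""
        cx = build_complex("CO+O2")
        i_o2, i_o1 = cx.ligands["O2"]
        n = 60
        frames = np.repeat(cx.positions[None], n, axis=0)
        ts = np.linspace(0.0, 1.0, n)
        for k, t in enumerate(ts):
            pos = (1 - t) * np.array([4.5, 0.0, 0.5]) + t * np.array([0.0, 0.0, 2.6])
            frames[k, i_o2] = pos
            frames[k, i_o1] = pos + [0.0, 0.0, 1.21]
        ap = approach_pattern(frames, cx)
        closer_to_fe = ap.fe_distance < ap.n_heme_distance
        assert not closer_to_fe[0] and closer_to_fe[-1]
        assert int(np.sum(np.diff(closer_to_fe.astype(int)) != 0)) == 1
        assert 0.0 < ap.direct_fraction <= 1.0
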