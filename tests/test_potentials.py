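"""Closed-form term tests: pair LJ, switching, biases, finite differences."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coordff import (
    BiasKind,
    BiasSpec,
    LJConvention,
    LJPairParams,
    PotentialCurve,
    bias_energy_force,
    finite_difference_force,
    lj_energy,
    lj_force,
    lj_max_attractive_force,
    switching_factor,
)
from coordff.potentials import switching_derivative

RMIN_FACTOR = 2.0 ** (1.0 / 6.0)


class TestLJ:
    @pytest.mark.parametrize(
        "eps,sig,r,expected",
        [
            (-1.0, 1.0, 1.0, 0.0),  # U(sigma) = 0
            (-1.0, 1.0, RMIN_FACTOR, -1.0),  # analytic minimum
            (-21.49, 1.79, RMIN_FACTOR * 1.79, -21.49),  # printed Fe-C depth
        ],
    )
    def test_energy_examples(self, eps, sig, r, expected):
        assert lj_energy(LJPairParams(eps, sig), r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "eps,sig,r,expected",
        [
            (-1.0, 1.0, RMIN_FACTOR, 0.0),  # force vanishes at the minimum
            (-1.0, 1.0, 1.0, 24.0),  # repulsive at r = sigma
        ],
    )
    def test_force_examples(self, eps, sig, r, expected):
        assert lj_force(LJPairParams(eps, sig), r) == pytest.approx(expected, abs=1e-9)

    def test_rmin_convention_minimum(self):
        p = LJPairParams(-6.55, 1.90, LJConvention.RMIN)
        assert lj_energy(p, 1.90) == pytest.approx(-6.55)
        assert lj_force(p, 1.90) == pytest.approx(0.0, abs=1e-9)

    @given(
        eps=st.floats(0.5, 30.0),
        sig=st.floats(1.0, 3.5),
        r=st.floats(0.8, 8.0),
    )
    def test_force_is_minus_du_dr(self, eps, sig, r):
        """Analytic force matches central differences of the energy."""
        p = LJPairParams(-eps, sig)
        h = 1e-5
        num = -(lj_energy(p, r + h) - lj_energy(p, r - h)) / (2 * h)
        assert lj_force(p, r) == pytest.approx(num, rel=1e-5, abs=1e-6)

    def test_max_attractive_force_location(self):
        p = LJPairParams(-21.49, 1.79)
        r_star = (26.0 / 7.0) ** (1.0 / 6.0) * 1.79
        assert -lj_force(p, r_star) == pytest.approx(lj_max_attractive_force(p))
        # slightly off the inflection the attraction is weaker
        assert -lj_force(p, r_star + 0.01) < lj_max_attractive_force(p)
        assert -lj_force(p, r_star - 0.01) < lj_max_attractive_force(p)

    def test_domain_errors(self):
        p = LJPairParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            lj_energy(p, 0.0)
        with pytest.raises(ValueError):
            lj_force(p, -1.0)
        with pytest.raises(ValueError):
            LJPairParams(-1.0, -2.0)


class TestFiniteDifference:
    def test_linear_energy_gives_constant_force(self):
        r = np.arange(1.0, 3.01, 0.1)
        c = finite_difference_force(PotentialCurve(r=r, U=3.0 * r))
        assert np.allclose(c.F, -3.0)
        assert len(c.r) == len(r) - 1

    def test_matches_analytic_away_from_wall(self):
        """The adjacent difference is midpoint-accurate: away from the
        repulsive wall it tracks the analytic force at r + dr/2 within 5%."""
        p = LJPairParams(-1.0, 1.0)
        r = np.arange(1.0, 3.01, 0.1)
        c = finite_difference_force(PotentialCurve(r=r, U=lj_energy(p, r)))
        sel = c.r >= 1.2
        assert np.allclose(c.F[sel], lj_force(p, c.r[sel] + 0.05), rtol=0.05)

    def test_local_energy_jump_produces_force_spike(self):
        """A single interval with a larger energy step than its neighbours
        leaves a localized artifact in the difference scheme."""
        r = np.arange(2.0, 3.01, 0.1)
        u = np.zeros_like(r)
        k = 4
        u[k + 1 :] += 1.0  # one 1-kcal/mol jump between r[k] and r[k+1]
        c = finite_difference_force(PotentialCurve(r=r, U=u))
        assert np.argmax(np.abs(c.F)) == k
        assert c.F[k] == pytest.approx(-10.0)

    def test_recovers_integrated_force_to_first_order(self):
        # U integrated from a smooth force; recovery error is O(dr)
        r = np.arange(1.5, 3.51, 0.1)
        force = lambda x: np.sin(x)
        u = np.cos(r)  # -dU/dr = sin(r)
        c = finite_difference_force(PotentialCurve(r=r, U=u))
        mid = force(c.r + 0.05)
        assert np.max(np.abs(c.F - mid)) < 0.05 * 0.1  # ~dr^2/24 * |F''|

    def test_errors(self):
        with pytest.raises(ValueError):
            finite_difference_force(PotentialCurve(r=[1.0], U=[0.0]))
        with pytest.raises(ValueError):
            finite_difference_force(PotentialCurve(r=[1.0, 1.1, 1.3], U=[0.0, 1, 2]))


class TestSwitching:
    def test_plateaus_and_interior(self):
        assert switching_factor(5.0) == 1.0
        assert switching_factor(11.0) == 0.0
        s9 = switching_factor(9.0)
        assert 0.0 < s9 < 1.0
        # monotone decreasing inside the switching window
        rs = np.linspace(8.0, 10.0, 50)
        assert np.all(np.diff(switching_factor(rs)) <= 0)

    def test_continuity_at_boundaries(self):
        eps = 1e-7
        assert switching_factor(8.0 + eps) == pytest.approx(1.0, abs=1e-8)
        assert switching_factor(10.0 - eps) == pytest.approx(0.0, abs=1e-8)
        assert switching_derivative(8.0 + eps) == pytest.approx(0.0, abs=1e-5)
        assert switching_derivative(10.0 - eps) == pytest.approx(0.0, abs=1e-5)

    def test_derivative_consistency(self):
        rs = np.linspace(8.1, 9.9, 17)
        h = 1e-6
        num = (switching_factor(rs + h) - switching_factor(rs - h)) / (2 * h)
        assert np.allclose(switching_derivative(rs), num, atol=1e-6)

    def test_config_error(self):
        with pytest.raises(ValueError):
            switching_factor(5.0, r_on=10.0, r_off=8.0)


class TestBias:
    def test_harmonic_closed_form(self):
        spec = BiasSpec(BiasKind.HARMONIC, kappa=3.0, r0=0.0)
        e, f = bias_energy_force(spec, 2.8)
        assert e == pytest.approx(11.76)
        assert f == pytest.approx(-8.4)  # restoring, magnitude kappa*x

    def test_upper_wall_inactive_inside(self):
        spec = BiasSpec(BiasKind.UPPER_WALL, kappa=150.0, ceiling=1.89)
        assert bias_energy_force(spec, 1.5) == (0.0, 0.0)
        e, f = bias_energy_force(spec, 2.0)
        assert e > 0 and f < 0

    def test_lower_wall_mirrors_upper(self):
        spec = BiasSpec(BiasKind.LOWER_WALL, kappa=150.0, ceiling=1.0)
        assert bias_energy_force(spec, 1.2) == (0.0, 0.0)
        e, f = bias_energy_force(spec, 0.8)
        assert e > 0 and f > 0

    def test_moving_reference_advances_at_rate(self):
        d0 = 2.0
        spec = BiasSpec(BiasKind.MOVING_HARMONIC, kappa=10.0, r0=d0, rate=1.0)
        assert spec.reference(0.0) == d0
        assert spec.reference(1.0) == pytest.approx(d0 + 1.0)  # 1 A after 1 ns

    @pytest.mark.parametrize(
        "spec,x",
        [
            (BiasSpec(BiasKind.HARMONIC, kappa=3.0, r0=1.0), 2.2),
            (BiasSpec(BiasKind.MOVING_HARMONIC, kappa=10.0, r0=2.0, rate=1.0), 2.7),
            (BiasSpec(BiasKind.UPPER_WALL, kappa=150.0, ceiling=1.89), 2.1),
            (BiasSpec(BiasKind.LOWER_WALL, kappa=150.0, ceiling=2.0), 1.7),
        ],
    )
    def test_energy_force_consistency(self, spec, x):
        h = 1e-5
        t = 0.5
        e_p, _ = bias_energy_force(spec, x + h, t)
        e_m, _ = bias_energy_force(spec, x - h, t)
        _, f = bias_energy_force(spec, x, t)
        assert f == pytest.approx(-(e_p - e_m) / (2 * h), abs=1e-6)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            BiasSpec(BiasKind.HARMONIC, kappa=-1.0)
        with pytest.raises(ValueError):
            BiasSpec(BiasKind.MOVING_HARMONIC, kappa=1.0)  # no rate
        with pytest.raises(ValueError):
            BiasSpec(BiasKind.UPPER_WALL, kappa=1.0)  # no ceiling
        with pytest.raises(ValueError):
            bias_energy_force(BiasSpec(BiasKind.HARMONIC, kappa=1.0), 1.0, t_ns=-0.1)
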