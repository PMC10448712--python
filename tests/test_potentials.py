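import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import constants as sconst

from gagcg import constants as c
from gagcg import potentials as pot


KT = c.KB * 300.0


class TestHarmonicBond:
    def test_equilibrium(self):
        v, f = pot.harmonic_bond(0.56, 0.56, 8038.0)
        assert v == 0.0 and f == 0.0

    def test_hand_value(self):
        v, _ = pot.harmonic_bond(0.66, 0.56, 8038.0)
        assert v == pytest.approx(0.5 * 8038.0 * 0.01, rel=1e-12)

    @given(st.floats(1e-4, 0.3))
    def test_even_symmetry(self, d):
        v1, _ = pot.harmonic_bond(0.56 + d, 0.56, 8038.0)
        v2, _ = pot.harmonic_bond(0.56 - d, 0.56, 8038.0)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestTabulated:
    def test_exact_at_grid_points(self):
        grid = np.arange(0.0, 181.0, 1.0)
        e = np.sin(grid / 30.0)
        p = pot.TabulatedPotential.from_energy(grid, e)
        ev, _ = p(grid)
        np.testing.assert_allclose(ev, e, atol=1e-14)

    def test_constant_table_zero_force(self):
        grid = np.arange(0.0, 181.0, 1.0)
        p = pot.TabulatedPotential.from_energy(grid, np.full(181, 3.5))
        _, f = p(np.linspace(0.3, 179.7, 57))
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_cosine_interpolation_accuracy(self):
        grid = np.arange(-180.0, 180.1, 7.2)
        p = pot.TabulatedPotential.from_energy(grid, np.cos(np.radians(grid)),
                                               periodic=True)
        mid = grid[:-1] + 3.6
        ev, _ = p(mid)
        assert np.max(np.abs(ev - np.cos(np.radians(mid)))) < 1e-3

    def test_force_is_centered_fd_of_energy(self):
        grid = np.arange(0.0, 181.0, 1.0)
        e = np.exp(-((grid - 100) / 25.0) ** 2) * 30
        p = pot.TabulatedPotential.from_energy(grid, e)
        fd = -(e[2:] - e[:-2]) / (2 * p.dx)
        np.testing.assert_allclose(p.force[1:-1], fd, rtol=1e-12)

    def test_periodic_wrap_continuity(self):
        grid = np.arange(-180.0, 180.1, 7.2)
        p = pot.TabulatedPotential.from_energy(grid, np.cos(np.radians(grid - 33)),
                                               periodic=True)
        e1, f1 = p(-179.999)
        e2, f2 = p(180.001)
        assert e1 == pytest.approx(e2, abs=1e-4)
        assert f1 == pytest.approx(f2, abs=1e-4)

    def test_cap_potential(self):
        grid = np.arange(-180.0, 180.1, 7.2)
        e = 40 * KT * (1 + np.cos(np.radians(grid))) / 2
        p = pot.TabulatedPotential.from_energy(grid, e, periodic=True)
        capped = pot.cap_potential(p, 20 * KT)
        assert capped.energy.max() == pytest.approx(20 * KT)
        assert capped.energy.min() == p.energy.min()
        assert capped.grid[np.argmin(capped.energy)] == p.grid[np.argmin(p.energy)]
        below = pot.cap_potential(p, 100 * KT)
        np.testing.assert_allclose(below.energy, p.energy)


class TestPenalty:
    def test_divergent_at_180(self):
        assert pot.penalty_energy(np.pi) == np.inf
        assert pot.penalty_energy(np.pi - 0.5 * c.PENALTY_B) == np.inf

    def test_monotone_increasing(self):
        th = np.linspace(np.pi / 2 + 0.01, np.pi - c.PENALTY_B - 1e-4, 200)
        v = pot.penalty_energy(th)
        assert np.all(np.diff(v) > 0)

    def test_linear_in_a(self):
        th = np.linspace(1.0, np.pi - 0.1, 50)
        v1 = pot.penalty_energy(th, pot.PenaltyParams(a=100.0))
        v2 = pot.penalty_energy(th, pot.PenaltyParams(a=200.0))
        np.testing.assert_allclose(v1 / v2, 0.5, rtol=1e-12)

    def test_negligible_at_typical_peak(self):
        # typical XGG distributions peak well below 150 degrees
        assert pot.penalty_energy(np.radians(130.0)) < 0.1 * KT

    def test_rejects_nonpositive_theta(self):
        with pytest.raises(ValueError):
            pot.penalty_energy(0.0)


class TestElectrostatics:
    def test_debye_length_against_si_constants(self):
        # independent evaluation of the closed form with scipy's constants
        p = pot.ElectrostaticsParams(C_s=0.150, T=300.0)
        expected = math.sqrt(sconst.epsilon_0 * 80 * sconst.k * 300
                             / (2 * sconst.e ** 2 * sconst.N_A * 150.0)) * 1e9
        assert pot.debye_length(p) == pytest.approx(expected, rel=1e-9)
        assert pot.debye_length(p) == pytest.approx(0.78, abs=0.03)

    def test_debye_length_sqrt_scaling(self):
        lam1 = pot.debye_length(pot.ElectrostaticsParams(C_s=0.05))
        lam4 = pot.debye_length(pot.ElectrostaticsParams(C_s=0.20))
        assert lam1 / lam4 == pytest.approx(2.0, rel=1e-12)
        assert pot.debye_length(pot.ElectrostaticsParams(C_s=0.010)) == pytest.approx(3.0, abs=0.1)

    def test_zero_charge_site(self):
        p = pot.ElectrostaticsParams(C_s=0.15)
        assert pot.debye_huckel_energy(0.5, 0.0, -1.0, p) == 0.0

    def test_magnitude_at_debye_length(self):
        p = pot.ElectrostaticsParams(C_s=0.150, T=300.0)
        lam = pot.debye_length(p)
        v = pot.debye_huckel_energy(lam, -1, -1, p)
        assert v / KT == pytest.approx(0.33, abs=0.02)

    def test_screened_coulomb_identity(self):
        # V(r) * r * exp(kappa r) is constant in r
        p = pot.ElectrostaticsParams(C_s=0.1)
        lam = pot.debye_length(p)
        r = np.linspace(0.3, 4.0, 40)
        prod = pot.debye_huckel_energy(r, -1, -1, p) * r * np.exp(r / lam)
        np.testing.assert_allclose(prod, prod[0], rtol=1e-10)

    def test_truncation_beyond_cutoff(self):
        p = pot.ElectrostaticsParams(C_s=0.15, cutoff_factor=3.0)
        lam = pot.debye_length(p)
        assert pot.debye_huckel_energy(3.01 * lam, -1, -1, p) == 0.0


class TestWCA:
    def test_zero_at_and_beyond_cutoff(self):
        s = 0.356
        rc = 2 ** (1 / 6) * s
        assert pot.wca_energy(rc, s) == 0.0
        assert pot.wca_energy(2 * s, s) == 0.0

    def test_value_at_sigma(self):
        assert pot.wca_energy(0.329, 0.329) == pytest.approx(c.EPS_LJ, rel=1e-12)
        assert c.EPS_LJ == 0.6276

    def test_continuous_at_cutoff(self):
        s = 0.329
        rc = 2 ** (1 / 6) * s
        assert pot.wca_energy(rc - 1e-9, s) == pytest.approx(0.0, abs=1e-6)


class TestBoltzmannInversion:
    def test_uniform_gives_constant_zero(self):
        grid = np.arange(0.5, 180.0, 1.0)
        p = np.full_like(grid, 1.0 / 179.0)
        v = pot.boltzmann_invert(grid, p, 300.0)
        np.testing.assert_allclose(v.energy, 0.0, atol=1e-12)

    def test_gaussian_gives_harmonic_curvature(self):
        grid = np.arange(0.5, 180.0, 1.0)
        s = 9.0
        p = np.exp(-((grid - 95.0) / s) ** 2 / 2)
        p /= np.trapezoid(p, grid)
        v = pot.boltzmann_invert(grid, p, 300.0, p_floor=1e-30)
        core = (grid > 70) & (grid < 120)
        coef = np.polyfit(grid[core], v.energy[core], 2)
        assert coef[0] == pytest.approx(KT / (2 * s * s), rel=1e-3)

    def test_roundtrip(self):
        grid = np.arange(0.5, 180.0, 1.0)
        v0 = 10 * np.sin(grid / 40.0) ** 2
        p = np.exp(-v0 / KT)
        p /= np.trapezoid(p, grid)
        v = pot.boltzmann_invert(grid, p, 300.0, p_floor=1e-30)
        np.testing.assert_allclose(v.energy - v.energy.min(), v0 - v0.min(), atol=1e-8)

    def test_unsampled_bins_capped_wall(self):
        grid = np.arange(0.5, 180.0, 1.0)
        p = np.where((grid > 80) & (grid < 110), 1.0, 0.0)
        p /= np.trapezoid(p, grid)
        v = pot.boltzmann_invert(grid, p, 300.0, v_wall_kt=50.0)
        assert v.energy.max() <= 50.0 * KT + 1e-9
        assert np.isfinite(v.energy).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pot.boltzmann_invert(np.arange(5.0), np.zeros(5), 300.0)


class TestAngleFit:
    def test_pure_lognormal_recovery(self):
        rng = np.random.default_rng(3)
        s_true, mu_true = 0.08, math.log(110.0)
        samples = rng.lognormal(mu_true, s_true, size=100_000)
        grid = pot.ANGLE_GRID
        hist, _ = np.histogram(samples, bins=np.arange(0.0, 180.5, 1.0), density=True)
        fit = pot.fit_angle_pdf(grid, hist)
        assert fit.beta > 0.9  # mixture pushed to the log-normal boundary
        assert fit.s == pytest.approx(s_true, rel=0.05)
        assert fit.mu == pytest.approx(mu_true, rel=0.05)

    def test_mixture_self_consistency(self):
        true = pot.AngleFitParams(beta=0.6, s=0.07, mu=math.log(120.0),
                                  gamma=95.0, delta=8.0)
        grid = pot.ANGLE_GRID
        dens = pot.angle_mixture_pdf(grid, true)
        fit = pot.fit_angle_pdf(grid, dens)
        fitted = pot.angle_mixture_pdf(grid, fit)
        assert np.max(np.abs(fitted - dens)) < 0.01

    def test_bounds_clamped(self):
        grid = pot.ANGLE_GRID
        dens = pot.angle_mixture_pdf(grid, pot.AngleFitParams(
            beta=1.0, s=0.05, mu=math.log(100.0), gamma=100.0, delta=5.0))
        bounds = {"s": (0.10, 2.0)}  # true s=0.05 lies outside
        fit = pot.fit_angle_pdf(grid, dens, bounds=bounds)
        assert fit.s >= 0.10

    def test_fitted_pdf_normalized(self):
        fitp = pot.AngleFitParams(beta=0.4, s=0.1, mu=math.log(100.0),
                                  gamma=120.0, delta=12.0)
        dense = np.linspace(1e-3, 180.0, 5001)
        total = np.trapezoid(pot.angle_mixture_pdf(dense, fitp), dense)
        assert total == pytest.approx(1.0, abs=1e-3)


class TestDihedralSpline:
    def test_uniform(self):
        grid = pot.DIHEDRAL_GRID
        d = pot.fit_dihedral_spline(grid, np.full_like(grid, 1.0 / 360.0))
        np.testing.assert_allclose(d(np.linspace(-179, 179, 100)), 1.0 / 360.0,
                                   rtol=1e-6)

    def test_periodic_value_and_slope(self):
        rng = np.random.default_rng(1)
        samples = np.degrees(np.angle(np.exp(1j * rng.normal(1.0, 0.6, 50_000))))
        hist, _ = np.histogram(samples, bins=np.arange(-180, 180.5, 7.2), density=True)
        d = pot.fit_dihedral_spline(pot.DIHEDRAL_GRID, hist)
        assert d(-180.0) == pytest.approx(d(180.0), rel=1e-9)
        assert d.derivative(-180.0) == pytest.approx(d.derivative(180.0), rel=1e-6, abs=1e-12)

    def test_matches_wrapped_gaussian_density(self):
        rng = np.random.default_rng(5)
        samples = (rng.normal(40.0, 30.0, 200_000) + 180) % 360 - 180
        edges = np.arange(-180, 180.5, 7.2)
        hist, _ = np.histogram(samples, bins=edges, density=True)
        d = pot.fit_dihedral_spline(pot.DIHEDRAL_GRID, hist)
        # sup-norm within 2 bin heights of the empirical density
        assert np.max(np.abs(d(pot.DIHEDRAL_GRID) - hist)) < 2 * hist.max() / len(hist)

    def test_nonnegative(self):
        grid = pot.DIHEDRAL_GRID
        hist = np.zeros_like(grid)
        hist[10] = 1.0 / 7.2
        d = pot.fit_dihedral_spline(grid, hist)
        assert np.all(d(np.linspace(-180, 180, 1000)) >= 0.0)
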