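"""Parameterization: chi(T), water properties, cutoff, repulsion parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpdgel.errors import DomainError, ParameterizationError, RangeError
from dpdgel.forcefield import (
    ALPHA_EOS, BeadSpec, FloryHugginsModel, build_forcefield,
    chi_of_temperature, cutoff_radius, fmax_cross, fmax_self, fmax_water,
    inverse_compressibility, matching_pressure, reduced_units,
)
from dpdgel.water import water_density, water_properties


class TestChi:
    @pytest.mark.parametrize("T, expected", [
        (308.3, 0.5),                                # theta temperature
        (330.0, 0.5 + 35.2 * (1 - 308.3 / 330.0)),   # ~2.815
        (280.0, 0.5 + 35.2 * (1 - 308.3 / 280.0)),   # ~-3.058
    ])
    def test_fitted_law(self, T, expected):
        assert chi_of_temperature(T) == pytest.approx(expected, abs=1e-12)

    def test_theta_point_exact(self):
        assert chi_of_temperature(308.3) == 0.5

    @given(st.floats(200.0, 400.0), st.floats(0.1, 50.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing(self, T, dT):
        m = FloryHugginsModel()
        assert chi_of_temperature(T + dT, m) > chi_of_temperature(T, m)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(DomainError):
            chi_of_temperature(0.0)
        with pytest.raises(DomainError):
            chi_of_temperature(-10.0)


class TestWaterProperties:
    def test_ambient_density(self):
        rho, kappa = water_properties(298.15)
        assert rho == pytest.approx(997.0, abs=1.0)
        assert kappa == pytest.approx(4.52e-10, rel=0.01)

    def test_density_anomaly_maximum_near_277K(self):
        grid = np.arange(273.15, 373.16, 0.25)
        dens = np.array([water_density(t) for t in grid])
        t_max = grid[np.argmax(dens)]
        assert abs(t_max - 277.13) < 1.0
        assert water_density(277.0) > water_density(273.15)
        assert water_density(277.0) > water_density(298.15)

    def test_out_of_range_rejected(self):
        for T in (250.0, 400.0):
            with pytest.raises(RangeError):
                water_properties(T)


class TestCutoffRadius:
    def test_paper_coarse_graining(self):
        # Nm=5 water bead at rho~=3: rc about 7.66 angstrom
        assert cutoff_radius(298.15) * 1e10 == pytest.approx(7.66, abs=0.02)

    def test_single_molecule_bead(self):
        assert cutoff_radius(298.15, Nm=1, rho_reduced=1.0) * 1e10 == \
            pytest.approx(3.10, abs=0.02)

    def test_doubling_Nm_scales_cube_root(self):
        r1 = cutoff_radius(300.0, Nm=5)
        r2 = cutoff_radius(300.0, Nm=10)
        assert r2 / r1 == pytest.approx(2.0 ** (1 / 3), rel=1e-12)

    @pytest.mark.parametrize("T", np.arange(275.0, 372.0, 8.0).tolist())
    def test_density_identity(self, T):
        # rc^3 * rho_w == rho~ * Nm * m_w to machine precision
        beads = BeadSpec()
        rc = cutoff_radius(T, beads.Nm, 3.0, beads.water_molecule_mass)
        rho_w = water_properties(T)[0]
        assert rc**3 * rho_w == pytest.approx(
            3.0 * beads.Nm * beads.water_molecule_mass, rel=1e-14)


class TestCompressibilityAndRepulsion:
    def test_ambient_inverse_compressibility(self):
        assert inverse_compressibility(298.15, 3.33e28, 4.52e-10) == \
            pytest.approx(16.1, abs=0.1)

    def test_inverse_proportionality(self):
        a = inverse_compressibility(300.0, 3.3e28, 4.5e-10)
        b = inverse_compressibility(300.0, 3.3e28, 9.0e-10)
        assert a / b == pytest.approx(2.0, rel=1e-12)

    def test_definition_identity(self):
        from dpdgel.forcefield import KB
        k = inverse_compressibility(310.0, 3.3e28, 4.4e-10)
        assert k * (3.3e28 * KB * 310.0 * 4.4e-10) == pytest.approx(1.0)

    def test_fmax_water_examples(self):
        assert fmax_water(5, 16.1) == pytest.approx(
            (5 * 16.1 - 1) / (2 * ALPHA_EOS * 3.0), rel=1e-12)
        # Nm=1, k_inv=16 recovers the classic a ~ 25
        assert fmax_water(1, 16.0) == pytest.approx(24.75, abs=0.01)

    def test_fmax_water_degenerate_limit(self):
        assert fmax_water(1, 1.0 + 1e-9) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ParameterizationError):
            fmax_water(1, 0.5)

    def test_matching_pressure_examples(self):
        assert matching_pressure(0.0) == pytest.approx(3.0)
        assert matching_pressure(131.4) == pytest.approx(
            3.0 + ALPHA_EOS * 131.4 * 9.0, rel=1e-12)

    @given(st.floats(0.0, 500.0))
    @settings(max_examples=50, derandomize=True)
    def test_pressure_matching_round_trip(self, x):
        assert fmax_self(matching_pressure(x), 3.0) == pytest.approx(
            x, rel=1e-12, abs=1e-12)

    def test_fmax_self_boundaries(self):
        assert fmax_self(3.0, 3.0) == 0.0
        with pytest.raises(ParameterizationError):
            fmax_self(2.0, 3.0)


class TestFmaxCross:
    def test_athermal_geometric_mean(self):
        assert fmax_cross(100.0, 25.0, 0.0, 122.0, 3.0, 2.6) == 50.0
        assert fmax_cross(80.0, 80.0, 0.0, 122.0, 3.0, 3.0) == 80.0

    def test_linear_in_chi(self):
        args = (131.0, 170.0, 122.0, 3.0, 2.6)
        f = lambda chi: fmax_cross(args[0], args[1], chi, *args[2:])
        d1 = f(1.0) - f(0.0)
        d2 = f(2.5) - f(1.5)
        assert d1 == pytest.approx(d2, rel=1e-12)
        assert d1 > 0

    def test_groot_warren_limit(self):
        # identical water-like beads at rho~=3, a=25: excess slope ~3.50
        p = matching_pressure(25.0)
        slope = fmax_cross(25.0, 25.0, 1.0, p, 3.0, 3.0) - 25.0
        assert slope == pytest.approx(1.0 / 0.286, rel=0.01)


class TestBuildForceField:
    def test_fluctuation_dissipation(self, ff_ambient):
        assert ff_ambient.sigma == pytest.approx(3.0, rel=1e-15)
        assert ff_ambient.sigma**2 / (2 * ff_ambient.gamma) == \
            pytest.approx(1.0, rel=1e-15)

    def test_water_monomer_repulsion_grows_with_temperature(self):
        temps = np.arange(280.0, 330.5, 5.0)
        fwm = [build_forcefield(T).fmax_wm for T in temps]
        assert np.all(np.diff(fwm) > 0)
        assert fwm[-1] > fwm[0]

    def test_excess_changes_sign_with_chi(self):
        for T in (280.0, 300.0, 320.0, 330.0):
            ff = build_forcefield(T)
            excess = ff.fmax_wm - math.sqrt(ff.fmax_ww * ff.fmax_mm)
            assert excess == pytest.approx(0.0, abs=1e-9) or \
                (excess > 0) == (ff.chi > 0)

    def test_cross_bound_in_poor_solvent(self):
        # chi >= 0 implies fmax_wm >= geometric mean of the self terms
        for T in (308.3, 315.0, 330.0):
            ff = build_forcefield(T)
            assert ff.fmax_wm >= math.sqrt(ff.fmax_ww * ff.fmax_mm) - 1e-12

    def test_reduced_unit_time_scale(self, ff_ambient):
        u = ff_ambient.units
        assert u.time_unit == pytest.approx(
            u.rc * math.sqrt(u.mass_unit / u.energy_unit), rel=1e-15)
        assert u.rho_reduced == 3.0

    def test_monomer_bead_distinct_from_water(self, ff_ambient):
        assert ff_ambient.fmax_mm > 0
        assert ff_ambient.fmax_mm != pytest.approx(ff_ambient.fmax_ww)
        # similar bead volumes: reduced monomer density close to water's 3
        assert 2.0 < ff_ambient.rho_m_reduced < 3.5
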