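"""Closed-form physics: forward formulas, inverses, and scalings."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import passivemotion as pm


class TestWaterViscosity:
    @pytest.mark.parametrize("temperature, expected_mpa_s, rtol", [
        (293.15, 1.0016, 0.005),
        (363.15, 0.31417, 0.01),
    ])
    def test_reference_values(self, temperature, expected_mpa_s, rtol):
        assert pm.water_viscosity(temperature) * 1e3 == pytest.approx(
            expected_mpa_s, rel=rtol)

    def test_strictly_decreasing_with_temperature(self):
        temps = np.linspace(263.15, 373.15, 200)
        visc = [pm.water_viscosity(t) for t in temps]
        assert np.all(np.diff(visc) < 0)

    @pytest.mark.parametrize("temperature", [200.0, 262.0, 380.0, 500.0])
    def test_out_of_range_raises(self, temperature):
        with pytest.raises(ValueError):
            pm.water_viscosity(temperature)


class TestDiffusion:
    def test_coefficient_at_20C(self, water20):
        # D * r for water at 20 degC, micrometre scale
        D = pm.diffusion_coefficient(1.0e-6, water20)
        assert D * 1e12 == pytest.approx(0.2146, rel=0.005)

    def test_half_micron_sphere(self, water20):
        D = pm.diffusion_coefficient(0.5e-6, water20)
        assert D * 1e12 == pytest.approx(0.43, rel=0.01)

    def test_inverse_proportionality_in_radius(self, water20):
        r = 0.8e-6
        assert pm.diffusion_coefficient(2 * r, water20) == pytest.approx(
            pm.diffusion_coefficient(r, water20) / 2, rel=1e-12)

    @given(st.floats(min_value=1e-8, max_value=1e-4))
    def test_radius_round_trip(self, radius):
        fluid = pm.FluidMedium(293.15, 1.002e-3, 998.0)
        D = pm.diffusion_coefficient(radius, fluid)
        assert pm.radius_from_diffusivity(D, fluid) == pytest.approx(
            radius, rel=1e-12)

    def test_radius_from_einstein_diffusivity(self, water20):
        # 0.43 um^2/s at 20 degC corresponds to a 1.0 um diameter sphere
        r = pm.radius_from_diffusivity(0.43e-12, water20)
        assert 2 * r * 1e6 == pytest.approx(1.0, rel=0.01)
        r = pm.radius_from_diffusivity(0.2146e-12, water20)
        assert r * 1e6 == pytest.approx(1.0, rel=0.005)

    def test_nonpositive_diffusivity_raises(self, water20):
        with pytest.raises(ValueError):
            pm.radius_from_diffusivity(0.0, water20)


class TestBrownianTime:
    def test_one_dimensional(self):
        # 1 um RMS at D = 0.2146 um^2/s
        tau = pm.brownian_time(1e-6, 0.2146e-12, dimensions=1)
        assert tau == pytest.approx(2.330, rel=1e-3)

    def test_quadratic_in_distance(self):
        assert pm.brownian_time(2e-6, 1e-13) == pytest.approx(
            4 * pm.brownian_time(1e-6, 1e-13), rel=1e-12)

    def test_2d_halves_1d(self):
        assert pm.brownian_time(1e-6, 1e-13, dimensions=2) == pytest.approx(
            pm.brownian_time(1e-6, 1e-13, dimensions=1) / 2, rel=1e-12)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            pm.brownian_time(1e-6, 1e-13, dimensions=3)


class TestStokes:
    def test_alumina_sinks(self, earth):
        particle = pm.ParticleSpec(0.75e-6, 998.0 + 1932.0, "Alumina")
        v = pm.stokes_velocity(particle, earth)
        assert v * 1e6 == pytest.approx(2.36, abs=0.01)

    def test_gas_vesicles_rise(self, earth):
        particle = pm.ParticleSpec(1.0e-6, 998.0 - 879.0)
        v = pm.stokes_velocity(particle, earth)
        assert v < 0
        assert abs(v) * 1e6 == pytest.approx(1.9, abs=0.02)

    def test_neutral_buoyancy_is_static(self, earth):
        particle = pm.ParticleSpec(1.0e-6, 998.0)
        assert pm.stokes_velocity(particle, earth) == 0.0

    @given(st.floats(min_value=-2000, max_value=2000),
           st.floats(min_value=1e-7, max_value=5e-6))
    def test_density_round_trip(self, delta_rho, radius):
        fluid = pm.FluidMedium(293.15, 1.002e-3, 998.0)
        env = pm.MissionEnvironment("Earth", 9.81, fluid)
        if 998.0 + delta_rho <= 0:
            return
        particle = pm.ParticleSpec(radius, 998.0 + delta_rho)
        v = pm.stokes_velocity(particle, env)
        rec = pm.density_diff_from_velocity(v, radius, env)
        assert rec == pytest.approx(delta_rho, rel=1e-12, abs=1e-9)

    def test_density_from_known_velocities(self, earth):
        assert pm.density_diff_from_velocity(
            2.36e-6, 0.75e-6, earth) == pytest.approx(1928.5, rel=0.01)
        assert pm.density_diff_from_velocity(0.0, 1e-6, earth) == 0.0
        # polystyrene-like contrast from its Stokes velocity
        assert pm.density_diff_from_velocity(
            0.0283e-6, 0.5e-6, earth) == pytest.approx(52, rel=0.01)


class TestGravityTime:
    def test_alumina_over_two_microns(self, earth):
        particle = pm.ParticleSpec(0.75e-6, 998.0 + 1932.0)
        tau = pm.gravity_time(2e-6, particle, earth)
        assert tau == pytest.approx(2e-6 / 2.3644e-6, rel=1e-3)

    def test_consistency_with_velocity(self, earth):
        particle = pm.ParticleSpec(1.2e-6, 2000.0)
        v = abs(pm.stokes_velocity(particle, earth))
        d = 5e-6
        assert pm.gravity_time(d, particle, earth) * v == pytest.approx(
            d, rel=1e-12)

    def test_halving_contrast_doubles_time(self, water20):
        env = pm.MissionEnvironment("Earth", 9.81, water20)
        full = pm.ParticleSpec(1e-6, 998.0 + 400.0)
        half = pm.ParticleSpec(1e-6, 998.0 + 200.0)
        assert pm.gravity_time(1e-6, half, env) == pytest.approx(
            2 * pm.gravity_time(1e-6, full, env), rel=1e-12)

    def test_neutral_gives_infinity(self, earth):
        particle = pm.ParticleSpec(1e-6, 998.0)
        assert math.isinf(pm.gravity_time(1e-6, particle, earth))


class TestStrouhal:
    def test_alumina_reference_value(self, earth):
        particle = pm.ParticleSpec(0.75e-6, 998.0 + 1932.0)
        assert pm.strouhal(particle, earth) == pytest.approx(0.161, rel=0.01)

    def test_locked_constant(self, earth):
        # Sr * (drho g r^4) / (k_B T) must equal 3 / (4 pi)
        particle = pm.ParticleSpec(1.1e-6, 998.0 + 500.0)
        sr = pm.strouhal(particle, earth)
        const = sr * (500.0 * 9.81 * (1.1e-6) ** 4) / (
            pm.K_B * earth.fluid.temperature)
        assert const == pytest.approx(3 / (4 * math.pi), rel=1e-12)

    def test_linear_in_temperature(self):
        p = pm.ParticleSpec(1e-6, 1500.0)
        env1 = pm.MissionEnvironment(
            "a", 9.81, pm.FluidMedium(300.0, 1e-3, 998.0))
        env2 = pm.MissionEnvironment(
            "b", 9.81, pm.FluidMedium(600.0, 1e-3, 998.0))
        assert pm.strouhal(p, env2) == pytest.approx(
            2 * pm.strouhal(p, env1), rel=1e-12)

    @given(st.floats(min_value=1e-4, max_value=10.0))
    def test_independent_of_viscosity(self, viscosity_pa_s):
        p = pm.ParticleSpec(1e-6, 1500.0)
        base = pm.MissionEnvironment(
            "a", 9.81, pm.FluidMedium(293.15, 1.002e-3, 998.0))
        other = pm.MissionEnvironment(
            "b", 9.81, pm.FluidMedium(293.15, viscosity_pa_s, 998.0))
        assert pm.strouhal(p, other) == pytest.approx(
            pm.strouhal(p, base), rel=1e-12)

    def test_r_minus_fourth_scaling(self, earth):
        small = pm.ParticleSpec(0.5e-6, 1500.0)
        large = pm.ParticleSpec(1.0e-6, 1500.0)
        assert pm.strouhal(small, earth) == pytest.approx(
            16 * pm.strouhal(large, earth), rel=1e-12)

    def test_neutral_gives_infinity(self, earth):
        assert math.isinf(pm.strouhal(pm.ParticleSpec(1e-6, 998.0), earth))


class TestMotionRegime:
    @pytest.mark.parametrize("sr, expected", [
        (0.01, "gravity"),
        (1.0, "mixed"),
        (100.0, "brownian"),
        (0.1, "mixed"),   # boundary values fall in the mixed band
        (10.0, "mixed"),
    ])
    def test_default_thresholds(self, sr, expected):
        assert pm.motion_regime(sr) == expected

    def test_configurable_thresholds(self):
        assert pm.motion_regime(0.5, gravity_below=1.0) == "gravity"


class TestObservationTime:
    def test_earth_benchmark(self, earth):
        # 0.1 g/cm^3 contrast at r = 0.75 um, 2 um axial resolution
        t = pm.required_observation_time(100.0, 0.75e-6, 2e-6, earth)
        assert t == pytest.approx(16.3, rel=0.01)

    def test_inverse_linear_in_gravity(self, water20):
        earth = pm.MissionEnvironment("Earth", 9.81, water20)
        low_g = pm.MissionEnvironment("low", 0.0981, water20)
        t_e = pm.required_observation_time(100.0, 0.75e-6, 2e-6, earth)
        t_l = pm.required_observation_time(100.0, 0.75e-6, 2e-6, low_g)
        assert t_l == pytest.approx(100 * t_e, rel=1e-12)

    def test_linear_in_axial_resolution(self, earth):
        t1 = pm.required_observation_time(100.0, 0.75e-6, 2e-6, earth)
        t2 = pm.required_observation_time(100.0, 0.75e-6, 4e-6, earth)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_neutral_gives_infinity(self, earth):
        assert math.isinf(
            pm.required_observation_time(0.0, 1e-6, 2e-6, earth))


class TestStrouhalGrid:
    def test_single_cell_matches_scalar(self, earth):
        grid = pm.strouhal_grid([0.75e-6], [998.0 + 1932.0], earth)
        scalar = pm.strouhal(pm.ParticleSpec(0.75e-6, 998.0 + 1932.0), earth)
        assert grid.iloc[0, 0] == pytest.approx(math.log10(scalar), rel=1e-12)

    def test_rows_decrease_with_radius(self, earth):
        radii = np.linspace(0.3e-6, 3e-6, 8)
        grid = pm.strouhal_grid(radii, [1100.0, 2930.0], earth)
        assert (grid.diff(axis=0).iloc[1:] < 0).all().all()

    def test_gravity_environments_differ_by_constant(self, water20,
                                                     environments):
        radii = [0.5e-6, 1e-6, 2e-6]
        dens = [1100.0, 1600.0, 2930.0]
        g_earth = pm.strouhal_grid(radii, dens, environments["Earth"])
        g_enc = pm.strouhal_grid(radii, dens, environments["Enceladus"])
        expected = math.log10(9.81 / 0.113)
        np.testing.assert_allclose(g_enc.values - g_earth.values, expected,
                                   rtol=1e-12)

    def test_fluid_density_cell_is_infinite(self, earth):
        grid = pm.strouhal_grid([1e-6], [998.0], earth)
        assert math.isinf(grid.iloc[0, 0])


class TestMaterialLibrary:
    def test_delta_rho_consistent_with_density(self, library):
        table = library.table
        water_rho = library.WATER_DENSITY
        for row in table.itertuples():
            assert row.delta_rho_kg_m3 == pytest.approx(
                row.density_kg_m3 - water_rho, abs=1e-9)

    def test_reference_entries(self, library):
        assert library.density("Water") == 998.0
        assert library.delta_rho("Alumina") == 1932.0
        assert library.delta_rho("Polystyrene") == 52.0
        assert library.delta_rho("Anabaena Gas Vesicles") == -879.0

    def test_unknown_material_raises(self, library):
        with pytest.raises(KeyError):
            library.density("Unobtainium")

    def test_packaged_environments(self, environments):
        assert set(environments) == {"Earth", "Mars", "Europa", "Enceladus"}
        assert environments["Earth"].gravity == 9.81
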