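"""Diffusion-Langmuir solver: conservation, bounds, equilibria, conversions."""

import numpy as np
import pytest

from proteocell import (
    GridControls,
    ProteinParams,
    ProteinTrajectory,
    SolverError,
    SteadyState,
    WellGeometry,
    average_surface_concentration,
    equilibrium_state,
    solve_protein_kinetics,
    steady_state_capacity,
)


class TestSteadyStateCapacity:
    def test_fitted_point_implies_capacity_from_balance(self):
        # zero net Langmuir flux at the observed endpoint fixes the capacity
        csm = steady_state_capacity(6.2e-4, 0.2, SteadyState(5300.0, 29.04))
        assert csm == pytest.approx(30.81, abs=0.005)
        # plugging back: attach and detach terms balance
        assert 6.2e-4 * 5300.0 * (csm - 29.04) == pytest.approx(0.2 * 29.04, rel=1e-12)

    def test_no_desorption_equilibrates_at_observed_coverage(self):
        assert steady_state_capacity(1e-3, 0.0, SteadyState(500.0, 12.0)) == 12.0

    def test_hand_arithmetic(self):
        assert steady_state_capacity(1e-3, 0.1, SteadyState(1000.0, 10.0)) == pytest.approx(11.0)

    def test_undefined_without_adsorption(self):
        with pytest.raises(ValueError):
            steady_state_capacity(0.0, 0.1, SteadyState(1000.0, 10.0))
        with pytest.raises(ValueError):
            steady_state_capacity(1e-3, 0.1, SteadyState(0.0, 10.0))


class TestEquilibriumState:
    def test_empty_system(self, fitted_params, geometry):
        assert equilibrium_state(fitted_params, geometry, 0.0) == (0.0, 0.0)

    def test_all_mass_adsorbs_without_desorption(self, geometry):
        p = ProteinParams(k_a=1e-3, k_d=0.0, c_s_max=31.5)
        mass = 0.5 * geometry.area_mm2 * 31.5  # below capacity
        c_eq, cs_eq = equilibrium_state(p, geometry, mass)
        assert c_eq == pytest.approx(0.0, abs=1e-9)
        assert cs_eq == pytest.approx(mass / geometry.area_mm2, rel=1e-9)

    def test_against_bruteforce_root_scan(self, fitted_params, geometry):
        # independent oracle: dense scan of the net-flux residual over c_s
        mass = 29.04 * geometry.area_mm2
        c_eq, cs_eq = equilibrium_state(fitted_params, geometry, mass)
        cs_grid = np.linspace(0.0, fitted_params.c_s_max, 2_000_001)
        c_grid = (mass - geometry.area_mm2 * cs_grid) / geometry.volume_mL
        resid = fitted_params.k_a * c_grid * (fitted_params.c_s_max - cs_grid) \
            - fitted_params.k_d * cs_grid
        valid = c_grid >= 0
        best = np.argmin(np.abs(np.where(valid, resid, np.inf)))
        assert cs_eq == pytest.approx(cs_grid[best], abs=2e-5)
        assert c_eq == pytest.approx(c_grid[best], rel=1e-4)
        # conservation and zero net flux hold exactly at the returned root
        assert geometry.volume_mL * c_eq + geometry.area_mm2 * cs_eq == pytest.approx(mass)


class TestSolver:
    def test_uniform_field_without_exchange_is_fixed_point(self, geometry, coarse_grid):
        p = ProteinParams(k_a=0.0, k_d=0.0, c_s_max=31.5)
        traj = solve_protein_kinetics(
            p, geometry, initial_fluid=1234.0, initial_surface=5.0,
            t_end=24.0, output_times=[0, 6, 12, 24], grid=coarse_grid,
        )
        assert np.allclose(traj.c, 1234.0, rtol=1e-12)
        assert np.allclose(traj.c_surface, 5.0, rtol=1e-12)

    def test_mass_ledger_and_bounds_desorption(self, fitted_params, geometry):
        traj = solve_protein_kinetics(
            fitted_params, geometry, initial_fluid=0.0, initial_surface=29.04,
            t_end=80.0,
        )
        drift = np.abs(traj.mass_total - traj.mass_total[0]) / traj.mass_total[0]
        assert np.max(drift) < 1e-3
        assert np.all(traj.c >= 0)
        assert np.all(traj.c_surface >= 0)
        assert np.all(traj.c_surface <= fitted_params.c_s_max)
        # pure desorption: coverage never increases
        assert np.all(np.diff(traj.c_surface) <= 1e-12)

    def test_fluid_loss_equals_surface_gain(self, fitted_params, geometry, coarse_grid):
        # asserts the ug/mL <-> ug/mm^3 conversion at the reactive boundary:
        # a wrong factor would desynchronise the two mass pools immediately
        traj = solve_protein_kinetics(
            fitted_params, geometry, initial_fluid=9500.0, initial_surface=0.0,
            t_end=8.0, output_times=np.linspace(0, 8, 17), grid=coarse_grid,
        )
        fluid_loss = (traj.mean_fluid[0] - traj.mean_fluid) * geometry.volume_mL
        surface_gain = traj.c_surface * geometry.area_mm2
        assert fluid_loss == pytest.approx(surface_gain, rel=1e-6)
        # pure adsorption: coverage never decreases
        assert np.all(np.diff(traj.c_surface) >= -1e-12)

    def test_long_time_limit_matches_closed_form(self, fitted_params, geometry, coarse_grid):
        traj = solve_protein_kinetics(
            fitted_params, geometry, initial_fluid=9500.0, initial_surface=0.0,
            t_end=500.0, output_times=[500.0], grid=coarse_grid,
        )
        c_eq, cs_eq = equilibrium_state(
            fitted_params, geometry, 9500.0 * geometry.volume_mL
        )
        assert traj.mean_fluid[-1] == pytest.approx(c_eq, rel=5e-3)
        assert traj.c_surface[-1] == pytest.approx(cs_eq, rel=5e-3)

    def test_grid_convergence(self, fitted_params, geometry, protein_schedule):
        base = solve_protein_kinetics(
            fitted_params, geometry, 9500.0, 0.0, t_end=72.0,
            output_times=protein_schedule, grid=GridControls(200, 0.05),
        )
        fine = solve_protein_kinetics(
            fitted_params, geometry, 9500.0, 0.0, t_end=72.0,
            output_times=protein_schedule, grid=GridControls(400, 0.025),
        )
        rel = np.abs(fine.mean_fluid - base.mean_fluid) / base.mean_fluid
        assert np.max(rel) < 5e-3

    def test_mixing_hook_preserves_mass_and_mean(self, fitted_params, geometry, coarse_grid):
        traj = solve_protein_kinetics(
            fitted_params, geometry, 0.0, 29.04, t_end=24.0,
            output_times=[2.0, 8.0, 24.0], grid=coarse_grid,
            mix_times=[2.0, 8.0],
        )
        drift = np.abs(traj.mass_total - traj.mass_total[0]) / traj.mass_total[0]
        assert np.max(drift) < 1e-3
        # immediately after a mix event the field is uniform
        assert np.ptp(traj.c[:, 0]) < 1e-9 * max(traj.mean_fluid[0], 1.0)

    def test_invalid_inputs_rejected(self, fitted_params, geometry, coarse_grid):
        with pytest.raises(ValueError):
            solve_protein_kinetics(fitted_params, geometry, -1.0, 0.0, t_end=1.0,
                                   grid=coarse_grid)
        with pytest.raises(ValueError):
            solve_protein_kinetics(fitted_params, geometry, 0.0, 40.0, t_end=1.0,
                                   grid=coarse_grid)  # above capacity
        with pytest.raises(ValueError):
            solve_protein_kinetics(fitted_params, geometry, 0.0, 1.0, t_end=-2.0)


class TestAverageSurfaceConcentration:
    def _traj(self, times, cs, geometry):
        times = np.asarray(times, float)
        cs = np.asarray(cs, float)
        nz = 4
        return ProteinTrajectory(
            times=times,
            z_grid=np.linspace(0, 1, nz),
            c=np.zeros((nz, times.size)),
            c_surface=cs,
            mean_fluid=np.zeros_like(times),
            mass_total=np.ones_like(times),
            geometry=geometry,
            params=ProteinParams(1e-4, 0.1, 30.0),
        )

    def test_constant_coverage(self, geometry):
        traj = self._traj([0, 1, 2, 3], [7.5, 7.5, 7.5, 7.5], geometry)
        assert average_surface_concentration(traj, (0.5, 2.5)) == pytest.approx(7.5)

    def test_linear_ramp_midpoint(self, geometry):
        t = np.linspace(0, 10, 11)
        traj = self._traj(t, t, geometry)
        assert average_surface_concentration(traj, (0.0, 10.0)) == pytest.approx(5.0)

    def test_window_validation(self, geometry):
        traj = self._traj([0, 1, 2], [1, 2, 3], geometry)
        with pytest.raises(ValueError):
            average_surface_concentration(traj, (1.0, 5.0))
        with pytest.raises(ValueError):
            average_surface_concentration(traj, (2.0, 2.0))
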