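"""Transport discretization and the coupled steady-state solver."""

from dataclasses import replace

import numpy as np
import pytest

from sedrtm import (RCMParams, analytic_toc_profile, integrate_rates,
                    site_config, solve_steady_state)
from sedrtm.core import Species, build_grid
from sedrtm.solver import SolverError
from sedrtm.transport import assemble_transport


@pytest.fixture(scope="module")
def quiet_config():
    """A station config with mixing and irrigation switched off."""
    cfg = site_config("B13")
    return replace(cfg, bioturbation_coeff=0.0, mixed_layer_depth=0.0,
                   bioirrigation_coeff=0.0)


class TestTransportOperator:
    def test_constant_profile_is_steady_for_conservative_tracer(self, quiet_config):
        # with a uniform concentration equal to the boundary value, diffusive,
        # irrigative and (divergence of) advective fluxes all vanish
        cfg = site_config("B13")
        grid = cfg.build_grid(n_nodes=120)
        sp = Species("NO3", "dissolved", 300.0, 0.012)
        op = assemble_transport(sp, grid, cfg)
        res = op.residual(np.full(grid.n_nodes, 0.012))
        assert np.abs(res).max() < 1e-12

    def test_solid_tracer_pure_advection_is_constant(self, quiet_config):
        grid = quiet_config.build_grid(n_nodes=120)
        sp = Species("MnO2", "solid", 0.0, 5.0)
        op = assemble_transport(sp, grid, quiet_config)
        c = op.solve_steady()
        assert np.allclose(c, 5.0, rtol=1e-12)

    def test_irrigation_vanishes_for_uniform_profile(self):
        cfg = site_config("B13")
        grid = cfg.build_grid(n_nodes=120)
        sp = Species("O2", "dissolved", 300.0, 0.1)
        op = assemble_transport(sp, grid, cfg)
        assert op.irrigation_exchange(np.full(grid.n_nodes, 0.1)) == pytest.approx(0.0)
        assert op.irrigation[0] > 0  # irrigation present for dissolved species

    def test_solids_have_no_irrigation(self):
        cfg = site_config("B13")
        grid = cfg.build_grid(n_nodes=120)
        sp = Species("FeOOH", "solid", 0.0, 100.0)
        op = assemble_transport(sp, grid, cfg)
        assert np.all(op.irrigation == 0.0)

    def test_unknown_flux_mode_rejected(self):
        cfg = site_config("B13")
        grid = cfg.build_grid(n_nodes=120)
        sp = Species("O2", "dissolved", 300.0, 0.1)
        with pytest.raises(ValueError):
            assemble_transport(sp, grid, cfg, bc_mode="nonsense")


class TestOMOnlySolution:
    def test_matches_unmixed_analytic_profile(self, quiet_config):
        cfg = replace(quiet_config, sedimentation_rate=0.05,
                      rcm=RCMParams(20.0, 0.15))
        sol = solve_steady_state(cfg, om_only=True)
        z = sol.grid.node_depths
        exact = analytic_toc_profile(cfg.rcm, 0.05, cfg.upper_bc["TOC"], z)
        assert np.max(np.abs(sol.toc - exact) / exact) < 0.01

    def test_mixing_enhances_degradation(self, quiet_config):
        mixed = site_config("B13")
        quiet = solve_steady_state(quiet_config, om_only=True)
        stirred = solve_steady_state(mixed, om_only=True)
        assert stirred.grid.integrate(stirred.r_c) > quiet.grid.integrate(quiet.r_c)


class TestCoupledSolver:
    def test_zero_om_flux_relaxes_to_boundary_values(self):
        cfg = site_config("B13")
        bc = dict(cfg.upper_bc)
        bc["TOC"] = 0.0
        cfg = replace(cfg, upper_bc=bc)
        sol = solve_steady_state(cfg, n_nodes=100, n_fractions=20)
        assert sol.r_c.max() == 0.0
        for name in ("O2", "NO3", "SO4"):
            c = sol.concentrations[name]
            assert np.allclose(c, cfg.upper_bc[name], rtol=1e-6, atol=1e-12)
        for rate in sol.pathway_rates.values():
            assert np.allclose(rate, 0.0)

    def test_converged_solution_is_nonnegative(self, b13_solution):
        assert b13_solution.converged
        assert b13_solution.residual_norm < 1e-8
        for name, c in b13_solution.concentrations.items():
            assert c.min() >= 0.0, name

    def test_oxygen_monotonically_depleted(self, b13_solution):
        o2 = b13_solution.concentrations["O2"]
        assert o2[0] == pytest.approx(0.1)  # 100 uM at the interface
        assert np.all(np.diff(o2) <= 1e-12)
        assert o2[-1] < 1e-6  # fully consumed within the domain

    def test_warm_start_reaches_same_solution(self, b13_solution,
                                              reduced_solver_opts):
        cfg = site_config("B13")
        cold = solve_steady_state(cfg, **reduced_solver_opts)
        warm_state = np.stack([cold.concentrations[s] for s in cold.operators])
        warm = solve_steady_state(cfg, initial_state=warm_state,
                                  **reduced_solver_opts)
        for name in cold.concentrations:
            assert np.allclose(warm.concentrations[name],
                               cold.concentrations[name], rtol=1e-5, atol=1e-10)

    def test_nonconvergence_raises_with_history(self):
        cfg = site_config("B13")
        with pytest.raises(SolverError) as err:
            solve_steady_state(cfg, n_nodes=100, n_fractions=20, max_iter=2)
        assert len(err.value.residual_history) >= 1

    def test_grid_refinement_converges(self):
        cfg = site_config("B13")
        coarse = integrate_rates(solve_steady_state(cfg, n_nodes=150,
                                                    n_fractions=100)).total
        fine = integrate_rates(solve_steady_state(cfg, n_nodes=300,
                                                  n_fractions=100)).total
        assert abs(fine - coarse) / coarse < 0.01
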