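"""Rate budgets, benthic flux decomposition and conservation checks."""

from dataclasses import replace

import numpy as np
import pytest

from sedrtm import (RCMParams, carbon_budget, integrate_rates, site_config,
                    solve_steady_state, species_balance, swi_fluxes)
from sedrtm.diagnostics import DiagnosticsError
from sedrtm.om_reactivity import MultiG
from sedrtm.reaction_network import PATHWAYS


class TestRateBudget:
    def test_carbon_closure(self, b13_solution):
        budget = carbon_budget(b13_solution)
        assert abs(budget["closure"]) / budget["deposition"] < 1e-3
        assert budget["deposition"] == pytest.approx(
            budget["degradation"] + budget["burial"], rel=1e-3)

    def test_contributions_sum_to_100(self, b13_solution):
        budget = integrate_rates(b13_solution)
        assert sum(budget.contributions_pct.values()) == pytest.approx(100.0, abs=0.1)
        assert all(v >= 0 for v in budget.by_pathway.values())

    def test_single_g_closed_form_column(self):
        # one dominant fraction, no mixing or irrigation: the depth-integrated
        # rate of a first-order column is F_dep * (1 - exp(-k L / omega))
        cfg = replace(site_config("B13"), bioturbation_coeff=0.0,
                      mixed_layer_depth=0.0, bioirrigation_coeff=0.0)
        k = 0.004
        mg = MultiG(k=np.array([k, 1e3 * k]), f=np.array([1.0 - 1e-12, 1e-12]),
                    params=cfg.rcm)
        grid = cfg.build_grid(n_nodes=400)
        sol = solve_steady_state(cfg, grid=grid, multig=mg, om_only=True)
        total = grid.integrate(sol.r_c)
        sigma_omega = (1 - grid.porosity[0]) * cfg.sedimentation_rate
        f_dep = sigma_omega * cfg.upper_bc["TOC"]
        expected = f_dep * (1.0 - np.exp(-k * grid.L / cfg.sedimentation_rate))
        assert total == pytest.approx(expected, rel=5e-3)

    def test_zero_degradation_flagged(self):
        cfg = site_config("B13")
        bc = dict(cfg.upper_bc)
        bc["TOC"] = 0.0
        sol = solve_steady_state(replace(cfg, upper_bc=bc), n_nodes=100,
                                 n_fractions=20)
        budget = integrate_rates(sol)
        assert budget.total == 0.0
        assert budget.contributions_pct is None

    def test_unconverged_solution_refused(self, b13_solution):
        broken = replace(b13_solution, converged=False)
        with pytest.raises(DiagnosticsError):
            integrate_rates(broken)

    def test_rate_increases_with_v_decreases_with_a(self):
        base = site_config("B13")
        def total(a, v):
            sol = solve_steady_state(replace(base, rcm=RCMParams(a, v)),
                                     om_only=True, n_nodes=120, n_fractions=60)
            return sol.grid.integrate(sol.r_c)
        mid = total(20.0, 0.15)
        assert total(20.0, 0.30) > mid > total(20.0, 0.075)
        assert total(10.0, 0.15) > mid > total(40.0, 0.15)


class TestFluxDecomposition:
    def test_components_sum_to_total(self, b13_solution):
        for sp in ("O2", "NO3", "NH4", "PO4", "Mn2", "Fe2", "SO4", "H2S"):
            flux = swi_fluxes(b13_solution, sp)
            assert flux.total == pytest.approx(
                sum(flux.components().values()), rel=1e-3, abs=1e-12)

    def test_absolute_shares_sum_to_100(self, b13_solution):
        flux = swi_fluxes(b13_solution, "NH4")
        assert sum(flux.shares_pct("absolute").values()) == pytest.approx(100.0)

    def test_unknown_species_rejected(self, b13_solution):
        with pytest.raises(KeyError):
            swi_fluxes(b13_solution, "Xe")

    def test_nutrient_efflux_positive(self, b13_solution):
        # degradation releases NH4 and PO4 at depth; both escape upward
        assert swi_fluxes(b13_solution, "NH4").total > 0
        assert swi_fluxes(b13_solution, "PO4").total > 0

    def test_oxygen_influx_negative(self, b13_solution):
        assert swi_fluxes(b13_solution, "O2").total < 0


class TestSpeciesBalance:
    @pytest.mark.parametrize("species", ["O2", "NO3", "NH4", "PO4", "Mn2",
                                         "Fe2", "SO4", "H2S", "MnO2", "FeOOH"])
    def test_closure_within_tolerance(self, b13_solution, species):
        bal = species_balance(b13_solution, species)
        scale = max(abs(bal["swi_influx"]), abs(bal["net_reaction"]),
                    abs(bal["burial_outflux"]), abs(bal["irrigation"]), 1e-10)
        assert abs(bal["closure"]) / scale < 1e-3
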