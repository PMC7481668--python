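"""Rate laws, pathway partitioning and stoichiometric bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedrtm.core import default_rate_constants
from sedrtm.reaction_network import (PATHWAYS, apply_sorption,
                                     nh4_retardation_factor,
                                     om_degradation_rate, partition_pathways,
                                     secondary_rates, species_sources,
                                     network_table, _IDX)

K = default_rate_constants()


class TestPathwayPartition:
    def test_oxygen_saturation_takes_all(self):
        p = partition_pathways({"O2": 1e3 * K["K_O2"]}, K)
        assert p["aerobic"] == pytest.approx(1.0, abs=1e-3)
        for other in PATHWAYS[1:]:
            assert p[other] < 2e-3

    def test_methanogenesis_is_residual(self):
        p = partition_pathways({}, K)
        assert p["methanogenesis"] == 1.0
        assert all(p[x] == 0.0 for x in PATHWAYS[:-1])

    def test_half_saturation_splits_evenly(self):
        p = partition_pathways({"O2": K["K_O2"]}, K)
        assert p["aerobic"] == pytest.approx(0.5)
        assert p["methanogenesis"] == pytest.approx(0.5)

    @given(st.lists(st.floats(0, 10.0), min_size=5, max_size=5))
    @settings(max_examples=80, deadline=None)
    def test_factors_sum_to_one_and_bounded(self, concs):
        names = ("O2", "NO3", "MnO2", "FeOOH", "SO4")
        p = partition_pathways(dict(zip(names, concs)), K)
        total = sum(p[x] for x in PATHWAYS)
        assert total == pytest.approx(1.0, abs=1e-9)
        for x in PATHWAYS:
            assert 0.0 <= p[x] <= 1.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            partition_pathways({"O2": -0.1}, K)


class TestDegradationRate:
    def test_first_order_single_fraction(self):
        # phi=0 so bulk and solid volumes coincide
        out = om_degradation_rate(np.array([100.0]), np.array([0.01]), 0.0)
        assert out["total"] == pytest.approx(1.0)

    def test_zero_om_zero_rate(self):
        out = om_degradation_rate(np.array([0.0]), np.array([0.5]), 0.5)
        assert out["total"] == 0.0

    def test_sum_of_fraction_products(self):
        out = om_degradation_rate(np.array([10.0, 1000.0]),
                                  np.array([0.1, 0.001]), 0.0)
        assert out["total"] == pytest.approx(2.0)

    def test_pathway_apportionment_conserves_total(self):
        part = partition_pathways({"O2": K["K_O2"], "SO4": 10.0}, K)
        out = om_degradation_rate(np.array([50.0, 50.0]),
                                  np.array([0.01, 0.1]), 0.4, part)
        summed = sum(out["by_pathway"][p] for p in PATHWAYS)
        assert summed == pytest.approx(out["total"], rel=1e-12)


class TestSecondaryRates:
    def test_zero_reductant_zero_rate(self):
        rates = secondary_rates({"NH4": 0.0, "O2": 0.2}, K)
        assert rates["nitrification"] == 0.0

    def test_bimolecular_product(self):
        rates = secondary_rates({"NH4": 0.01, "O2": 0.1},
                                {**K, "k_nit": 1e4})
        assert rates["nitrification"] == pytest.approx(10.0)

    @given(factor=st.sampled_from([2.0, 3.0]),
           which=st.sampled_from(["NH4", "O2"]))
    @settings(max_examples=10, deadline=None)
    def test_bilinearity(self, factor, which):
        base = {"NH4": 0.013, "O2": 0.07}
        r0 = secondary_rates(base, K)["nitrification"]
        scaled = dict(base)
        scaled[which] *= factor
        assert secondary_rates(scaled, K)["nitrification"] == \
            pytest.approx(factor * r0)

    def test_all_rates_nonnegative(self):
        state = {"O2": 0.1, "NH4": 0.05, "Mn2": 0.01, "Fe2": 0.02, "H2S": 0.03,
                 "MnO2": 10.0, "FeOOH": 50.0, "FeS": 5.0, "PO4": 0.01}
        for name, rate in secondary_rates(state, K).items():
            assert rate >= 0.0, name


class TestSorption:
    def test_no_sorption_identity(self):
        out = apply_sorption("NH4", 0.5, k_ads=0.0, phi=0.8)
        assert out["retardation"] == 1.0
        assert out["sorbed"] == 0.0

    def test_retardation_formula(self):
        assert nh4_retardation_factor(1.3, 0.8) == pytest.approx(1.0 + 1.3 * 0.25)

    def test_no_iron_no_p_adsorption(self):
        out = apply_sorption("PO4", 0.5, feooh=0.0, k_pfe_ads=0.1)
        assert out["adsorption_rate"] == 0.0


class TestStoichiometry:
    """Electron-acceptor bookkeeping at a single node."""

    def _sources_for(self, conc_overrides, r_c=1.0):
        state = np.zeros((12, 1))
        for name, val in conc_overrides.items():
            state[_IDX[name], 0] = val
        s, aux = species_sources(state, np.array([r_c]), K,
                                 redfield_n=16 / 106, redfield_p=1 / 106)
        return {n: s[i, 0] for n, i in _IDX.items()}, aux

    def test_aerobic_oxygen_one_to_one(self):
        s, aux = self._sources_for({"O2": 100.0})  # saturating O2, no NH4 yet
        assert aux["partition"]["aerobic"] == pytest.approx(1.0, abs=1e-3)
        assert s["O2"] == pytest.approx(-1.0, rel=1e-3)

    def test_denitrification_four_fifths(self):
        s, aux = self._sources_for({"NO3": 10.0})
        assert aux["partition"]["denitrification"] == pytest.approx(1.0, abs=1e-3)
        assert s["NO3"] == pytest.approx(-0.8, rel=2e-3)

    def test_sulfate_half_and_sulfide_release(self):
        s, aux = self._sources_for({"SO4": 1e4})
        assert s["SO4"] == pytest.approx(-0.5, rel=1e-3)
        assert s["H2S"] == pytest.approx(+0.5, rel=1e-3)

    def test_metal_oxide_ratios(self):
        s, _ = self._sources_for({"MnO2": 1e6})
        assert s["MnO2"] == pytest.approx(-2.0, rel=1e-3)
        assert s["Mn2"] == pytest.approx(+2.0, rel=1e-3)
        s, _ = self._sources_for({"FeOOH": 1e7})
        assert s["FeOOH"] == pytest.approx(-4.0, rel=1e-3)
        assert s["Fe2"] == pytest.approx(+4.0, rel=1e-3)

    def test_redfield_nutrient_release(self):
        s, _ = self._sources_for({}, r_c=106.0)
        assert s["NH4"] == pytest.approx(16.0)
        assert s["PO4"] == pytest.approx(1.0)

    def test_pathway_carbon_sums_to_total(self):
        state = np.abs(np.random.default_rng(0).normal(1.0, 0.5, (12, 7)))
        s, aux = species_sources(state, np.linspace(1, 2, 7), K,
                                 redfield_n=16 / 106, redfield_p=1 / 106)
        total = sum(aux["pathway_rates"][p] for p in PATHWAYS)
        assert np.allclose(total, np.linspace(1, 2, 7))


def test_network_table_renders():
    table = network_table()
    assert {"reaction", "rate_law", "stoichiometry", "constant"} <= set(table.columns)
    assert (table["rate_law"] == "primary").sum() == 6
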