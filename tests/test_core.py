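"""Units, configuration loading and grid construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedrtm.core import (ConfigurationError, GridError, MOLAR_MASS, Species,
                         build_grid, load_site_config, molar_to_wtpct,
                         molecular_diffusion, wtpct_to_molar)
from sedrtm.sites import site_document


class TestUnitConversions:
    @pytest.mark.parametrize("wt, mm, expected", [
        (2.21, 12.011, 4876.4),       # typical shelf TOC
        (0.0, 12.011, 0.0),
        (100.0, 12.011, 2.2064e5),    # pure carbon limit
    ])
    def test_wtpct_to_molar(self, wt, mm, expected):
        assert wtpct_to_molar(wt, mm) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            wtpct_to_molar(1.0, 0.0)

    @given(wt=st.floats(0, 100), mm=st.floats(1.0, 300.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_to_machine_precision(self, wt, mm):
        back = molar_to_wtpct(wtpct_to_molar(wt, mm), mm)
        assert back == pytest.approx(wt, rel=1e-12, abs=1e-12)


class TestDiffusionCoefficients:
    @given(t1=st.floats(-2.0, 20.0), dt=st.floats(0.1, 10.0),
           name=st.sampled_from(["O2", "NO3", "NH4", "PO4", "Mn2", "Fe2", "SO4", "H2S"]))
    @settings(max_examples=50, deadline=None)
    def test_monotonic_in_temperature(self, t1, dt, name):
        assert molecular_diffusion(name, t1 + dt) > molecular_diffusion(name, t1)

    def test_computed_at_site_temperature(self):
        # northernmost station: warm Atlantic-water intrusion at 1.75 C
        doc = site_document("B17")
        cfg = load_site_config(doc)
        reg = cfg.species_registry()
        assert cfg.bottom_temperature == 1.75
        assert cfg.bottom_salinity == 34.901
        expected = molecular_diffusion("O2", 1.75, 34.901)
        assert reg["O2"].molecular_diffusion_coeff == pytest.approx(expected)


class TestSiteConfigLoading:
    def test_station_document_echoes_boundary_values(self):
        cfg = load_site_config(site_document("B13"))
        assert cfg.upper_bc["TOC"] == pytest.approx(wtpct_to_molar(2.21, MOLAR_MASS["C"]))
        assert cfg.upper_bc["O2"] == pytest.approx(100e-3)
        assert cfg.upper_bc["NO3"] == pytest.approx(12e-3)
        assert cfg.upper_bc["SO4"] == pytest.approx(28.0)
        assert cfg.upper_bc["NH4"] == 0.0

    def test_missing_sedimentation_rate_named(self):
        doc = site_document("B13")
        del doc["sedimentation_rate_cm_yr"]
        with pytest.raises(ConfigurationError, match="sedimentation_rate"):
            load_site_config(doc)

    def test_missing_site_id_named(self):
        doc = site_document("B13")
        del doc["site_id"]
        with pytest.raises(ConfigurationError, match="site_id"):
            load_site_config(doc)

    def test_negative_concentration_rejected(self):
        doc = site_document("B13")
        doc["no3_um"] = -1.0
        with pytest.raises(ConfigurationError, match="no3_um"):
            load_site_config(doc)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        path = tmp_path / "site.yml"
        path.write_text(yaml.safe_dump(site_document("B14")))
        cfg = load_site_config(path)
        assert cfg.site_id == "B14"
        assert cfg.rcm.a == 20.0 and cfg.rcm.v == 0.090

    def test_defaults_logged(self, caplog):
        doc = site_document("B13")
        del doc["bioturbation_cm2_yr"]
        with caplog.at_level("WARNING", logger="sedrtm.core"):
            cfg = load_site_config(doc)
        assert cfg.bioturbation_coeff == 10.0
        assert any("bioturbation_cm2_yr" in r.message for r in caplog.records)


class TestSpecies:
    def test_solid_with_diffusion_rejected(self):
        with pytest.raises(ValueError):
            Species("MnO2", "solid", 100.0, 1.0)

    def test_negative_boundary_rejected(self):
        with pytest.raises(ValueError):
            Species("O2", "dissolved", 100.0, -1.0)


class TestGrid:
    def test_constant_porosity(self):
        g = build_grid(100.0, 200, porosity_surface=0.8)
        assert np.allclose(g.porosity, 0.8)

    def test_exponential_porosity_profile(self):
        g = build_grid(100.0, 200, porosity_surface=0.9, porosity_depth=0.7,
                       porosity_efold=5.0)
        assert g.porosity[0] == pytest.approx(0.9)
        assert g.porosity[-1] == pytest.approx(0.7, abs=1e-6)
        z = g.node_depths
        assert np.allclose(g.porosity, 0.7 + 0.2 * np.exp(-z / 5.0))

    def test_too_few_nodes_rejected(self):
        with pytest.raises(GridError):
            build_grid(100.0, 5)

    def test_refinement_rule_enforced(self):
        # enough nodes in absolute terms, but too coarse near the interface
        with pytest.raises(GridError):
            build_grid(100.0, 30, stretch=0.5)

    def test_surface_refinement(self):
        g = build_grid(100.0, 200)
        dz = np.diff(g.node_depths)
        assert np.all(dz[g.node_depths[:-1] < 2.0] < 0.25)

    def test_integral_of_constant(self):
        g = build_grid(100.0, 137)
        assert g.integrate(np.full(g.n_nodes, 3.7)) == pytest.approx(370.0, rel=1e-12)
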