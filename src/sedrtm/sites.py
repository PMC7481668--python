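"""Built-in station configurations for the Barents Sea 30E S-N transect.

The five stations (B13, southernmost, to B17, northernmost) span the Polar
Front and the summer sea-ice edge at ~300 m water depth.  Bottom-water
temperature/salinity/oxygen and the upper-boundary concentrations
prescribed at the sediment-water interface are transcribed station tables;
the reactivity parameters (a, v) are the best-fit values obtained by
inverse modelling of the summer 2017 porewater and solid-phase profiles.

Transport parameters shared across the transect are package defaults
chosen once (see docs/methods.md): burial velocity 0.06 cm/yr (upper end
of the site 210Pb estimates), constant porosity 0.55 (the value that makes
the carbon accumulation implied by the TOC boundary values and burial
velocity consistent with the transect's depth-integrated degradation
rates), mixed-layer bioturbation D_bio = 10 cm^2/yr over 3 cm, and a
global-compilation bioirrigation profile (alpha0 = 20/yr, 3 cm e-folding).

Secondary redox rate constants are site-specific where the observed
regimes require it (intense nitrification and P-Fe adsorption at the
central station B15; weak nitrification at B14 under low interface
oxygen), mirroring the study's calibration of these constants per site.
"""

from __future__ import annotations

from .core import SiteConfig, load_site_config

__all__ = ["SITE_IDS", "site_document", "site_config", "transect_configs"]

SITE_IDS = ("B13", "B14", "B15", "B16", "B17")

_SHARED = {
    "sedimentation_rate_cm_yr": 0.06,
    "bioturbation_cm2_yr": 10.0,
    "mixed_layer_cm": 3.0,
    "bioturbation_taper_cm": 2.0,
    "bioirrigation_yr": 20.0,
    "bioirrigation_depth_cm": 3.0,
    "porosity_surface": 0.55,
    "nh4_adsorption": 1.3,
}

# site -> (water depth m, bottom T degC, bottom S, bottom-water O2 uM)
_BOTTOM_WATER = {
    "B13": (355, 1.76, 35.014, 318.7),
    "B14": (290, 1.94, 35.010, 300.8),
    "B15": (330, -1.50, 34.900, 338.7),
    "B16": (294, -1.45, 34.682, 343.7),
    "B17": (291, 1.75, 34.901, 317.4),
}

# site -> upper boundary condition row:
# (TOC wt%, O2 uM at the SWI, NO3 uM, Mn wt%, Fe wt%, SO4 mM, NH4, PO4, Mn2+, Fe2+ uM)
_UPPER_BC = {
    "B13": (2.21, 100.0, 12.0, 0.04, 0.83, 28.0, 0.0, 0.0, 0.0, 0.0),
    "B14": (2.50, 50.0, 12.0, 0.11, 1.82, 28.0, 0.0, 0.0, 0.0, 0.0),
    "B15": (1.80, 75.0, 12.0, 0.48, 1.70, 28.0, 0.0, 0.0, 0.0, 0.0),
    "B16": (1.58, 200.0, 12.0, 0.63, 1.52, 28.0, 0.0, 0.0, 0.0, 0.0),
    "B17": (1.70, 125.0, 12.0, 0.62, 1.38, 28.0, 0.0, 0.0, 0.0, 0.0),
}

# site -> best-fit reactivity parameters (a yr, v dimensionless)
_RCM = {
    "B13": (20.0, 0.150),
    "B14": (20.0, 0.090),
    "B15": (100.0, 0.100),
    "B16": (10.0, 0.090),
    "B17": (20.0, 0.200),
}

# site-specific secondary rate-constant overrides
_RATE_OVERRIDES = {
    "B13": {},
    "B14": {"k_nit": 2.0e3, "k_pfe_ads": 0.01},
    "B15": {"k_nit": 5.0e4, "k_pfe_ads": 0.2},
    "B16": {"k_nit": 2.0e4, "k_pfe_ads": 0.1},
    "B17": {"k_nit": 1.0e4, "k_pfe_ads": 0.1},
}


def site_document(site_id: str) -> dict:
    """Raw configuration document (field units) for one built-in station."""
    if site_id not in SITE_IDS:
        raise KeyError(f"unknown site {site_id!r}; available: {SITE_IDS}")
    depth, temp, sal, _o2bw = _BOTTOM_WATER[site_id]
    toc, o2, no3, mn, fe, so4, nh4, po4, mn2, fe2 = _UPPER_BC[site_id]
    a, v = _RCM[site_id]
    doc = dict(_SHARED)
    doc.update({
        "site_id": site_id,
        "water_depth_m": depth,
        "bottom_temperature_c": temp,
        "bottom_salinity": sal,
        "toc_wtpct": toc, "o2_um": o2, "no3_um": no3,
        "mn_wtpct": mn, "fe_wtpct": fe, "so4_mm": so4,
        "nh4_um": nh4, "po4_um": po4, "mn2_um": mn2, "fe2_um": fe2,
        "rcm_a_yr": a, "rcm_v": v,
        "rate_constants": dict(_RATE_OVERRIDES[site_id]),
    })
    return doc


def site_config(site_id: str) -> SiteConfig:
    """Fully populated :class:`SiteConfig` for one built-in station."""
    return load_site_config(site_document(site_id))


def transect_configs() -> dict[str, SiteConfig]:
    """All five stations, south to north."""
    return {s: site_config(s) for s in SITE_IDS}
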