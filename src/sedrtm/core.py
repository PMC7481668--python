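"""Domain types, unit conventions, site configuration and the spatial grid.

Internal unit conventions used throughout the package:

* depth ``z`` in cm below the sediment-water interface (SWI), positive down;
* time in years;
* dissolved concentrations in umol per cm^3 of porewater
  (so 1 uM = 1e-3 umol/cm^3 and 1 mM = 1 umol/cm^3);
* solid concentrations in umol per cm^3 of solid phase;
* fluxes in umol per cm^2 of bulk sediment per year.

These conventions make the porosity weighting of the mass-conservation
equation explicit and deliver benthic fluxes directly in umol cm^-2 yr^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .om_reactivity import RCMParams

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "GridError",
    "Species",
    "SiteConfig",
    "SedimentGrid",
    "PARTICLE_DENSITY",
    "MOLAR_MASS",
    "wtpct_to_molar",
    "molar_to_wtpct",
    "molecular_diffusion",
    "tortuosity_sq",
    "build_grid",
    "load_site_config",
    "default_rate_constants",
]


class ConfigurationError(ValueError):
    """A site configuration document is missing or violates a required field."""


class GridError(ValueError):
    """The requested spatial grid cannot satisfy the resolution rules."""


#: Default particle (grain) density of the solid phase, g/cm^3.
PARTICLE_DENSITY = 2.65

#: Molar masses (g/mol) used for weight-percent conversions.
MOLAR_MASS = {"C": 12.011, "Mn": 54.938, "Fe": 55.845}

SECONDS_PER_YEAR = 3.15576e7

# Free-solution molecular diffusion coefficients for seawater, expressed as
# D0 = m0 + m1 * T with T in degrees C and D0 in 1e-6 cm^2/s (the standard
# linear-in-temperature empirical fits for S ~= 35 electrolytes).  The
# salinity dependence over the range encountered on shelf bottom waters
# (S = 34-35) is below 1% and is not modelled.
_DIFFUSION_LINEAR = {
    "O2": (11.70, 0.344),
    "NO3": (9.50, 0.388),
    "SO4": (4.88, 0.232),
    "NH4": (9.50, 0.413),
    "PO4": (3.26, 0.177),  # HPO4(2-), the dominant species near pH 7.5
    "Mn2": (3.04, 0.153),
    "Fe2": (3.31, 0.150),
    "H2S": (10.40, 0.273),
}


def molecular_diffusion(name: str, temperature_c: float, salinity: float = 35.0) -> float:
    """Free-solution molecular diffusion coefficient in cm^2/yr.

    Linear empirical temperature fits for seawater; ``salinity`` is accepted
    for interface completeness but the (sub-percent) salinity correction at
    S = 34-35 is neglected.
    """
    try:
        m0, m1 = _DIFFUSION_LINEAR[name]
    except KeyError:
        raise KeyError(f"no molecular diffusion coefficients tabulated for {name!r}")
    d0 = (m0 + m1 * temperature_c) * 1e-6  # cm^2/s
    return d0 * SECONDS_PER_YEAR


def tortuosity_sq(phi) -> np.ndarray | float:
    """Tortuosity squared, theta^2 = 1 - 2 ln(phi)."""
    return 1.0 - 2.0 * np.log(phi)


def wtpct_to_molar(wt_percent: float, molar_mass: float,
                   particle_density: float = PARTICLE_DENSITY) -> float:
    """Convert a solid-phase weight percent to umol per cm^3 of solid.

    ``wt_percent/100 * particle_density / molar_mass * 1e6``.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    wt = np.asarray(wt_percent, dtype=float)
    if np.any(wt < 0):
        raise ValueError("weight percent must be non-negative")
    out = wt / 100.0 * particle_density / molar_mass * 1e6
    return float(out) if out.ndim == 0 else out


def molar_to_wtpct(conc: float, molar_mass: float,
                   particle_density: float = PARTICLE_DENSITY) -> float:
    """Inverse of :func:`wtpct_to_molar` (umol/cm^3 solid -> weight percent)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    out = np.asarray(conc, dtype=float) * molar_mass / particle_density / 1e6 * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Species:
    """One transported species and its boundary/transport attributes."""

    name: str
    phase: str  # "solid" | "dissolved"
    molecular_diffusion_coeff: float  # cm^2/yr at in-situ T, S (0 for solids)
    upper_bc_value: float  # concentration in internal units
    sorption_coeff: float = 0.0  # dimensionless linear equilibrium constant

    def __post_init__(self) -> None:
        if self.phase not in ("solid", "dissolved"):
            raise ValueError(f"phase must be 'solid' or 'dissolved', got {self.phase!r}")
        if self.phase == "solid" and self.molecular_diffusion_coeff != 0:
            raise ValueError("solid species must have zero molecular diffusion")
        if self.molecular_diffusion_coeff < 0:
            raise ValueError("molecular diffusion coefficient must be >= 0")
        if self.upper_bc_value < 0:
            raise ValueError(f"upper boundary value of {self.name} must be >= 0")
        if self.sorption_coeff < 0:
            raise ValueError("sorption coefficient must be >= 0")


def default_rate_constants() -> dict[str, float]:
    """Kinetic and half-saturation constants with literature-typical defaults.

    Half-saturation (K_*) and inhibition (Kin_*) constants are in internal
    concentration units (umol/cm^3 porewater for dissolved electron
    acceptors, umol/cm^3 solid for the metal-oxide pools).  Bimolecular
    constants (k_*) are in cm^3 umol^-1 yr^-1 and produce rates per cm^3 of
    bulk sediment.  All are overridable per site: the study design requires
    site-specific secondary constants.
    """
    return {
        # Monod limitation / inhibition of the primary redox cascade
        "K_O2": 8e-3, "Kin_O2": 8e-3,          # 8 uM
        "K_NO3": 10e-3, "Kin_NO3": 10e-3,      # 10 uM
        "K_MnO2": 42.0, "Kin_MnO2": 42.0,      # ~16 umol/g at 2.65 g/cm^3
        "K_FeOOH": 265.0, "Kin_FeOOH": 265.0,  # ~100 umol/g
        "K_SO4": 1.6, "Kin_SO4": 1.6,          # 1.6 mM
        # secondary redox (bimolecular)
        "k_nit": 1.0e4,        # NH4+ + 2 O2 -> NO3-
        "k_mnox": 5.0e3,       # Mn2+ + 1/2 O2 -> MnO2
        "k_feox": 5.0e4,       # Fe2+ + 1/4 O2 -> FeOOH
        "k_feox_mno2": 10.0,   # Fe2+ + 1/2 MnO2 -> FeOOH + 1/2 Mn2+
        "k_sox_o2": 160.0,     # H2S + 2 O2 -> SO4
        "k_sox_mno2": 20.0,    # H2S + 4 MnO2 -> SO4 + 4 Mn2+
        "k_sox_feooh": 8.0,    # H2S + 8 FeOOH -> SO4 + 8 Fe2+
        # mineral precipitation / dissolution-free sinks
        "k_fes": 100.0,        # Fe2+ + H2S -> FeS
        "k_fes2": 0.0,         # Fe2+ + 2 H2S -> FeS2 (off by default)
        "k_fesox": 20.0,       # FeS + 2 O2 -> Fe2+ + SO4
        # phosphate-iron coupling
        "k_pfe_ads": 0.05,     # PO4 + FeOOH surface -> Fe-bound P
    }


@dataclass
class SedimentGrid:
    """Node-centred 1-D grid on [0, L], z positive downward from the SWI."""

    node_depths: np.ndarray  # cm, strictly increasing, node 0 at z=0, last at L
    cell_widths: np.ndarray  # cm, finite-volume cell width per node
    porosity: np.ndarray     # phi at nodes, in (0, 1)
    L: float                 # domain length, cm

    def __post_init__(self) -> None:
        z = np.asarray(self.node_depths, dtype=float)
        w = np.asarray(self.cell_widths, dtype=float)
        phi = np.asarray(self.porosity, dtype=float)
        self.node_depths, self.cell_widths, self.porosity = z, w, phi
        if np.any(np.diff(z) <= 0):
            raise GridError("node depths must be strictly increasing")
        if abs(z[0]) > 1e-12 or abs(z[-1] - self.L) > 1e-9:
            raise GridError("grid must span z=0 to z=L")
        if np.any(phi <= 0) or np.any(phi >= 1):
            raise GridError("porosity must lie strictly within (0, 1)")

    @property
    def n_nodes(self) -> int:
        return self.node_depths.size

    def integrate(self, values: np.ndarray) -> float:
        """Column integral of a per-node quantity using cell-width quadrature.

        This is the quadrature under which the finite-volume discretization
        conserves mass exactly; for a constant it returns L * constant to
        machine precision.
        """
        return float(np.asarray(values, dtype=float) @ self.cell_widths)


def _porosity_profile(z: np.ndarray, phi0: float, phi_inf: float, efold: float) -> np.ndarray:
    if not (0 < phi0 < 1 and 0 < phi_inf < 1):
        raise GridError("porosity must lie within (0, 1)")
    if phi0 == phi_inf:
        return np.full_like(z, phi0)
    if efold <= 0:
        raise GridError("porosity e-folding depth must be positive")
    return phi_inf + (phi0 - phi_inf) * np.exp(-z / efold)


def build_grid(L: float = 100.0, n_nodes: int = 200, porosity_surface: float = 0.55,
               porosity_depth: float | None = None, porosity_efold: float = 10.0,
               stretch: float = 5.0) -> SedimentGrid:
    """Build a surface-refined grid with an exponential porosity profile.

    Nodes are clustered towards the SWI by an exponential map so that the
    oxygen boundary layer is resolved: the spacing must be finer than
    0.25 cm everywhere in the top 2 cm, otherwise a :class:`GridError` is
    raised (increase ``n_nodes`` or ``stretch``).

    ``porosity_depth=None`` gives a constant profile at ``porosity_surface``.
    """
    if L <= 0:
        raise GridError("domain length must be positive")
    if n_nodes < 20:
        raise GridError(f"n_nodes must be at least 20, got {n_nodes}")
    s = np.linspace(0.0, 1.0, n_nodes)
    z = L * np.expm1(stretch * s) / np.expm1(stretch)
    z[0], z[-1] = 0.0, L
    dz = np.diff(z)
    top = dz[z[:-1] < 2.0]
    if top.size == 0 or np.any(top >= 0.25):
        raise GridError(
            "grid spacing in the top 2 cm must be finer than 0.25 cm; "
            f"n_nodes={n_nodes} with stretch={stretch} does not satisfy this"
        )
    faces = 0.5 * (z[:-1] + z[1:])
    edges = np.concatenate(([0.0], faces, [L]))
    widths = np.diff(edges)
    phi_inf = porosity_surface if porosity_depth is None else porosity_depth
    phi = _porosity_profile(z, porosity_surface, phi_inf, porosity_efold)
    return SedimentGrid(node_depths=z, cell_widths=widths, porosity=phi, L=L)


#: Species held in the reactive porewater/oxide subsystem, in solver order.
SUBSYSTEM_SPECIES = (
    "O2", "NO3", "SO4", "NH4", "PO4", "Mn2", "Fe2", "H2S",
    "MnO2", "FeOOH", "FeS", "PFe",
)

SOLID_SPECIES = ("MnO2", "FeOOH", "FeS", "PFe")


@dataclass
class SiteConfig:
    """All boundary conditions, transport parameters and rate constants for one station."""

    site_id: str
    sedimentation_rate: float                  # omega, cm/yr
    water_depth: float = 300.0                 # m
    bottom_temperature: float = 0.0            # degrees C
    bottom_salinity: float = 35.0
    bioturbation_coeff: float = 10.0           # D_bio, cm^2/yr in the mixed layer
    mixed_layer_depth: float = 3.0             # cm
    bioturbation_taper: float = 2.0            # cm, linear taper below the mixed layer
    bioirrigation_coeff: float = 20.0          # alpha0, 1/yr at the SWI
    bioirrigation_depth: float = 3.0           # e-folding depth of alpha(z), cm
    porosity_surface: float = 0.55
    porosity_depth: float | None = None        # None => constant profile
    porosity_efold: float = 10.0               # cm
    rcm: RCMParams = field(default_factory=lambda: RCMParams(a=20.0, v=0.15))
    upper_bc: dict[str, float] = field(default_factory=dict)  # internal units
    rate_constants: dict[str, float] = field(default_factory=default_rate_constants)
    nh4_adsorption: float = 1.3                # dimensionless linear K
    redfield_c: float = 106.0
    redfield_n: float = 16.0
    redfield_p: float = 1.0
    solid_bc_mode: str = "concentration"       # "concentration" | "flux"

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ConfigurationError("site_id is required")
        if not (self.sedimentation_rate > 0):
            raise ConfigurationError("sedimentation_rate must be positive")
        if self.mixed_layer_depth < 0:
            raise ConfigurationError("mixed_layer_depth must be >= 0")
        if not (0 < self.porosity_surface < 1):
            raise ConfigurationError("porosity must lie in (0, 1)")
        if self.porosity_depth is not None and not (0 < self.porosity_depth < 1):
            raise ConfigurationError("porosity must lie in (0, 1)")
        if self.solid_bc_mode not in ("concentration", "flux"):
            raise ConfigurationError("solid_bc_mode must be 'concentration' or 'flux'")
        for name, value in self.upper_bc.items():
            if value < 0:
                raise ConfigurationError(f"negative upper boundary value for {name}")

    def species_registry(self) -> dict[str, Species]:
        """Transported subsystem species with diffusion coefficients at in-situ T, S."""
        reg: dict[str, Species] = {}
        for name in SUBSYSTEM_SPECIES:
            solid = name in SOLID_SPECIES
            d = 0.0 if solid else molecular_diffusion(
                name, self.bottom_temperature, self.bottom_salinity)
            reg[name] = Species(
                name=name,
                phase="solid" if solid else "dissolved",
                molecular_diffusion_coeff=d,
                upper_bc_value=float(self.upper_bc.get(name, 0.0)),
                sorption_coeff=self.nh4_adsorption if name == "NH4" else 0.0,
            )
        return reg

    def build_grid(self, L: float = 100.0, n_nodes: int = 200,
                   stretch: float = 5.0) -> SedimentGrid:
        return build_grid(L=L, n_nodes=n_nodes,
                          porosity_surface=self.porosity_surface,
                          porosity_depth=self.porosity_depth,
                          porosity_efold=self.porosity_efold, stretch=stretch)


# External config keys, their SiteConfig destinations and unit conversions.
_REQUIRED_KEYS = ("site_id", "sedimentation_rate_cm_yr")
_UM = 1e-3  # uM -> umol/cm^3

_BC_KEYS = {
    # config key -> (species name, conversion to internal units)
    "o2_um": ("O2", _UM),
    "no3_um": ("NO3", _UM),
    "so4_mm": ("SO4", 1.0),
    "nh4_um": ("NH4", _UM),
    "po4_um": ("PO4", _UM),
    "mn2_um": ("Mn2", _UM),
    "fe2_um": ("Fe2", _UM),
    "h2s_um": ("H2S", _UM),
}

_DEFAULTED_FIELDS = {
    "water_depth_m": ("water_depth", 300.0),
    "bottom_temperature_c": ("bottom_temperature", 0.0),
    "bottom_salinity": ("bottom_salinity", 35.0),
    "bioturbation_cm2_yr": ("bioturbation_coeff", 10.0),
    "mixed_layer_cm": ("mixed_layer_depth", 3.0),
    "bioturbation_taper_cm": ("bioturbation_taper", 2.0),
    "bioirrigation_yr": ("bioirrigation_coeff", 20.0),
    "bioirrigation_depth_cm": ("bioirrigation_depth", 3.0),
    "porosity_surface": ("porosity_surface", 0.55),
    "porosity_efold_cm": ("porosity_efold", 10.0),
    "nh4_adsorption": ("nh4_adsorption", 1.3),
}


def load_site_config(document: Mapping | str | Path) -> SiteConfig:
    """Build a :class:`SiteConfig` from a configuration document.

    ``document`` may be a mapping or a path to a YAML file.  Keys use
    field units (uM, mM, wt%, cm/yr ...) and are converted to internal
    units; defaults are applied only to documented defaulted fields, with
    a logged warning naming each one.

    Raises :class:`ConfigurationError` naming the missing field if the
    site id or sedimentation rate is absent, and on negative concentrations.
    """
    if isinstance(document, (str, Path)):
        with open(document) as fh:
            document = yaml.safe_load(fh)
    if not isinstance(document, Mapping):
        raise ConfigurationError("configuration document must be a mapping")
    doc = dict(document)

    for key in _REQUIRED_KEYS:
        if key not in doc or doc[key] in (None, ""):
            raise ConfigurationError(f"missing required configuration field: {key!r}")

    kwargs: dict = {
        "site_id": str(doc["site_id"]),
        "sedimentation_rate": float(doc["sedimentation_rate_cm_yr"]),
    }
    for key, (attr, default) in _DEFAULTED_FIELDS.items():
        if key in doc and doc[key] is not None:
            kwargs[attr] = float(doc[key])
        else:
            logger.warning("site %s: %s not given, using default %s",
                           kwargs["site_id"], key, default)
    if doc.get("porosity_depth") is not None:
        kwargs["porosity_depth"] = float(doc["porosity_depth"])

    a = float(doc.get("rcm_a_yr", 20.0))
    v = float(doc.get("rcm_v", 0.15))
    kwargs["rcm"] = RCMParams(a=a, v=v)

    bc: dict[str, float] = {}
    for key, (species, factor) in _BC_KEYS.items():
        raw = float(doc.get(key, 0.0) or 0.0)
        if raw < 0:
            raise ConfigurationError(f"negative concentration for {key!r}")
        bc[species] = raw * factor
    for key, species, element in (("toc_wtpct", "TOC", "C"),
                                  ("mn_wtpct", "MnO2", "Mn"),
                                  ("fe_wtpct", "FeOOH", "Fe")):
        raw = float(doc.get(key, 0.0) or 0.0)
        if raw < 0:
            raise ConfigurationError(f"negative concentration for {key!r}")
        bc[species] = wtpct_to_molar(raw, MOLAR_MASS[element])
    bc.setdefault("FeS", 0.0)
    bc.setdefault("PFe", 0.0)
    kwargs["upper_bc"] = bc

    constants = default_rate_constants()
    constants.update({k: float(x) for k, x in (doc.get("rate_constants") or {}).items()})
    kwargs["rate_constants"] = constants
    if "solid_bc_mode" in doc:
        kwargs["solid_bc_mode"] = str(doc["solid_bc_mode"])
    return SiteConfig(**kwargs)
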