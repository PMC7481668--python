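"""Kinetic rate laws and stoichiometry of the sediment redox network.

Primary pathways oxidize organic carbon in thermodynamic ladder order
(aerobic respiration, denitrification, Mn-oxide reduction, Fe-oxide
reduction, sulfate reduction, methanogenesis).  Total carbon oxidation is
first order in the electron donor; the pathways only apportion it, through
a Monod limitation / inhibition cascade whose factors sum to one
(methanogenesis takes the residual).  Secondary reactions re-oxidize the
reduced products (NH4+, Mn2+, Fe2+, sulfide, FeS) and precipitate iron
sulfides; phosphate couples kinetically to the reactive Fe-oxide pool.

All reaction rates returned here are per cm^3 of bulk sediment per year.
Dissolved concentrations are umol/cm^3 porewater, solid concentrations
umol/cm^3 solid phase; the bimolecular constants absorb the phase factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAYS",
    "Reaction",
    "PathwayPartition",
    "partition_pathways",
    "om_degradation_rate",
    "secondary_rates",
    "nh4_retardation_factor",
    "apply_sorption",
    "species_sources",
    "network_table",
]

PATHWAYS = (
    "aerobic",
    "denitrification",
    "manganese_reduction",
    "iron_reduction",
    "sulfate_reduction",
    "methanogenesis",
)

# electron acceptor consumed per mol organic C oxidized, by pathway
ACCEPTOR_STOICH = {
    "aerobic": ("O2", 1.0),
    "denitrification": ("NO3", 0.8),
    "manganese_reduction": ("MnO2", 2.0),
    "iron_reduction": ("FeOOH", 4.0),
    "sulfate_reduction": ("SO4", 0.5),
    "methanogenesis": (None, 0.0),
}

# (acceptor species, limitation constant key, inhibition constant key) in ladder order
_LADDER = (
    ("O2", "K_O2", "Kin_O2"),
    ("NO3", "K_NO3", "Kin_NO3"),
    ("MnO2", "K_MnO2", "Kin_MnO2"),
    ("FeOOH", "K_FeOOH", "Kin_FeOOH"),
    ("SO4", "K_SO4", "Kin_SO4"),
)


@dataclass(frozen=True)
class Reaction:
    """One reaction of the network, for documentation and bookkeeping."""

    name: str
    rate_law: str  # "primary" | "bimolecular" | "precipitation" | "equilibrium_sorption"
    stoichiometry: dict[str, float]  # signed coefficients per species
    rate_constant: str  # name of the governing constant in the site config


@dataclass
class PathwayPartition:
    """Dimensionless pathway factors at one or more depth nodes.

    Each factor lies in [0, 1]; across pathways they sum to 1 because
    methanogenesis takes the residual of the Monod/inhibition cascade.
    """

    factors: dict[str, np.ndarray]

    def __getitem__(self, pathway: str) -> np.ndarray:
        return self.factors[pathway]

    def total(self) -> np.ndarray:
        return sum(self.factors.values())


def partition_pathways(concentrations: Mapping[str, np.ndarray | float],
                       constants: Mapping[str, float]) -> PathwayPartition:
    """Monod-limitation / inhibition cascade over the redox ladder.

    Pathway n receives ``C_n/(C_n+K_n) * prod_{m<n} Kin_m/(C_m+Kin_m)``;
    methanogenesis takes ``1 - sum`` so the factors always sum to one.
    Raises on negative concentrations.
    """
    conc = {name: np.asarray(concentrations.get(name, 0.0), dtype=float)
            for name, _, _ in _LADDER}
    for name, c in conc.items():
        if np.any(c < 0):
            raise ValueError(f"negative concentration for {name}")
    factors: dict[str, np.ndarray] = {}
    inhibition = 1.0
    for pathway, (name, k_key, kin_key) in zip(PATHWAYS[:-1], _LADDER):
        c = conc[name]
        limit = c / (c + constants[k_key])
        factors[pathway] = limit * inhibition
        inhibition = inhibition * (constants[kin_key] / (c + constants[kin_key]))
    used = sum(factors.values())
    factors["methanogenesis"] = np.clip(1.0 - used, 0.0, 1.0)
    return PathwayPartition(factors=factors)


def om_degradation_rate(g_fractions: np.ndarray, k_fractions: np.ndarray,
                        phi: np.ndarray | float,
                        partition: PathwayPartition | None = None) -> dict:
    """First-order multi-G carbon oxidation rates.

    Parameters
    ----------
    g_fractions:
        Per-fraction OM concentrations, shape (n_fractions,) or
        (n_fractions, n_nodes), umol C per cm^3 solid.
    k_fractions:
        Matching first-order constants, 1/yr.
    phi:
        Porosity (the solid-phase rate is weighted by 1-phi to express it
        per cm^3 of bulk sediment).
    partition:
        Optional pathway partition used to apportion the total.

    Returns a dict with ``per_fraction`` (umol C cm^-3 solid yr^-1),
    ``total`` (umol C cm^-3 bulk yr^-1) and, when a partition is given,
    ``by_pathway``.
    """
    g = np.asarray(g_fractions, dtype=float)
    if np.any(g < -1e-12):
        raise ValueError("fraction concentrations must be non-negative")
    k = np.asarray(k_fractions, dtype=float)
    per_fraction = (k * g.T).T  # broadcast along fractions axis
    total = (1.0 - np.asarray(phi, dtype=float)) * per_fraction.sum(axis=0)
    out = {"per_fraction": per_fraction, "total": total}
    if partition is not None:
        out["by_pathway"] = {p: partition[p] * total for p in PATHWAYS}
    return out


def secondary_rates(concentrations: Mapping[str, np.ndarray | float],
                    constants: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Bimolecular re-oxidation and precipitation rates, per cm^3 bulk per yr.

    Every rate is ``k * [reductant] * [oxidant]`` and therefore vanishes
    when either reactant does; negative inputs are clipped to zero so the
    laws stay one-sided during solver iterations.
    """
    def c(name):
        return np.maximum(np.asarray(concentrations.get(name, 0.0), dtype=float), 0.0)

    o2, nh4, mn2, fe2, h2s = c("O2"), c("NH4"), c("Mn2"), c("Fe2"), c("H2S")
    mno2, feooh, fes, po4 = c("MnO2"), c("FeOOH"), c("FeS"), c("PO4")
    return {
        "nitrification": constants["k_nit"] * nh4 * o2,
        "mn_oxidation": constants["k_mnox"] * mn2 * o2,
        "fe_oxidation": constants["k_feox"] * fe2 * o2,
        "fe_oxidation_mno2": constants["k_feox_mno2"] * fe2 * mno2,
        "h2s_oxidation_o2": constants["k_sox_o2"] * h2s * o2,
        "h2s_oxidation_mno2": constants["k_sox_mno2"] * h2s * mno2,
        "h2s_oxidation_feooh": constants["k_sox_feooh"] * h2s * feooh,
        "fes_precipitation": constants["k_fes"] * fe2 * h2s,
        "fes2_precipitation": constants["k_fes2"] * fe2 * h2s,
        "fes_oxidation": constants["k_fesox"] * fes * o2,
        "pfe_adsorption": constants["k_pfe_ads"] * po4 * feooh,
    }


def nh4_retardation_factor(k_ads: float, phi: np.ndarray | float) -> np.ndarray | float:
    """Linear-equilibrium ammonium retardation, 1 + K_ads (1-phi)/phi.

    With the dimensionless K_ads relating sorbed concentration per cm^3
    solid to dissolved concentration per cm^3 porewater.  K_ads = 0 leaves
    dissolved behaviour unchanged.
    """
    if k_ads < 0:
        raise ValueError("sorption coefficient must be >= 0")
    phi = np.asarray(phi, dtype=float)
    out = 1.0 + k_ads * (1.0 - phi) / phi
    return float(out) if out.ndim == 0 else out


def apply_sorption(species: str, dissolved_conc, *, k_ads: float = 0.0,
                   phi: float = 0.55, feooh=0.0,
                   k_pfe_ads: float = 0.0) -> dict:
    """Sorption bookkeeping for NH4+ (equilibrium) and PO4 (kinetic to Fe oxides).

    For NH4+ returns the retardation factor and the sorbed load per cm^3
    solid; for PO4 returns the kinetic adsorption rate onto the reactive
    Fe-oxide pool (zero whenever Fe(s) is zero).  Other species pass through
    unchanged.
    """
    c = np.maximum(np.asarray(dissolved_conc, dtype=float), 0.0)
    if species == "NH4":
        return {"retardation": nh4_retardation_factor(k_ads, phi),
                "sorbed": k_ads * c}
    if species == "PO4":
        return {"adsorption_rate": k_pfe_ads * c * np.asarray(feooh, dtype=float)}
    return {"retardation": 1.0, "sorbed": np.zeros_like(c)}


# index map for the solver's stacked state; mirrors core.SUBSYSTEM_SPECIES
_IDX = {n: i for i, n in enumerate(
    ("O2", "NO3", "SO4", "NH4", "PO4", "Mn2", "Fe2", "H2S",
     "MnO2", "FeOOH", "FeS", "PFe"))}


def species_sources(state: np.ndarray, r_c: np.ndarray, constants: Mapping[str, float],
                    redfield_n: float, redfield_p: float) -> tuple[np.ndarray, dict]:
    """Net reaction source for every subsystem species, per cm^3 bulk per yr.

    Parameters
    ----------
    state:
        Array (12, n_nodes) of subsystem concentrations in solver order.
    r_c:
        Total organic-carbon oxidation rate per node (umol C cm^-3 bulk yr^-1),
        fixed by the multi-G profiles.
    redfield_n, redfield_p:
        N:C and P:C release ratios of the degrading organic matter.

    Returns ``(sources, aux)`` where ``aux`` carries the pathway partition,
    per-pathway carbon rates and secondary rates for diagnostics.
    """
    conc = {name: state[i] for name, i in _IDX.items()}
    part = partition_pathways(
        {k: np.maximum(conc[k], 0.0) for k in ("O2", "NO3", "MnO2", "FeOOH", "SO4")},
        constants)
    rates = {p: part[p] * r_c for p in PATHWAYS}
    sec = secondary_rates(conc, constants)

    # reductive consumption of the FeOOH pool drives stoichiometric P release
    feooh_reduction = 4.0 * rates["iron_reduction"] + 8.0 * sec["h2s_oxidation_feooh"]
    pfe = np.maximum(conc["PFe"], 0.0)
    feooh_pool = np.maximum(conc["FeOOH"], 0.0)
    sec = dict(sec)
    # P:Fe ratio of the oxide-bound pool, capped well above any physical
    # loading so a vanishing FeOOH pool cannot make the release law stiff
    pfe_ratio = np.minimum(pfe / (feooh_pool + 1e-10), 10.0)
    sec["pfe_release"] = feooh_reduction * pfe_ratio

    s = np.zeros_like(state)
    s[_IDX["O2"]] = (-rates["aerobic"] - 2.0 * sec["nitrification"]
                     - 0.5 * sec["mn_oxidation"] - 0.25 * sec["fe_oxidation"]
                     - 2.0 * sec["h2s_oxidation_o2"] - 2.0 * sec["fes_oxidation"])
    s[_IDX["NO3"]] = -0.8 * rates["denitrification"] + sec["nitrification"]
    s[_IDX["SO4"]] = (-0.5 * rates["sulfate_reduction"] + sec["h2s_oxidation_o2"]
                      + sec["h2s_oxidation_mno2"] + sec["h2s_oxidation_feooh"]
                      + sec["fes_oxidation"])
    s[_IDX["NH4"]] = redfield_n * r_c - sec["nitrification"]
    s[_IDX["PO4"]] = redfield_p * r_c - sec["pfe_adsorption"] + sec["pfe_release"]
    s[_IDX["Mn2"]] = (2.0 * rates["manganese_reduction"] - sec["mn_oxidation"]
                      + 4.0 * sec["h2s_oxidation_mno2"]
                      + 0.5 * sec["fe_oxidation_mno2"])
    s[_IDX["Fe2"]] = (4.0 * rates["iron_reduction"] - sec["fe_oxidation"]
                      - sec["fe_oxidation_mno2"] + 8.0 * sec["h2s_oxidation_feooh"]
                      - sec["fes_precipitation"] - sec["fes2_precipitation"]
                      + sec["fes_oxidation"])
    s[_IDX["H2S"]] = (0.5 * rates["sulfate_reduction"] - sec["h2s_oxidation_o2"]
                      - sec["h2s_oxidation_mno2"] - sec["h2s_oxidation_feooh"]
                      - sec["fes_precipitation"] - 2.0 * sec["fes2_precipitation"])
    s[_IDX["MnO2"]] = (-2.0 * rates["manganese_reduction"] + sec["mn_oxidation"]
                       - 4.0 * sec["h2s_oxidation_mno2"]
                       - 0.5 * sec["fe_oxidation_mno2"])
    s[_IDX["FeOOH"]] = (-4.0 * rates["iron_reduction"] + sec["fe_oxidation"]
                        + sec["fe_oxidation_mno2"] - 8.0 * sec["h2s_oxidation_feooh"])
    s[_IDX["FeS"]] = sec["fes_precipitation"] - sec["fes_oxidation"]
    s[_IDX["PFe"]] = sec["pfe_adsorption"] - sec["pfe_release"]

    aux = {"partition": part, "pathway_rates": rates, "secondary_rates": sec}
    return s, aux


def network_table() -> pd.DataFrame:
    """Human-readable rendering of the reaction network."""
    rows = []
    for rxn in _REACTIONS:
        stoich = " ; ".join(f"{v:+g} {k}" for k, v in rxn.stoichiometry.items())
        rows.append({"reaction": rxn.name, "rate_law": rxn.rate_law,
                     "stoichiometry": stoich, "constant": rxn.rate_constant})
    return pd.DataFrame(rows)


_REACTIONS = (
    Reaction("aerobic_respiration", "primary",
             {"OM-C": -1, "O2": -1, "NH4": +16 / 106, "PO4": +1 / 106}, "K_O2"),
    Reaction("denitrification", "primary",
             {"OM-C": -1, "NO3": -0.8, "NH4": +16 / 106, "PO4": +1 / 106}, "K_NO3"),
    Reaction("manganese_reduction", "primary",
             {"OM-C": -1, "MnO2": -2, "Mn2": +2, "NH4": +16 / 106, "PO4": +1 / 106},
             "K_MnO2"),
    Reaction("iron_reduction", "primary",
             {"OM-C": -1, "FeOOH": -4, "Fe2": +4, "NH4": +16 / 106, "PO4": +1 / 106},
             "K_FeOOH"),
    Reaction("sulfate_reduction", "primary",
             {"OM-C": -1, "SO4": -0.5, "H2S": +0.5, "NH4": +16 / 106, "PO4": +1 / 106},
             "K_SO4"),
    Reaction("methanogenesis", "primary",
             {"OM-C": -1, "NH4": +16 / 106, "PO4": +1 / 106}, "residual"),
    Reaction("nitrification", "bimolecular", {"NH4": -1, "O2": -2, "NO3": +1}, "k_nit"),
    Reaction("mn_oxidation", "bimolecular", {"Mn2": -1, "O2": -0.5, "MnO2": +1}, "k_mnox"),
    Reaction("fe_oxidation", "bimolecular", {"Fe2": -1, "O2": -0.25, "FeOOH": +1}, "k_feox"),
    Reaction("fe_oxidation_mno2", "bimolecular",
             {"Fe2": -1, "MnO2": -0.5, "FeOOH": +1, "Mn2": +0.5}, "k_feox_mno2"),
    Reaction("h2s_oxidation_o2", "bimolecular", {"H2S": -1, "O2": -2, "SO4": +1}, "k_sox_o2"),
    Reaction("h2s_oxidation_mno2", "bimolecular",
             {"H2S": -1, "MnO2": -4, "SO4": +1, "Mn2": +4}, "k_sox_mno2"),
    Reaction("h2s_oxidation_feooh", "bimolecular",
             {"H2S": -1, "FeOOH": -8, "SO4": +1, "Fe2": +8}, "k_sox_feooh"),
    Reaction("fes_precipitation", "precipitation", {"Fe2": -1, "H2S": -1, "FeS": +1}, "k_fes"),
    Reaction("fes2_precipitation", "precipitation", {"Fe2": -1, "H2S": -2}, "k_fes2"),
    Reaction("fes_oxidation", "bimolecular",
             {"FeS": -1, "O2": -2, "Fe2": +1, "SO4": +1}, "k_fesox"),
    Reaction("pfe_adsorption", "precipitation", {"PO4": -1, "PFe": +1}, "k_pfe_ads"),
    Reaction("pfe_release", "bimolecular", {"PFe": -1, "PO4": +1}, "coupled to FeOOH reduction"),
    Reaction("nh4_sorption", "equilibrium_sorption", {"NH4": 0}, "nh4_adsorption"),
)
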