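"""Depth-integrated rate budgets and sediment-water interface fluxes.

Sign convention: a positive benthic flux is an efflux out of the sediment
into the bottom water.  Flux components follow the conservation equation:
molecular diffusion ``-phi D/theta^2 dC/dz`` at z=0, bioturbation
``-sigma D_bio dC/dz`` at z=0, advection ``-sigma omega C(0)`` (burial
removes material, hence a negative efflux), and bioirrigation as the
column-integrated nonlocal exchange ``integral phi alpha (C(z) - C(0)) dz``
counted as an interface exchange term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reaction_network import PATHWAYS
from .solver import SteadyStateSolution

__all__ = ["DiagnosticsError", "RateBudget", "FluxDecomposition",
           "integrate_rates", "swi_fluxes", "carbon_budget", "species_balance",
           "budget_table"]


class DiagnosticsError(RuntimeError):
    """Raised when diagnostics are requested from an unusable solution."""


@dataclass
class RateBudget:
    """Depth-integrated organic-carbon degradation over the model domain."""

    total: float                        # umol C cm^-2 yr^-1 over [0, L]
    by_pathway: dict[str, float]        # same units
    contributions_pct: dict[str, float] | None  # None when total is zero

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in PATHWAYS:
            rows.append({
                "pathway": p,
                "rate_umol_C_cm2_yr": self.by_pathway[p],
                "contribution_pct": (np.nan if self.contributions_pct is None
                                     else self.contributions_pct[p]),
            })
        return pd.DataFrame(rows)


@dataclass
class FluxDecomposition:
    """Benthic flux of one species split by transport mechanism."""

    species: str
    total: float
    advection: float
    diffusion: float
    bioturbation: float
    bioirrigation: float

    def components(self) -> dict[str, float]:
        return {"advection": self.advection, "diffusion": self.diffusion,
                "bioturbation": self.bioturbation,
                "bioirrigation": self.bioirrigation}

    def shares_pct(self, mode: str = "absolute") -> dict[str, float]:
        """Percentage share per component.

        ``mode="absolute"`` normalizes by the sum of absolute component
        values (robust when components oppose); ``mode="signed"``
        normalizes by the signed total.
        """
        comps = self.components()
        if mode == "absolute":
            denom = sum(abs(v) for v in comps.values())
            return {k: (100.0 * abs(v) / denom if denom else np.nan)
                    for k, v in comps.items()}
        if mode == "signed":
            denom = self.total
            return {k: (100.0 * v / denom if denom else np.nan)
                    for k, v in comps.items()}
        raise ValueError("mode must be 'absolute' or 'signed'")


def _require_converged(solution: SteadyStateSolution) -> None:
    if not solution.converged:
        raise DiagnosticsError(
            f"solution for {solution.config.site_id} is not converged "
            f"(residual {solution.residual_norm:.3e})")


def integrate_rates(solution: SteadyStateSolution,
                    depth_limit: float | None = None) -> RateBudget:
    """Depth-integrate the per-pathway carbon oxidation rates.

    Rates are per cm^3 of bulk sediment, so the column integral uses the
    finite-volume cell widths directly (the quadrature under which the
    discrete solution conserves carbon exactly).  ``depth_limit``
    restricts the integral to the uppermost part of the column; default is
    the whole domain.
    """
    _require_converged(solution)
    grid = solution.grid
    weights = grid.cell_widths.copy()
    if depth_limit is not None:
        edges = np.concatenate(([0.0], np.cumsum(weights)))
        clipped = np.clip(edges, None, depth_limit)
        weights = np.diff(clipped)
    by_pathway = {p: float(solution.pathway_rates[p] @ weights) for p in PATHWAYS}
    total = float(sum(by_pathway.values()))
    if total > 0:
        contributions = {p: 100.0 * by_pathway[p] / total for p in PATHWAYS}
    else:
        contributions = None
    return RateBudget(total=total, by_pathway=by_pathway,
                      contributions_pct=contributions)


def swi_fluxes(solution: SteadyStateSolution, species: str) -> FluxDecomposition:
    """Decompose the benthic flux of one species at the SWI.

    Gradients are evaluated one-sided over the first grid interval (the
    grid is refined to ~0.02 cm there).  Positive values are effluxes to
    the bottom water.
    """
    _require_converged(solution)
    if species == "TOC":
        op = solution.om_operators[0]
        c = solution.toc
        # rebuild a bulk operator view from the first fraction's coefficients:
        # all fractions share transport, so faces scale with concentration
        sigma0 = op.sigma[0]
        grid = solution.grid
        dz0 = grid.node_depths[1] - grid.node_depths[0]
        grad = (c[1] - c[0]) / dz0
        dbio = op.d_face_bio[0]
        return FluxDecomposition(
            species="TOC",
            total=float(dbio * grad - sigma0 * solution.config.sedimentation_rate * c[0]),
            advection=float(-sigma0 * solution.config.sedimentation_rate * c[0]),
            diffusion=0.0,
            bioturbation=float(dbio * grad),
            bioirrigation=0.0)
    try:
        op = solution.operators[species]
        c = solution.concentrations[species]
    except KeyError:
        raise KeyError(f"unknown species {species!r}")
    grid = solution.grid
    config = solution.config
    phi0 = grid.porosity[0]
    dz0 = grid.node_depths[1] - grid.node_depths[0]
    grad = (c[1] - c[0]) / dz0

    sp = config.species_registry()[species]
    if sp.phase == "dissolved":
        from .core import tortuosity_sq
        d_mol = sp.molecular_diffusion_coeff / tortuosity_sq(phi0)
        diffusion = phi0 * d_mol * grad
        sigma0 = phi0
    else:
        diffusion = 0.0
        sigma0 = 1.0 - phi0
    from .transport import bioturbation_profile
    dbio0 = bioturbation_profile(np.array([0.0]), config)[0]
    # sorbed load of equilibrium-sorbing species rides on the solid phase
    sorb = sp.sorption_coeff * (1.0 - phi0) if sp.phase == "dissolved" else 0.0
    bioturbation = (sigma0 if sp.phase == "solid" else phi0 + sorb) * dbio0 * grad
    advection = -(sigma0 + sorb) * config.sedimentation_rate * c[0]
    irrigation = float(grid.integrate(op.irrigation * (c - op.c0)))
    total = diffusion + bioturbation + advection + irrigation
    return FluxDecomposition(species=species, total=float(total),
                             advection=float(advection), diffusion=float(diffusion),
                             bioturbation=float(bioturbation),
                             bioirrigation=float(irrigation))


def carbon_budget(solution: SteadyStateSolution) -> dict[str, float]:
    """Global steady-state carbon balance: deposition = degradation + burial.

    Computed from the discrete face fluxes of every organic-matter
    fraction, so closure holds to solver precision.  All terms in
    umol C cm^-2 yr^-1, positive into/within the sediment column.
    """
    _require_converged(solution)
    grid = solution.grid
    w = grid.cell_widths
    phi = grid.porosity
    deposition = 0.0
    burial = 0.0
    degradation = 0.0
    for op, ki, g in zip(solution.om_operators, solution.multig.k,
                         solution.g_fractions):
        rate = (1.0 - phi) * ki * g
        degradation += float(rate @ w)
        if op.bc_mode == "flux":
            deposition += op.deposition_flux
        else:
            # flux across the first interior face plus degradation in the
            # half-cell behind the fixed-concentration node
            deposition += float(op.face_fluxes(g)[0] + rate[0] * w[0])
        burial += float(op.sigma[-1] * solution.config.sedimentation_rate * g[-1])
    return {"deposition": deposition, "degradation": degradation,
            "burial": burial,
            "closure": deposition - degradation - burial}


def species_balance(solution: SteadyStateSolution, species: str) -> dict[str, float]:
    """Discrete steady-state balance of one subsystem species.

    Returns influx across the SWI face, irrigation column exchange, net
    reaction source and burial outflux, whose sum is the closure residual
    (zero to solver precision).  Positive terms add material to the column.
    """
    _require_converged(solution)
    op = solution.operators[species]
    c = solution.concentrations[species]
    grid = solution.grid
    w = grid.cell_widths

    from . import reaction_network as rn
    state = np.stack([solution.concentrations[s] for s in solution.operators])
    src, _ = rn.species_sources(
        state, solution.r_c, solution.config.rate_constants,
        redfield_n=solution.config.redfield_n / solution.config.redfield_c,
        redfield_p=solution.config.redfield_p / solution.config.redfield_c)
    source = src[list(solution.operators).index(species)]

    # summing the conservative rows i>=1 (weighted by cell width) telescopes
    # the face fluxes, so the closure below holds to solver precision
    irr_cell = op.irrigation * (op.c0 - c) * w
    src_cell = source * w
    if op.bc_mode == "dirichlet":
        influx = float(op.face_fluxes(c)[0])
        irrigation = float(irr_cell[1:].sum())
        reaction = float(src_cell[1:].sum())
    else:
        influx = op.deposition_flux
        irrigation = float(irr_cell.sum())
        reaction = float(src_cell.sum())
    burial = float(op.bottom_outflux_coeff * c[-1])
    closure = influx + irrigation + reaction - burial
    return {"swi_influx": influx, "irrigation": irrigation,
            "net_reaction": reaction, "burial_outflux": burial,
            "closure": closure}


def budget_table(solutions: dict[str, SteadyStateSolution]) -> pd.DataFrame:
    """Site summary mirroring the reactivity/flux table layout."""
    rows = []
    for site, sol in solutions.items():
        budget = integrate_rates(sol)
        jnh4 = swi_fluxes(sol, "NH4")
        jpo4 = swi_fluxes(sol, "PO4")
        rcm = sol.config.rcm
        rows.append({
            "site": site, "a_yr": rcm.a, "v": rcm.v, "k_swi_per_yr": rcm.k_swi,
            "sum_R_Corg_umol_C_cm2_yr": budget.total,
            "J_NH4_umol_cm2_yr": jnh4.total,
            "J_PO4_umol_cm2_yr": jpo4.total,
        })
    return pd.DataFrame(rows)
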