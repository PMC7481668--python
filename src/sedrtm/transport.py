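"""Finite-volume discretization of 1-D sediment transport.

Each species obeys the porosity-weighted conservation law

    d(sigma C)/dt = d/dz( sigma (D_bio + D_i/theta^2) dC/dz ) - d(sigma w C)/dz
                    + alpha(z) phi (C0 - C) + sum_j s_ij R_j,

with sigma = phi for dissolved species and 1-phi for solids, molecular
diffusion D_i tortuosity-corrected by theta^2 = 1 - 2 ln phi, burial
velocity w (constant omega), bioturbation D_bio constant in the mixed layer
with a linear taper below, and nonlocal bioirrigation exchange against the
bottom-water concentration C0 (dissolved species only).

Discretization: flux-divergence finite volumes on the (possibly stretched)
node grid, diffusive face fluxes centred, advection upwinded (flow is
downward).  The upper boundary is a fixed concentration at the SWI node
(or a prescribed deposition flux for solids in flux mode); the lower
boundary is zero diffusive gradient with advective outflow.

The steady transport residual for a profile C is ``A @ C + b`` where rows
1..N-1 are flux divergences per unit bulk volume (umol cm^-3 yr^-1) and
row 0 encodes the boundary condition.  For equilibrium-sorbing dissolved
species (NH4+), the sorbed load K_ads * C rides on the solid phase and is
bioturbated and buried; the corresponding solid-phase operator is added to
the dissolved one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solve_banded

from .core import SedimentGrid, SiteConfig, Species, tortuosity_sq

__all__ = ["TransportOperator", "assemble_transport", "bioturbation_profile",
           "bioirrigation_profile"]


def bioturbation_profile(z: np.ndarray, config: SiteConfig) -> np.ndarray:
    """D_bio(z): constant in the mixed layer, linear taper to zero below."""
    zml, taper = config.mixed_layer_depth, config.bioturbation_taper
    if zml <= 0:
        return np.zeros_like(z)
    if taper <= 0:
        return np.where(z <= zml, config.bioturbation_coeff, 0.0)
    frac = np.clip((zml + taper - z) / taper, 0.0, 1.0)
    frac = np.where(z <= zml, 1.0, frac)
    return config.bioturbation_coeff * frac


def bioirrigation_profile(z: np.ndarray, config: SiteConfig) -> np.ndarray:
    """alpha(z) = alpha0 * exp(-z / z_irr), 1/yr."""
    if config.bioirrigation_coeff <= 0:
        return np.zeros_like(z)
    return config.bioirrigation_coeff * np.exp(-z / config.bioirrigation_depth)


@dataclass
class TransportOperator:
    """Banded steady-transport operator and flux bookkeeping for one species."""

    species: str
    phase: str
    grid: SedimentGrid
    lower: np.ndarray     # sub-diagonal coefficients (length N, lower[0] unused)
    diag: np.ndarray
    upper: np.ndarray     # super-diagonal (upper[-1] unused)
    rhs: np.ndarray       # b in residual = A C + b
    d_face: np.ndarray    # sigma-weighted total diffusivity at interior faces (N-1)
    d_face_bio: np.ndarray    # bioturbation part of d_face
    adv_face: np.ndarray  # sigma*omega at interior faces (N-1)
    irrigation: np.ndarray    # phi * alpha at nodes (zero for solids)
    c0: float             # bottom-water / upper-boundary concentration
    bc_mode: str          # "dirichlet" | "flux"
    deposition_flux: float  # prescribed flux in flux mode (umol cm^-2 yr^-1)
    sigma: np.ndarray     # porosity weighting at nodes
    bottom_outflux_coeff: float = 0.0  # advective outflow = coeff * C[-1]

    @property
    def n(self) -> int:
        return self.grid.n_nodes

    def residual(self, c: np.ndarray, decay: np.ndarray | float = 0.0) -> np.ndarray:
        """A C + b, optionally with a linear first-order decay sink."""
        r = self.matvec(c) + self.rhs
        dec = np.broadcast_to(np.asarray(decay, dtype=float), c.shape).copy()
        dec *= self.sigma * c
        if self.bc_mode == "dirichlet":
            dec[0] = 0.0
        return r - dec

    def matvec(self, c: np.ndarray) -> np.ndarray:
        out = self.diag * c
        out[1:] += self.lower[1:] * c[:-1]
        out[:-1] += self.upper[:-1] * c[1:]
        return out

    def banded(self, decay: np.ndarray | float = 0.0) -> np.ndarray:
        """(3, N) banded form for scipy.linalg.solve_banded, including decay."""
        ab = np.zeros((3, self.n))
        ab[0, 1:] = self.upper[:-1]
        ab[1, :] = self.diag
        ab[2, :-1] = self.lower[1:]
        dec = np.broadcast_to(np.asarray(decay, dtype=float), (self.n,)).copy()
        dec = dec * self.sigma
        if self.bc_mode == "dirichlet":
            dec[0] = 0.0
        ab[1, :] -= dec
        return ab

    def solve_steady(self, decay: np.ndarray | float = 0.0) -> np.ndarray:
        """Solve the linear steady state A C + b - decay*sigma*C = 0."""
        return solve_banded((1, 1), self.banded(decay), -self.rhs)

    def to_sparse(self) -> sparse.csr_matrix:
        return sparse.diags_array(
            [self.lower[1:], self.diag, self.upper[:-1]], offsets=[-1, 0, 1],
            format="csr")

    def face_fluxes(self, c: np.ndarray) -> np.ndarray:
        """Advective-diffusive flux at the N-1 interior faces, positive downward."""
        z = self.grid.node_depths
        grad = np.diff(c) / np.diff(z)
        return -self.d_face * grad + self.adv_face * c[:-1]

    def irrigation_exchange(self, c: np.ndarray) -> float:
        """Column-integrated irrigation uptake, positive into the sediment."""
        return self.grid.integrate(self.irrigation * (self.c0 - c))


def assemble_transport(species: Species, grid: SedimentGrid, config: SiteConfig,
                       bc_mode: str | None = None,
                       deposition_flux: float | None = None) -> TransportOperator:
    """Assemble the steady transport operator for one species on a grid.

    ``bc_mode`` defaults to a fixed concentration at the SWI node; solids
    may instead use ``"flux"`` with a prescribed ``deposition_flux``
    (umol cm^-2 yr^-1, positive into the sediment).
    """
    z = grid.node_depths
    phi = grid.porosity
    n = grid.n_nodes
    omega = config.sedimentation_rate

    solid = species.phase == "solid"
    sigma = (1.0 - phi) if solid else phi
    dbio = bioturbation_profile(z, config)
    if solid:
        d_node = sigma * dbio
        d_bio_node = d_node
        irrigation = np.zeros(n)
    else:
        d_mol = species.molecular_diffusion_coeff / tortuosity_sq(phi)
        d_node = sigma * (dbio + d_mol)
        d_bio_node = sigma * dbio
        irrigation = phi * bioirrigation_profile(z, config)

    # NH4-type equilibrium sorption: the sorbed load K*C is carried by the
    # solid phase, adding (1-phi)*K-weighted bioturbation and burial.
    if not solid and species.sorption_coeff > 0:
        ksorb = species.sorption_coeff * (1.0 - phi)
        d_node = d_node + ksorb * dbio
        d_bio_node = d_bio_node + ksorb * dbio
        adv_sigma = sigma + ksorb
    else:
        adv_sigma = sigma

    dz = np.diff(z)
    d_face = 0.5 * (d_node[:-1] + d_node[1:])
    d_face_bio = 0.5 * (d_bio_node[:-1] + d_bio_node[1:])
    adv_face = 0.5 * (adv_sigma[:-1] + adv_sigma[1:]) * omega
    w = grid.cell_widths

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = np.zeros(n)

    # interior rows: (F_{i-1/2} - F_{i+1/2}) / w_i with face flux
    # F_j = -dcoef_j (C_{j+1} - C_j) + adv_face_j C_j (upwind, flow downward)
    dcoef = d_face / dz
    lower[1:] += (dcoef + adv_face) / w[1:]
    diag[1:-1] += (-dcoef[:-1] - dcoef[1:] - adv_face[1:]) / w[1:-1]
    upper[1:-1] += dcoef[1:] / w[1:-1]
    # bottom row: (F_{n-2} - F_out)/w, F_out = sigma*omega*C_{n-1} (outflow)
    diag[-1] += (-dcoef[-1] - adv_sigma[-1] * omega) / w[-1]
    # irrigation exchange
    diag -= irrigation
    rhs += irrigation * species.upper_bc_value

    mode = bc_mode or ("flux" if (solid and config.solid_bc_mode == "flux") else "dirichlet")
    if mode == "dirichlet":
        lower[0] = 0.0
        diag[0] = 1.0
        upper[0] = 0.0
        rhs[0] = -species.upper_bc_value
        flux_in = 0.0
    elif mode == "flux":
        if deposition_flux is None:
            raise ValueError("flux boundary mode requires a deposition_flux")
        # half-cell conservation at the top node: (F_dep - F_0)/w_0
        diag[0] = (-d_face[0] / dz[0] - adv_face[0]) / w[0]
        upper[0] = d_face[0] / dz[0] / w[0]
        rhs[0] = rhs[0] + deposition_flux / w[0]
        flux_in = float(deposition_flux)
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")

    return TransportOperator(
        species=species.name, phase=species.phase, grid=grid,
        lower=lower, diag=diag, upper=upper, rhs=rhs,
        d_face=d_face, d_face_bio=d_face_bio, adv_face=adv_face,
        irrigation=irrigation, c0=species.upper_bc_value, bc_mode=mode,
        deposition_flux=flux_in, sigma=sigma,
        bottom_outflux_coeff=float(adv_sigma[-1] * omega))
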