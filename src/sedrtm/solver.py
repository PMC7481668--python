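"""Coupled nonlinear steady-state solution of the diagenetic model.

Strategy
--------
Because total organic-carbon oxidation is first order in the electron
donor and the pathway partition always sums to one, the multi-G organic
matter profiles decouple from the porewater chemistry: each of the
``n_fractions`` fraction profiles solves an independent *linear*
advection-diffusion-decay problem (one banded solve each).  The resulting
carbon oxidation rate profile R_C(z) then drives the coupled nonlinear
subsystem of dissolved species and reactive solid pools (12 species),
which is solved by a damped, projected Newton iteration on the stacked
state with an exact transport Jacobian and per-node finite-difference
reaction Jacobian blocks; a pseudo-transient continuation step is used as
a fallback whenever the Newton direction fails to reduce the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import reaction_network as rn
from .core import (SUBSYSTEM_SPECIES, MOLAR_MASS, SedimentGrid, SiteConfig,
                   Species, molar_to_wtpct)
from .om_reactivity import MultiG, discretize_rcm
from .transport import TransportOperator, assemble_transport

logger = logging.getLogger(__name__)

__all__ = ["SolverError", "SteadyStateSolution", "solve_steady_state"]


class SolverError(RuntimeError):
    """Raised when the nonlinear solve does not converge within budget."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


@dataclass
class SteadyStateSolution:
    """Converged concentration and rate profiles on the grid."""

    config: SiteConfig
    grid: SedimentGrid
    multig: MultiG
    g_fractions: np.ndarray          # (n_fractions, n_nodes), umol C / cm^3 solid
    concentrations: dict[str, np.ndarray]  # per species, internal units
    pathway_rates: dict[str, np.ndarray]   # umol C / cm^3 bulk / yr
    secondary_rates: dict[str, np.ndarray]
    r_c: np.ndarray                  # total C oxidation, umol C / cm^3 bulk / yr
    partition: rn.PathwayPartition
    operators: dict[str, TransportOperator]
    om_operators: list[TransportOperator]
    residual_norm: float
    iterations: int
    converged: bool
    residual_history: list = field(default_factory=list)

    @property
    def toc(self) -> np.ndarray:
        """Bulk TOC profile, umol C per cm^3 solid."""
        return self.g_fractions.sum(axis=0)

    @property
    def toc_wtpct(self) -> np.ndarray:
        return molar_to_wtpct(self.toc, MOLAR_MASS["C"])

    def profile(self, species: str) -> np.ndarray:
        """Concentration profile in internal units ('TOC' or a subsystem species)."""
        if species == "TOC":
            return self.toc
        return self.concentrations[species]


def _om_species(config: SiteConfig) -> Species:
    return Species(name="TOC", phase="solid", molecular_diffusion_coeff=0.0,
                   upper_bc_value=float(config.upper_bc.get("TOC", 0.0)))


def _solve_om_fractions(config: SiteConfig, grid: SedimentGrid, multig: MultiG):
    """Independent linear steady profiles for every OM fraction."""
    toc0 = float(config.upper_bc.get("TOC", 0.0))
    phi = grid.porosity
    sigma0 = 1.0 - phi[0]
    ops: list[TransportOperator] = []
    g = np.zeros((multig.n_fractions, grid.n_nodes))
    for i, (ki, fi) in enumerate(zip(multig.k, multig.f)):
        bc_value = fi * toc0
        sp = Species(name=f"TOC_{i}", phase="solid", molecular_diffusion_coeff=0.0,
                     upper_bc_value=bc_value)
        if config.solid_bc_mode == "flux":
            flux = sigma0 * config.sedimentation_rate * bc_value
            op = assemble_transport(sp, grid, config, bc_mode="flux",
                                    deposition_flux=flux)
        else:
            op = assemble_transport(sp, grid, config)
        g[i] = op.solve_steady(decay=ki)
        ops.append(op)
    g = np.maximum(g, 0.0)
    return g, ops


def _reaction_jacobian_blocks(state, r_c, constants, rn_kwargs, delta_scale):
    """Per-node dS_i/dC_j blocks by vectorized finite differences."""
    n_sp, n = state.shape
    s0, _ = rn.species_sources(state, r_c, constants, **rn_kwargs)
    blocks = np.zeros((n_sp, n_sp, n))
    for j in range(n_sp):
        h = np.maximum(1e-6 * np.abs(state[j]), delta_scale[j])
        pert = state.copy()
        pert[j] = pert[j] + h
        s1, _ = rn.species_sources(pert, r_c, constants, **rn_kwargs)
        blocks[:, j, :] = (s1 - s0) / h
    return s0, blocks


def _assemble_jacobian(transport_mats, blocks, dirichlet_rows, n_sp, n):
    """Block-sparse Jacobian: banded transport + per-node reaction coupling."""
    data, rows, cols = [], [], []
    for s, mat in enumerate(transport_mats):
        coo = mat.tocoo()
        rows.append(coo.row + s * n)
        cols.append(coo.col + s * n)
        data.append(coo.data)
    node_idx = np.arange(n)
    for i in range(n_sp):
        mask = np.ones(n, dtype=bool)
        if dirichlet_rows[i]:
            mask[0] = False  # no reaction term on a fixed-concentration row
        for j in range(n_sp):
            bij = blocks[i, j]
            nz = mask & (bij != 0.0)
            if not np.any(nz):
                continue
            rows.append(node_idx[nz] + i * n)
            cols.append(node_idx[nz] + j * n)
            data.append(bij[nz])
    jac = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_sp * n, n_sp * n))
    return jac.tocsc()


def _solve_once(config: SiteConfig, grid: SedimentGrid | None = None,
                multig: MultiG | None = None, *, n_nodes: int = 200,
                n_fractions: int = 200, L: float = 100.0,
                om_only: bool = False, tol: float = 1e-8,
                max_iter: int = 120,
                initial_state: np.ndarray | None = None) -> SteadyStateSolution:
    """Single Newton/pseudo-transient attempt; see :func:`solve_steady_state`.

    Parameters
    ----------
    config:
        Site configuration (boundary conditions, transport parameters,
        rate constants, reactivity parameters).
    grid, multig:
        Optional pre-built grid / multi-G discretization; by default built
        from the config with ``n_nodes`` nodes over ``L`` cm and
        ``n_fractions`` reactivity fractions.
    om_only:
        Solve only the organic-matter fraction profiles (the porewater
        subsystem is skipped and returned as its boundary values).
    tol:
        Convergence tolerance on the scaled max-norm residual.
    initial_state:
        Optional (12, n_nodes) warm-start state for the Newton iteration.

    Raises
    ------
    SolverError
        If the Newton/pseudo-transient iteration does not reach ``tol``
        within ``max_iter`` iterations; carries the residual history.
    """
    if grid is None:
        grid = config.build_grid(L=L, n_nodes=n_nodes)
    if multig is None:
        multig = discretize_rcm(config.rcm, n_fractions)
    phi = grid.porosity
    n = grid.n_nodes

    g, om_ops = _solve_om_fractions(config, grid, multig)
    r_c = (1.0 - phi) * (multig.k @ g)

    registry = config.species_registry()
    species = list(SUBSYSTEM_SPECIES)
    n_sp = len(species)

    def _subsystem_op(name):
        sp = registry[name]
        if sp.phase == "solid" and config.solid_bc_mode == "flux":
            # equivalent deposition flux implied by the tabulated concentration
            flux = (1.0 - phi[0]) * config.sedimentation_rate * sp.upper_bc_value
            return assemble_transport(sp, grid, config, bc_mode="flux",
                                      deposition_flux=flux)
        return assemble_transport(sp, grid, config, bc_mode="dirichlet")

    ops = {name: _subsystem_op(name) for name in species}
    dirichlet = [ops[name].bc_mode == "dirichlet" for name in species]
    bc_values = np.array([registry[name].upper_bc_value for name in species])

    if om_only:
        state = np.repeat(bc_values[:, None], n, axis=1)
        sources, aux = rn.species_sources(
            state, np.zeros(n), config.rate_constants,
            redfield_n=config.redfield_n / config.redfield_c,
            redfield_p=config.redfield_p / config.redfield_c)
        return SteadyStateSolution(
            config=config, grid=grid, multig=multig, g_fractions=g,
            concentrations={s: state[i] for i, s in enumerate(species)},
            pathway_rates={p: rn_part * 0.0 for p, rn_part in
                           aux["pathway_rates"].items()},
            secondary_rates={k: v * 0.0 for k, v in aux["secondary_rates"].items()},
            r_c=r_c, partition=aux["partition"], operators=ops,
            om_operators=om_ops, residual_norm=0.0, iterations=0, converged=True)

    rn_kwargs = dict(redfield_n=config.redfield_n / config.redfield_c,
                     redfield_p=config.redfield_p / config.redfield_c)
    constants = config.rate_constants
    tmats = [ops[name].to_sparse() for name in species]
    rhs = np.concatenate([ops[name].rhs for name in species])

    if initial_state is not None:
        state = np.maximum(np.asarray(initial_state, dtype=float).copy(), 0.0)
    else:
        state = np.repeat(bc_values[:, None], n, axis=1)

    # finite-difference perturbation scale per species
    delta_scale = 1e-6 * np.maximum(bc_values, 1e-2)

    def full_residual(x):
        s, aux = rn.species_sources(x, r_c, constants, **rn_kwargs)
        res = np.empty((n_sp, n))
        for i, name in enumerate(species):
            res[i] = ops[name].matvec(x[i]) + ops[name].rhs
            if dirichlet[i]:
                res[i, 0] = x[i, 0] - bc_values[i]
                s_i = s[i].copy()
                s_i[0] = 0.0
                res[i] += s_i
            else:
                res[i] += s[i]
        return res, s, aux

    def scaled_norm(res, x, s):
        # residual relative to the dominant term of each species' balance
        if not (np.all(np.isfinite(res)) and np.all(np.isfinite(x))):
            return np.inf
        worst = 0.0
        for i, name in enumerate(species):
            scale = max(np.abs(ops[name].rhs).max(),
                        np.abs(ops[name].matvec(x[i])).max(),
                        np.abs(s[i]).max(), 1e-10)
            worst = max(worst, np.abs(res[i]).max() / scale)
        return worst

    _olderr = np.seterr(over="ignore", invalid="ignore", divide="ignore")
    res, srcs, aux = full_residual(state)
    norm = scaled_norm(res, state, srcs)
    history = [norm]
    dt = None  # pseudo-transient step size; None while plain Newton works
    sigma_stack = np.concatenate([ops[name].sigma for name in species])

    it = 0
    while norm > tol and it < max_iter:
        it += 1
        _, blocks = _reaction_jacobian_blocks(state, r_c, constants, rn_kwargs,
                                              delta_scale)
        jac = _assemble_jacobian(tmats, blocks, dirichlet, n_sp, n)
        if dt is not None:
            jac = jac - sparse.diags_array(sigma_stack / dt, format="csc")
        try:
            lu = splu(jac)
        except RuntimeError as err:
            np.seterr(**_olderr)
            raise SolverError(f"Jacobian factorization failed: {err}", history)
        step = lu.solve(-res.ravel()).reshape(n_sp, n)
        if not np.all(np.isfinite(step)):
            dt = 1e-3 if dt is None else dt * 0.25
            history.append(norm)
            continue

        if dt is None:
            accepted = False
            for lam in (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125):
                trial = np.maximum(state + lam * step, 0.0)
                t_res, t_s, t_aux = full_residual(trial)
                t_norm = scaled_norm(t_res, trial, t_s)
                if t_norm < norm * (1.0 - 1e-4 * lam) or t_norm < tol:
                    state, res, srcs, norm, aux = trial, t_res, t_s, t_norm, t_aux
                    accepted = True
                    break
            if not accepted:
                dt = 1e-2  # switch to pseudo-transient continuation
        else:
            # implicit pseudo-time step; the step size doubles on success so
            # the march turns back into Newton, and shrinks on blow-up
            trial = np.maximum(state + step, 0.0)
            t_res, t_s, t_aux = full_residual(trial)
            t_norm = scaled_norm(t_res, trial, t_s)
            if np.isfinite(t_norm):
                state, res, srcs, norm, aux = trial, t_res, t_s, t_norm, t_aux
                dt *= 2.0
                if dt > 1e7:
                    dt = None
            else:
                dt *= 0.25
                if dt < 1e-12:
                    np.seterr(**_olderr)
                    raise SolverError(
                        f"pseudo-transient march collapsed at residual {norm:.3e}",
                        history)
        history.append(norm)

    np.seterr(**_olderr)
    if norm > tol:
        raise SolverError(
            f"no convergence after {it} iterations (residual {norm:.3e})", history)

    sources, aux = rn.species_sources(state, r_c, constants, **rn_kwargs)
    return SteadyStateSolution(
        config=config, grid=grid, multig=multig, g_fractions=g,
        concentrations={name: state[i] for i, name in enumerate(species)},
        pathway_rates=aux["pathway_rates"],
        secondary_rates=aux["secondary_rates"],
        r_c=r_c, partition=aux["partition"], operators=ops, om_operators=om_ops,
        residual_norm=float(norm), iterations=it, converged=True,
        residual_history=history)


# bimolecular / precipitation constants ramped during continuation fallback
_CONTINUATION_KEYS = ("k_nit", "k_mnox", "k_feox", "k_feox_mno2", "k_sox_o2",
                      "k_sox_mno2", "k_sox_feooh", "k_fes", "k_fes2",
                      "k_fesox", "k_pfe_ads")


def solve_steady_state(config: SiteConfig, grid: SedimentGrid | None = None,
                       multig: MultiG | None = None, *, n_nodes: int = 200,
                       n_fractions: int = 200, L: float = 100.0,
                       om_only: bool = False, tol: float = 1e-8,
                       max_iter: int = 120,
                       initial_state: np.ndarray | None = None) -> SteadyStateSolution:
    """Solve the steady-state reaction-transport problem for one site.

    Parameters are documented on the solver core (:func:`_solve_once`): the
    organic-matter fractions are solved linearly, the 12-species porewater/
    oxide subsystem by damped projected Newton with pseudo-transient
    fallback.  If the direct solve does not converge (sharp reaction fronts
    at extreme reactivity parameters can defeat the Newton march from a
    cold start), a homotopy retry ramps the bimolecular and precipitation
    rate constants up from 1% of their configured values, warm-starting
    each stage from the previous one.

    Raises :class:`SolverError` only when the continuation also fails.
    """
    from dataclasses import replace as _replace
    kwargs = dict(grid=grid, multig=multig, n_nodes=n_nodes,
                  n_fractions=n_fractions, L=L, om_only=om_only, tol=tol,
                  max_iter=max_iter)
    try:
        return _solve_once(config, initial_state=initial_state, **kwargs)
    except SolverError as direct_err:
        if om_only:
            raise
        logger.info("direct solve failed (%s); ramping reaction constants",
                    direct_err)
        warm = initial_state
        try:
            for gamma in (0.01, 0.1, 0.3, 1.0):
                constants = dict(config.rate_constants)
                for key in _CONTINUATION_KEYS:
                    constants[key] = constants.get(key, 0.0) * gamma
                stage_cfg = _replace(config, rate_constants=constants)
                sol = _solve_once(stage_cfg, initial_state=warm, **kwargs)
                warm = np.stack([sol.concentrations[s] for s in sol.operators])
        except SolverError as cont_err:
            raise SolverError(
                f"no convergence (direct: {direct_err}; "
                f"continuation at ramp {gamma}: {cont_err})",
                cont_err.residual_history) from cont_err
        # final stage ran at gamma=1.0, i.e. the configured constants
        return SteadyStateSolution(
            config=config, grid=sol.grid, multig=sol.multig,
            g_fractions=sol.g_fractions, concentrations=sol.concentrations,
            pathway_rates=sol.pathway_rates,
            secondary_rates=sol.secondary_rates, r_c=sol.r_c,
            partition=sol.partition, operators=sol.operators,
            om_operators=sol.om_operators, residual_norm=sol.residual_norm,
            iterations=sol.iterations, converged=sol.converged,
            residual_history=sol.residual_history)
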