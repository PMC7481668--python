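"""Inverse constraint of apparent OM reactivity from depth profiles.

The reactivity parameters (a, v) are estimated by best fit between forward
steady-state simulations and observed concentration depth profiles.  The
misfit is the species-weighted mean of range-normalized RMSEs (model
linearly interpolated to observation depths; replicates pooled, not
averaged, so scatter information is preserved).  The search is a coarse
grid — logarithmic in a, linear in v — followed by local grid refinement
around the optimum, which makes the procedure deterministic given its
inputs.  The interface oxygen concentration can optionally be co-fitted
over a small discrete set of candidate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import optimize

from .core import MOLAR_MASS, SiteConfig, wtpct_to_molar
from .om_reactivity import RCMParams
from .solver import SolverError, SteadyStateSolution, solve_steady_state

__all__ = ["ObservedProfileSet", "FitResult", "misfit", "fit_reactivity",
           "DEFAULT_FIT_SPECIES"]

DEFAULT_FIT_SPECIES = ("TOC", "NO3", "NH4", "PO4", "Mn2", "Fe2")

_UNIT_TO_INTERNAL = {
    "uM": 1e-3, "µM": 1e-3, "umol/l": 1e-3, "mM": 1.0, "umol/cm3": 1.0,
}


@dataclass
class ObservedProfileSet:
    """Observed depth profiles for one site, held as a tidy frame.

    Columns: ``site, species, depth_cm, value, unit, replicate``.
    Units are converted to internal model units on access (wt% for solid
    organic carbon, uM/mM for dissolved species).
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"site", "species", "depth_cm", "value", "unit", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"profile table lacks columns: {sorted(missing)}")
        if (self.frame["depth_cm"] < 0).any():
            raise ValueError("observation depths must be non-negative")
        for (sp, rep), group in self.frame.groupby(["species", "replicate"]):
            if np.any(np.diff(group["depth_cm"].to_numpy()) < 0):
                raise ValueError(
                    f"depths must be increasing within replicate {rep} of {sp}")

    @property
    def site(self) -> str:
        return str(self.frame["site"].iloc[0])

    def species_list(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def arrays(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """(depths, values) pooled over replicates, in internal units."""
        sub = self.frame[self.frame["species"] == species]
        depths = sub["depth_cm"].to_numpy(dtype=float)
        values = sub["value"].to_numpy(dtype=float)
        units = sub["unit"].to_numpy()
        out = np.empty_like(values)
        for unit in np.unique(units):
            mask = units == unit
            if unit in ("wt%", "wtpct"):
                out[mask] = wtpct_to_molar(values[mask], MOLAR_MASS["C"])
            elif unit in _UNIT_TO_INTERNAL:
                out[mask] = values[mask] * _UNIT_TO_INTERNAL[unit]
            else:
                raise ValueError(f"unit {unit!r} not resolvable to internal units")
        return depths, out


@dataclass
class FitResult:
    """Best-fit reactivity parameters with the explored misfit surface."""

    best_a: float
    best_v: float
    best_misfit: float
    a_grid: np.ndarray              # final (refined) grid
    v_grid: np.ndarray
    misfit_grid: np.ndarray         # shape (len(a_grid), len(v_grid))
    per_species: dict[str, float]   # misfit breakdown at the optimum
    fitted_o2_um: float | None = None
    stages: list = field(default_factory=list)  # (a_grid, v_grid, misfit_grid)
    cell_log10a: float = 0.0        # refined cell half-width in log10(a)
    cell_v: float = 0.0             # refined cell half-width in v

    @property
    def k_swi(self) -> float:
        return self.best_v / self.best_a

    def to_frame(self) -> pd.DataFrame:
        aa, vv = np.meshgrid(self.a_grid, self.v_grid, indexing="ij")
        return pd.DataFrame({"a_yr": aa.ravel(), "v": vv.ravel(),
                             "misfit": self.misfit_grid.ravel()})


def misfit(observed: ObservedProfileSet, solution: SteadyStateSolution,
           species_weights: dict[str, float] | None = None) -> float:
    """Weighted mean of range-normalized per-species RMSEs.

    The model is linearly interpolated to the observation depths; each
    species' RMSE is normalized by its observed range (or by the maximum
    absolute value for a flat profile), then averaged with the given
    weights (default: equal weights over the species present).

    Raises when no species has at least 3 observations inside the model
    domain.
    """
    if species_weights is None:
        present = [s for s in observed.species_list()
                   if s in DEFAULT_FIT_SPECIES or s in ("O2", "SO4", "H2S")]
        species_weights = {s: 1.0 for s in present}
    if not species_weights:
        raise ValueError("no species to fit")
    z_model = solution.grid.node_depths
    total, weight_sum = 0.0, 0.0
    n_used = 0
    for sp, wgt in species_weights.items():
        if wgt == 0:
            continue
        depths, values = observed.arrays(sp)
        inside = depths <= z_model[-1]
        depths, values = depths[inside], values[inside]
        if depths.size < 3:
            continue
        model = np.interp(depths, z_model, solution.profile(sp))
        rng = values.max() - values.min()
        if rng <= 0:
            rng = max(abs(values).max(), 1e-12)
        rmse = float(np.sqrt(np.mean((model - values) ** 2)))
        total += wgt * rmse / rng
        weight_sum += wgt
        n_used += 1
    if n_used == 0:
        raise ValueError(
            "no species with >= 3 observations overlapping the model domain")
    return total / weight_sum


def _grid_eval(observed, config, a_grid, v_grid, species_weights, o2_values,
               solver_kwargs):
    """Evaluate the misfit over an (a, v[, O2]) grid with warm starts."""
    shape = (len(a_grid), len(v_grid))
    surface = np.full(shape, np.inf)
    best_o2 = np.full(shape, np.nan)
    warm = None
    failures = []
    for i, a in enumerate(a_grid):
        for j, v in enumerate(v_grid):
            for o2 in o2_values:
                cfg = dc_replace(config, rcm=RCMParams(a=float(a), v=float(v)))
                if o2 is not None:
                    bc = dict(cfg.upper_bc)
                    bc["O2"] = o2 * 1e-3
                    cfg = dc_replace(cfg, upper_bc=bc)
                try:
                    sol = solve_steady_state(cfg, initial_state=warm,
                                             **solver_kwargs)
                except SolverError:
                    try:  # a stale warm start can mislead Newton; retry cold
                        sol = solve_steady_state(cfg, **solver_kwargs)
                    except SolverError:
                        failures.append((float(a), float(v), o2))
                        continue
                warm = np.stack([sol.concentrations[s]
                                 for s in sol.operators])
                value = misfit(observed, sol, species_weights)
                if value < surface[i, j]:
                    surface[i, j] = value
                    best_o2[i, j] = np.nan if o2 is None else o2
    return surface, best_o2, failures


def _polish(observed, config, a0, v0, f0, o2_um, a_bounds, v_bounds,
            species_weights, solver_kwargs):
    """Bounded Nelder-Mead descent in (log10 a, v) from the grid optimum."""
    la_lo, la_hi = np.log10(a_bounds[0]), np.log10(a_bounds[1])
    v_lo, v_hi = v_bounds
    warm = {"state": None}

    def objective(x):
        la = float(np.clip(x[0], la_lo, la_hi))
        v = float(np.clip(x[1], v_lo, v_hi))
        cfg = dc_replace(config, rcm=RCMParams(a=10.0 ** la, v=v))
        if o2_um is not None:
            bc = dict(cfg.upper_bc)
            bc["O2"] = o2_um * 1e-3
            cfg = dc_replace(cfg, upper_bc=bc)
        try:
            sol = solve_steady_state(cfg, initial_state=warm["state"],
                                     **solver_kwargs)
        except SolverError:
            return 10.0 * (1.0 + f0)
        warm["state"] = np.stack([sol.concentrations[s] for s in sol.operators])
        penalty = 0.0  # pull clipped coordinates back inside the box
        penalty += abs(x[0] - la) + abs(x[1] - v)
        return misfit(observed, sol, species_weights) + penalty

    res = optimize.minimize(
        objective, x0=np.array([np.log10(a0), v0]), method="Nelder-Mead",
        options=dict(xatol=5e-3, fatol=1e-6, maxfev=60,
                     initial_simplex=np.array([
                         [np.log10(a0), v0],
                         [np.log10(a0) + 0.08, v0],
                         [np.log10(a0), v0 + 0.6 * max(v0, 0.02) * 0.1],
                     ])))
    if res.fun <= f0:
        la = float(np.clip(res.x[0], la_lo, la_hi))
        v = float(np.clip(res.x[1], v_lo, v_hi))
        return 10.0 ** la, v, float(res.fun)
    return a0, v0, f0


def fit_reactivity(observed: ObservedProfileSet, config: SiteConfig,
                   a_bounds: tuple[float, float] = (1.0, 1000.0),
                   v_bounds: tuple[float, float] = (0.01, 1.0),
                   n_a: int = 9, n_v: int = 8, n_refine: int = 2,
                   species_weights: dict[str, float] | None = None,
                   co_fit_o2_um: list[float] | None = None,
                   polish: bool = True,
                   **solver_kwargs) -> FitResult:
    """Constrain (a, v) by grid search with local refinement.

    ``a`` is sampled logarithmically within ``a_bounds`` and ``v``
    linearly within ``v_bounds``; after the coarse stage the grid is
    rebuilt around the optimum (``n_refine`` times).  The misfit surface
    has a narrow valley along which v/a is nearly constant, so a greedy
    grid descent can stall partway along it; by default the grid optimum
    is therefore polished with a bounded Nelder-Mead search in
    (log10 a, v), which follows the curved valley to its floor and stays
    deterministic.  Collapsed bounds (lo == hi) reduce the search to one
    dimension.  ``co_fit_o2_um`` optionally co-fits the interface oxygen
    value over a discrete candidate list (in uM).

    Raises ``SolverError`` if every forward run in the coarse stage
    diverges.
    """
    o2_values = co_fit_o2_um if co_fit_o2_um else [None]
    a_bounds_full, v_bounds_full = tuple(a_bounds), tuple(v_bounds)
    a_lo, a_hi = a_bounds
    v_lo, v_hi = v_bounds
    if not (0 < a_lo <= a_hi) or not (0 < v_lo <= v_hi):
        raise ValueError("parameter bounds must be positive and ordered")

    stages = []
    for stage in range(n_refine + 1):
        a_grid = (np.array([a_lo]) if a_lo == a_hi
                  else np.geomspace(a_lo, a_hi, n_a))
        v_grid = (np.array([v_lo]) if v_lo == v_hi
                  else np.linspace(v_lo, v_hi, n_v))
        surface, o2_grid, failures = _grid_eval(
            observed, config, a_grid, v_grid, species_weights, o2_values,
            solver_kwargs)
        if not np.isfinite(surface).any():
            raise SolverError(
                f"all forward runs diverged; first failing corner {failures[0]}")
        i, j = np.unravel_index(np.argmin(surface), surface.shape)
        stages.append((a_grid, v_grid, surface))
        # bracket two cells either side of the optimum: the (a, v) misfit
        # ridge runs diagonally and a one-cell window around a coarse-grid
        # optimum can exclude the true minimum entirely
        a_lo = a_grid[max(i - 2, 0)]
        a_hi = a_grid[min(i + 2, len(a_grid) - 1)]
        v_lo = v_grid[max(j - 2, 0)]
        v_hi = v_grid[min(j + 2, len(v_grid) - 1)]

    a_grid, v_grid, surface = stages[-1]
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    best_a, best_v = float(a_grid[i]), float(v_grid[j])
    best_misfit = float(surface[i, j])
    best_o2 = o2_grid[i, j]

    if polish and a_grid.size > 1 and v_grid.size > 1:
        best_a, best_v, best_misfit = _polish(
            observed, config, best_a, best_v, best_misfit,
            None if np.isnan(best_o2) else float(best_o2),
            a_bounds_full, v_bounds_full, species_weights, solver_kwargs)

    # per-species breakdown at the optimum
    cfg = dc_replace(config, rcm=RCMParams(a=best_a, v=best_v))
    if not np.isnan(best_o2):
        bc = dict(cfg.upper_bc)
        bc["O2"] = best_o2 * 1e-3
        cfg = dc_replace(cfg, upper_bc=bc)
    sol = solve_steady_state(cfg, **solver_kwargs)
    per_species = {}
    weights = species_weights or {s: 1.0 for s in observed.species_list()
                                  if s in DEFAULT_FIT_SPECIES}
    for sp in weights:
        try:
            per_species[sp] = misfit(observed, sol, {sp: 1.0})
        except ValueError:
            continue

    cell_log10a = (np.diff(np.log10(a_grid)).max() if a_grid.size > 1 else 0.0)
    cell_v = (np.diff(v_grid).max() if v_grid.size > 1 else 0.0)
    return FitResult(best_a=best_a, best_v=best_v,
                     best_misfit=best_misfit,
                     a_grid=a_grid, v_grid=v_grid, misfit_grid=surface,
                     per_species=per_species,
                     fitted_o2_um=None if np.isnan(best_o2) else float(best_o2),
                     stages=stages, cell_log10a=float(cell_log10a),
                     cell_v=float(cell_v))
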