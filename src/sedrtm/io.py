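"""Delimited-text I/O: profile files, solution exports, run manifests.

All persistent formats are plain text so runs diff cleanly: profile files
are CSV with the header ``site,species,depth_cm,value,unit,replicate``;
solutions and budgets are tidy CSV tables; every output directory carries
exactly one JSON manifest sufficient to re-run the command.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import FluxDecomposition, RateBudget, integrate_rates, swi_fluxes
from .inverse import FitResult, ObservedProfileSet
from .solver import SteadyStateSolution
from .synthetic import PROFILE_COLUMNS

__all__ = ["read_profiles", "write_profiles", "write_solution", "write_budget",
           "write_fit_result", "RunManifest", "write_manifest", "read_manifest"]


def read_profiles(path) -> ObservedProfileSet:
    """Read a standard profile file into an :class:`ObservedProfileSet`."""
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"profile file {path} contains no observations")
    return ObservedProfileSet(frame=frame, provenance=str(path))


def write_profiles(frame: pd.DataFrame, path) -> None:
    """Write a tidy profile frame; values round-trip at full precision."""
    missing = set(PROFILE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"profile frame lacks columns: {sorted(missing)}")
    frame.to_csv(path, index=False)


def solution_frame(solution: SteadyStateSolution) -> pd.DataFrame:
    """Tidy (depth, species, concentration, unit) table for one solution."""
    z = solution.grid.node_depths
    rows = [pd.DataFrame({
        "site": solution.config.site_id, "species": "TOC", "depth_cm": z,
        "value": solution.toc_wtpct, "unit": "wt%"})]
    for name, c in solution.concentrations.items():
        unit = ("umol/cm3_solid" if name in ("MnO2", "FeOOH", "FeS", "PFe")
                else "uM")
        value = c if unit.endswith("solid") else c * 1e3
        rows.append(pd.DataFrame({
            "site": solution.config.site_id, "species": name, "depth_cm": z,
            "value": value, "unit": unit}))
    return pd.concat(rows, ignore_index=True)


def write_solution(solution: SteadyStateSolution, path) -> None:
    solution_frame(solution).to_csv(path, index=False)


def rates_frame(solution: SteadyStateSolution) -> pd.DataFrame:
    z = solution.grid.node_depths
    data = {"depth_cm": z, "R_Corg_total": solution.r_c}
    data.update({f"R_{p}": r for p, r in solution.pathway_rates.items()})
    return pd.DataFrame(data)


def write_budget(solution: SteadyStateSolution, path_budget, path_fluxes) -> None:
    """Write the rate budget and the per-species SWI flux decomposition."""
    budget = integrate_rates(solution)
    budget.to_frame().to_csv(path_budget, index=False)
    rows = []
    for sp in ("O2", "NO3", "SO4", "NH4", "PO4", "Mn2", "Fe2", "H2S"):
        flux = swi_fluxes(solution, sp)
        row = {"species": sp, "total_umol_cm2_yr": flux.total,
               **{f"{k}_umol_cm2_yr": v for k, v in flux.components().items()}}
        row.update({f"{k}_share_pct": v
                    for k, v in flux.shares_pct("absolute").items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_fluxes, index=False)


def write_fit_result(result: FitResult, path_summary, path_grid) -> None:
    summary = {
        "best_a_yr": result.best_a, "best_v": result.best_v,
        "k_swi_per_yr": result.k_swi, "misfit": result.best_misfit,
        "fitted_o2_um": result.fitted_o2_um,
        **{f"misfit_{sp}": val for sp, val in result.per_species.items()},
    }
    pd.DataFrame([summary]).to_csv(path_summary, index=False)
    result.to_frame().to_csv(path_grid, index=False)


@dataclass
class RunManifest:
    """Record of one CLI invocation, sufficient to re-run it."""

    command: str
    config: str
    seed: int | None
    out_dir: str
    version: str
    timestamp: str
    extra: dict | None = None


def write_manifest(out_dir, command: str, config: str, seed: int | None = None,
                   extra: dict | None = None) -> RunManifest:
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command, config=str(config), seed=seed, out_dir=str(out),
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        extra=extra or {})
    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest


def read_manifest(out_dir) -> RunManifest:
    with open(Path(out_dir) / "manifest.json") as fh:
        return RunManifest(**json.load(fh))
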