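"""Synthetic observation sets with the cruise sampling structure.

Porewater is sampled with Rhizon samplers at interval midpoints (1 cm
spacing to 2.5 cmbsf, 2 cm to 20.5 cmbsf, 5 cm to the core base) and the
parallel cores are sliced for solid-phase analysis (0.5 cm slices to
2 cmbsf, 1 cm below), each in triplicate from independent deployments.
The generator runs the forward model at known reactivity parameters,
samples the profiles at those depths and adds independent Gaussian noise
per replicate (relative sd times the local value plus an absolute,
detection-limit-like floor), truncated at zero.  Rhizon aspiration is
treated as point sampling at the interval midpoint, not interval
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SiteConfig
from .solver import SteadyStateSolution, solve_steady_state

__all__ = ["SamplingScheme", "default_scheme", "generate_site",
           "DEFAULT_NOISE", "PROFILE_COLUMNS"]

PROFILE_COLUMNS = ("site", "species", "depth_cm", "value", "unit", "replicate")

#: (relative sd, absolute floor in the species' measurement unit)
DEFAULT_NOISE = {
    "TOC": (0.05, 0.02),   # wt%
    "NO3": (0.05, 0.30),   # uM
    "NH4": (0.05, 0.20),   # uM
    "PO4": (0.05, 0.05),   # uM
    "Mn2": (0.05, 0.20),   # uM
    "Fe2": (0.05, 0.20),   # uM
}

_UNIT = {"TOC": "wt%", "NO3": "uM", "NH4": "uM", "PO4": "uM",
         "Mn2": "uM", "Fe2": "uM"}


@dataclass
class SamplingScheme:
    """Sampling depths, replication and noise model for one deployment."""

    porewater_depths: np.ndarray   # cm, interval midpoints
    solid_depths: np.ndarray       # cm, slice midpoints
    n_replicates: int = 3
    noise: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0

    def __post_init__(self) -> None:
        self.porewater_depths = np.asarray(self.porewater_depths, dtype=float)
        self.solid_depths = np.asarray(self.solid_depths, dtype=float)
        for depths in (self.porewater_depths, self.solid_depths):
            if depths.size and (np.any(depths <= 0) or np.any(np.diff(depths) <= 0)):
                raise ValueError("sampling depths must be positive and increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sp, (rel, floor) in self.noise.items():
            if rel < 0 or floor < 0:
                raise ValueError(f"noise parameters for {sp} must be >= 0")


def default_scheme(core_length: float, n_replicates: int = 3,
                   seed: int = 0) -> SamplingScheme:
    """The cruise sampling scheme truncated at ``core_length`` (cm).

    Porewater midpoints: 0.5, 1.5, 2.5 cm (1-cm intervals), then 2-cm
    intervals to 20.5 cm, then 5-cm intervals to the base.  Solid slices:
    0.5-cm slices to 2 cm (midpoints 0.25 ... 1.75), then 1-cm slices.
    """
    if core_length <= 2.5:
        raise ValueError("core_length must exceed the first sampling interval (2.5 cm)")
    pw = [d for d in (0.5, 1.5, 2.5) if d <= core_length]
    d = 4.5
    while d <= min(20.5, core_length):
        pw.append(d)
        d += 2.0
    d = 25.5
    while d <= core_length:
        pw.append(d)
        d += 5.0
    solid = [0.25, 0.75, 1.25, 1.75]
    d = 2.5
    while d <= core_length:
        solid.append(d)
        d += 1.0
    solid = [s for s in solid if s <= core_length]
    return SamplingScheme(porewater_depths=np.array(pw),
                          solid_depths=np.array(solid),
                          n_replicates=n_replicates, seed=seed)


def _measurement_values(solution: SteadyStateSolution, species: str,
                        depths: np.ndarray) -> np.ndarray:
    """Model profile interpolated to sampling depths, in measurement units."""
    z = solution.grid.node_depths
    if species == "TOC":
        return np.interp(depths, z, solution.toc_wtpct)
    return np.interp(depths, z, solution.concentrations[species]) * 1e3  # -> uM


def generate_site(true_config: SiteConfig, scheme: SamplingScheme,
                  species: tuple[str, ...] = ("TOC", "NO3", "NH4", "PO4", "Mn2", "Fe2"),
                  solution: SteadyStateSolution | None = None,
                  **solver_kwargs) -> pd.DataFrame:
    """Synthesize an observed profile set from a forward run at known (a, v).

    Returns a tidy frame with columns ``site, species, depth_cm, value,
    unit, replicate`` in measurement units (wt% for TOC, uM for dissolved
    species).  The true parameters are recorded in ``frame.attrs``.
    Noise draws are deterministic in ``scheme.seed`` and independent
    across replicates; values are truncated at zero.
    """
    if solution is None:
        solution = solve_steady_state(true_config, **solver_kwargs)
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for sp in species:
        depths = (scheme.solid_depths if sp == "TOC"
                  else scheme.porewater_depths)
        depths = depths[depths <= solution.grid.L]
        truth = _measurement_values(solution, sp, depths)
        rel, floor = scheme.noise.get(sp, (0.0, 0.0))
        for rep in range(1, scheme.n_replicates + 1):
            sd = rel * truth + floor
            noisy = truth + rng.standard_normal(truth.size) * sd
            noisy = np.maximum(noisy, 0.0)
            for z, val in zip(depths, noisy):
                rows.append((true_config.site_id, sp, z, val, _UNIT[sp], rep))
    frame = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    frame.attrs["true_a"] = true_config.rcm.a
    frame.attrs["true_v"] = true_config.rcm.v
    frame.attrs["seed"] = scheme.seed
    return frame
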