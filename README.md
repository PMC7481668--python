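# sedrtm

Steady-state reaction-transport modelling of organic-matter degradation
and benthic nutrient fluxes in muddy shelf sediments, with reactive
continuum kinetics. Built for benthic biogeochemists who want to run an
early-diagenesis model forward (degradation rates, redox pathway
contributions, sediment-water fluxes) or inversely (constraining apparent
organic-matter reactivity from porewater and solid-phase depth profiles),
from Python or a thin command line.

## The model

Every species obeys the 1-D porosity-weighted steady-state conservation
equation on 0-100 cm below the sediment-water interface (SWI):

    0 = d/dz[ σ (D_bio + D_i/θ²) dC_i/dz ] − d(σ ω C_i)/dz
        + α(z) φ (C_i(0) − C_i) + Σ_j s_ij R_j

with σ = φ (dissolved) or 1−φ (solids), molecular diffusion D_i
tortuosity-corrected (θ² = 1 − 2 ln φ), burial ω, mixed-layer
bioturbation D_bio, and bioirrigation α(z) exchanging porewater with
bottom water.

Bulk organic matter is a **reactive continuum**: first-order rate
constants are gamma-distributed with shape `v` and rate `a` (years), so
the apparent reactivity declines with age,

    k(age) = v / (a + age),      k_SWI = v/a,

and the model transports 200 discrete multi-G fractions whose mass-
weighted decay reproduces the continuum's closed form (a/(a+t))^v.
Carbon oxidation is apportioned down the redox ladder (O2, NO3⁻, Mn and
Fe oxides, SO4²⁻, methanogenesis) by a Monod limitation/inhibition
cascade; reduced products (NH4⁺, Mn²⁺, Fe²⁺, ΣH2S, FeS) re-oxidize
bimolecularly, iron sulfides precipitate, NH4⁺ sorbs at equilibrium and
PO4³⁻ couples kinetically to the reactive Fe-oxide pool.

Outputs follow the standard benthic-pelagic coupling diagnostics: the
depth-integrated degradation rate ΣR_Corg = Σ_n ∫₀ᴸ r_n dz (µmol C cm⁻²
yr⁻¹), per-pathway contributions, and SWI fluxes J_i decomposed into
advection, molecular diffusion, bioturbation and bioirrigation.

Five Barents Sea transect stations (B13-B17, ~300 m water depth, spanning
the Polar Front) ship as built-in configurations with their measured
bottom-water properties, interface boundary concentrations and best-fit
reactivity parameters.

## Worked example

```python
from sedrtm import site_config, solve_steady_state, integrate_rates, swi_fluxes

solution = solve_steady_state(site_config("B15"))   # central station, ~1 s
budget = integrate_rates(solution)
print(f"sum R_Corg = {budget.total:.1f} umol C cm^-2 yr^-1")
flux = swi_fluxes(solution, "NH4")
print(f"J_NH4 = {flux.total:+.2f} umol cm^-2 yr^-1, "
      f"bioirrigation share {flux.shares_pct('absolute')['bioirrigation']:.0f}%")
```

prints

```
sum R_Corg = 35.2 umol C cm^-2 yr^-1
J_NH4 = +2.25 umol cm^-2 yr^-1, bioirrigation share 96%
```

i.e. the low-reactivity central station degrades ~35 µmol C cm⁻² yr⁻¹ in
the top metre and releases ammonium to the bottom water mostly through
burrow flushing rather than molecular diffusion — intense nitrification
flattens the interface gradient, so the diffusive share collapses.

The inverse direction (`examples/synthesize_and_fit.py`) generates
triplicate synthetic observations with the cruise's Rhizon/slicing
sampling structure and 5% noise, then recovers the reactivity parameters
by grid search with Nelder-Mead polish; the ratio k_SWI = v/a comes back
within a few percent even though a and v individually trade off along a
misfit ridge.

More narrative scripts live in `examples/`: `reactivity_continuum.py`
(continuum vs multi-G), `forward_run.py` (budget and carbon closure),
`benthic_fluxes.py` (flux decomposition across stations).

A thin CLI wraps the same calls:

```bash
sedrtm forward --config B13 --out out/b13
sedrtm synth   --config B13 --seed 1 --out out/obs
sedrtm fit     --config B13 --profiles out/obs/profiles.csv --out out/fit
sedrtm report  --out out/transect
```

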