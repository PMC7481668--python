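# Methods

## Model

`sedrtm` solves the vertically resolved steady-state mass conservation
equation for solids and porewater solutes in the upper metre of a muddy
shelf sediment column (z in cm below the sediment-water interface,
positive down):

    0 = d/dz( sigma (D_bio + D_i/theta^2) dC_i/dz ) - d(sigma w C_i)/dz
        + alpha(z) phi (C_i(0) - C_i) + sum_j s_ij R_j

with sigma = phi for dissolved species and (1 - phi) for solids,
tortuosity theta^2 = 1 - 2 ln phi, burial velocity w (constant omega, no
compaction: the 210Pb-derived rates the configs carry are linear
accumulation rates), bioturbation D_bio constant inside a surface mixed
layer with a 2 cm linear taper below it (a discontinuous operator would
degrade the Newton convergence), and nonlocal bioirrigation exchange
alpha(z) = alpha0 exp(-z / z_irr) against the bottom-water concentration,
for dissolved species only.

Internal units: cm, yr, umol/cm^3 porewater (dissolved), umol/cm^3 solid
(solids), fluxes in umol cm^-2 yr^-1 of bulk sediment. Weight-percent
solid inputs convert with a particle density of 2.65 g/cm^3.

### Organic matter reactivity

Bulk organic matter is a reactive continuum: first-order rate constants k
are gamma-distributed at the interface with shape `v` (dimensionless) and
rate `a` (yr), so the apparent bulk reactivity declines with age as
k(age) = v/(a + age) and the surviving bulk fraction is (a/(a+t))^v.
Because age is undefined inside the bioturbated layer, the continuum is
discretized into n = 200 multi-G fractions (configurable): equal-mass
quantile bins of the gamma distribution, each carrying the bin-conditional
mean k. This binning makes sum(f) = 1 exact and sum(f k) = v/a analytic
for every n, and tracks the closed-form bulk decay within 0.5% out to
2000 yr of burial age at all transect parameter values. The fractions are
transported and degraded independently over the whole domain, not only the
mixed layer — below it this is mathematically identical to the age-based
continuum and avoids a stitching interface.

### Reaction network

Primary pathways oxidize organic carbon in ladder order (O2, NO3-, Mn
oxides, Fe oxides, SO4^2-, methanogenesis). Total carbon oxidation is
first order in the donor, sum_i k_i G_i; the pathways only apportion it
through a Monod limitation / inhibition cascade,
f_n = C_n/(C_n+K_n) * prod_{m<n} K'_m/(C_m+K'_m), with methanogenesis
taking the residual so the factors always sum to one. Nitrogen and
phosphorus are released at Redfield ratios (C:N:P = 106:16:1,
configurable), appropriate for the marine organic matter dominating these
surface sediments.

Secondary reactions are bimolecular (rate = k [reductant][oxidant], per
cm^3 bulk sediment): nitrification, Mn2+ / Fe2+ / sulfide / FeS oxidation
by O2, plus sulfide oxidation by Mn and Fe oxide phases and Fe2+ oxidation
by Mn oxide. FeS (and optionally FeS2) precipitate as irreversible kinetic
sinks proportional to [Fe2+][H2S]; dissolution is omitted at steady state.
NH4+ sorbs by linear equilibrium (dimensionless K, default 1.3): the
sorbed load rides on the solid phase, adding bioturbative and burial
transport (retardation 1 + K(1-phi)/phi in the transient sense). PO4^3-
adsorbs kinetically onto the reactive Fe-oxide pool and is re-released
stoichiometrically when that pool is reduced (the release rate carries the
instantaneous P:Fe loading of the pool, capped at 10 to keep the law
non-stiff as the pool vanishes).

Carbonate/borate equilibrium chemistry is not solved: pH is held fixed
and total sulfide is treated as one species. None of the reproduced
observables (TOC, NO3-, NH4+, PO4^3-, Mn2+, Fe2+) requires a pH solver;
this is a deliberate simplification of the full equilibrium network.
Methane is not transported and anaerobic methane oxidation is omitted.

### Numerics

Finite volumes on a node-centred grid over [0, 100] cm, exponentially
clustered towards the interface (first spacing ~0.02 cm at 200 nodes; the
builder refuses grids coarser than 0.25 cm anywhere in the top 2 cm, so
the oxygen boundary layer is always resolved). Diffusive face fluxes are
centred, advection is upwinded (downward flow). Upper boundary: fixed
concentration at the interface node for every species, reading the
station tables at face value; a deposition-flux mode for solids is
provided as an option (the flux implied by the tabulated concentration,
sigma0 * omega * C0, is then prescribed instead — with mixing this yields
a lower surface concentration and roughly half the depth-integrated
degradation, which is the documented sensitivity of the boundary-mode
ambiguity). Lower boundary: zero diffusive gradient with advective
outflow.

The multi-G fraction profiles are linear given the partition property and
solve by independent banded factorizations. The remaining 12-species
subsystem (8 solutes + MnO2, FeOOH, FeS, Fe-bound P) solves by damped,
projected Newton iteration: exact tridiagonal transport Jacobian plus
per-node reaction blocks obtained by vectorized finite differences;
line-search damping (factor 0.5) with non-negativity projection inside
iterations only; pseudo-transient continuation (initial step 1e-2 yr,
doubling on success) as fallback when a Newton direction fails to reduce
the residual. Convergence: scaled max-norm residual below 1e-8 of each
species' dominant balance term; the returned profiles are not clipped.
The solver is deterministic; seeds play no role.

Budgets integrate node rates with finite-volume cell widths — the
quadrature under which the discrete scheme conserves mass exactly, so
carbon and per-species closures hold to solver precision rather than to
quadrature error (a trapezoid on node values agrees to O(h^2) and is what
the cell-width rule reduces to on a uniform grid). Benthic fluxes are
decomposed at z = 0 into molecular diffusion, bioturbation, advection
(one-sided gradients over the ~0.02 cm first interval) and the
column-integrated bioirrigation exchange, with positive = efflux to
bottom water. Percentage shares are reported on absolute component values
by default (components can oppose in sign), with a signed mode available.

## Station parameterization

Boundary concentrations, bottom-water T/S and the best-fit (a, v) for the
five built-in stations are transcribed station tables. Parameters the
tables do not state were fixed once, package-wide:

- **Porosity 0.55, constant.** The transect's own numbers pin the product
  (1-phi)*omega: with the tabulated interface TOC values and burial at
  0.06 cm/yr, depth-integrated degradation rates of 30-140 umol C cm^-2
  yr^-1 require (1-phi)*omega of about 0.027 cm/yr. phi = 0.55 is a
  reasonable depth-average for compacted glacigenic silty mud; the
  commonly assumed surface value of 0.8 would underpredict all five
  stations' rates three- to five-fold. Overridable per site, with an
  exponential profile available.
- **Burial velocity 0.06 cm/yr** (upper end of the shallow 210Pb range
  for these stations).
- **D_bio = 10 cm^2/yr over a 3 cm mixed layer** (within the 2-5 cm
  macrofaunal estimates), 2 cm taper.
- **Bioirrigation alpha0 = 20 /yr, e-folding 3 cm** — global-compilation
  magnitudes for shelf depths.
- **Rate constants**: literature-typical defaults (see
  `core.default_rate_constants`), with site-specific overrides for
  nitrification and P-Fe adsorption reflecting the regimes the profiles
  demand (intense nitrification and P-Fe coupling at the central station,
  weak nitrification under the low-oxygen interface of B14). Site-specific
  secondary constants are part of the study design, not a fallback.

## Synthetic observations

The generator emulates the cruise's sampling structure: Rhizon porewater
samples at interval midpoints (1 cm spacing to 2.5 cmbsf, 2 cm to
20.5 cmbsf, 5 cm to the base), solid-phase slices (0.5 cm to 2 cmbsf,
1 cm below), triplicate deployments. Noise is independent Gaussian per
replicate with sd = 5% of the local value plus a per-species absolute
floor (detection-limit-like: 0.2-0.3 uM for nutrients and metals, 0.02
wt% for TOC), truncated at zero; values are point samples at midpoints,
not interval averages. The true measurement uncertainties of the field
data are not published; these defaults are labelled assumptions.

What the generator does **not** emulate: analytical drift, core
decompression/compaction artefacts, smearing during slicing, lateral
heterogeneity between deployments, or real deviations from steady state
(the central station's downcore TOC fluctuations, for instance). Passing
recovery tests therefore demonstrate the identifiability of (a, v) under
the model's own assumptions, not robustness to structural error in field
data.

## Inverse fitting

The misfit is the equal-weighted mean over species (TOC, NO3-, NH4+,
PO4^3-, Mn2+, Fe2+ by default) of RMSEs normalized by each species'
observed range, with the model interpolated to observation depths and
replicates pooled. The search is a coarse grid — logarithmic in a over
[1, 1000] yr, linear in v over [0.01, 1] — refined twice between the
neighbours of the running optimum. Everything is deterministic. The
misfit surface has the characteristic (a, v) trade-off ridge: the ratio
k_SWI = v/a is much better constrained than either parameter, which the
recovery tests assert explicitly. Interface O2 can be co-fitted over a
small discrete candidate set, mirroring how interface oxygen was chosen
below bottom-water values in the study design.

## Problem sizes and defaults

Forward runs default to 200 grid nodes and 200 reactivity fractions
(about a second per station); inverse fits and the recovery suite use 100
nodes and 60 fractions with a 7 x 6 coarse grid and two refinements,
which keeps a full fit near twenty seconds while leaving the recovered
k_SWI within a few percent of a full-resolution fit.

## Known limitations

- The aerobic contribution to total degradation is bounded by the oxygen
  influx that the prescribed interface O2, molecular diffusion,
  bioturbation and moderate bioirrigation can sustain (roughly
  50 umol O2 cm^-2 yr^-1 at the high-oxygen station B16). Reported
  aerobic shares above ~50% at comparable total rates imply an oxygen
  supply this transport parameterization cannot deliver; see the README's
  reproduction notes.
- Solid-phase upper boundary handling (fixed concentration vs deposition
  flux) changes absolute depth-integrated rates by about a factor of two;
  both modes ship, concentration mode is the default.
- Steady state only: seasonality, event deposition and transient mixing
  are out of scope by design.
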