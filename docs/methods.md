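# Methods

## The problem

Atmospheric oxygen controls how readily vegetation burns. Bench combustion
experiments show three effects as the O₂ mixing ratio rises above the
present atmospheric level (PAL, 20.95 % by volume): lightning ignites dead
fine fuel more readily, fuels can carry fire at higher moisture contents
(the *moisture of extinction* rises), and combustion releases more heat per
unit fuel. `oxfire` embeds these three pathways in a reduced-complexity
fire–vegetation simulator and asks the fire-window question: does raising
O₂ toward 35 % vol. burn forests off a present-day world, or do wet refugia
keep forests viable?

## Oxygen pathways (module `oxygen`)

**Probability of ignition.** An empirical regression in O₂ (% vol.) and
fuel moisture M (% of dry mass):

    PI(O₂, M) = (308.02 − 27.406·O₂ + 0.634·O₂² − 0.0044·O₂³)·ln M
                − 633.54 + 42.327·O₂ − 0.2194·O₂² − 0.0075·O₂³

PI is a percentage rating; the raw fit can leave [0, 100] at extreme
argument pairs, so the implementation clamps it to that interval. Its
validity range, O₂ ∈ [16, 35] % vol., is enforced — values outside raise
rather than extrapolate (dry fuel will not ignite below ~17 % O₂, so the
fire window's lower edge sits inside that range anyway).

**Ignition scaling.** The engine does not use PI directly but the ratio
PI(O₂, m)/PI(20.95, m), evaluated with the fast fine-fuel/live-grass
moisture ω_nl for grass fuels and the slow woody moisture ω_o for woody
fuels, so every prescribed per-PFT ignition efficiency is exactly unscaled
at PAL. At PAL the rating reaches zero near m ≈ 22 %; beyond that the ratio
would be 0/0. We cap the moisture argument (numerator and denominator
alike) at the m_cap where PI(20.95, m_cap) equals a configurable floor
(`pi_floor`, default 1 %). The factor is then continuous in m, finite, and
frozen at its capped value for wetter fuels — wet-fuel ignition efficiency
rises steeply with O₂ (×≈60 at 35 %), which is the model's version of
"wetter fuels ignite ever more readily even though they cannot carry fire".

**Moisture of extinction.** Mₑ = 8·O₂ − 128 (% dry mass): 39.6 % at PAL,
152 % at 35 % vol. The engine multiplies each fuel class's *native* (PAL)
extinction moisture by Mₑ(O₂)/Mₑ(20.95), so dry-mass moistures above 100 %
become burnable at high O₂ — legitimate on a dry-mass basis.

**Heat of combustion.** h = α/O₂ + β per PFT, FPC-weighted to a cell mean
that replaces the legacy single constant. The published per-PFT α, β are
not available here; the default scheme sets β to a complete-combustion
value per growth form (trees 20 000, grasses 18 500 kJ·kg⁻¹ — oxygen-bomb
tests burn under 100 % O₂ and overestimate natural fires) and
α = (h_PAL − β)·20.95 with h_PAL the conventional natural-fire heat
(trees 17 500, grasses 16 500 kJ·kg⁻¹). α is therefore negative and heat
rises toward β with O₂. All four numbers are config-exposed placeholders.

All three scalings equal exactly 1 at 20.95 % (they are ratios of identical
floating-point computations), so a PAL run is bit-identical to the
oxygen-feature-disabled engine — a regression guarantee the tests assert.

## Fire engine (module `fire`)

A deliberately desk-scale SPITFIRE-style engine: one representative fire
day, a fixed 240-minute burn, no multi-day coalescence.

- *Fire danger*: a Nesterov-type cumulative dryness index, Σ max(T,0)·(T−T_d)
  with a humidity-proxy dewpoint, reset by >3 mm rain, mapped to [0, 1) by
  1 − exp(−NI/5000).
- *Ignitions*: expected counts — flash density × cloud-to-ground fraction
  (0.2) × cell area × ieff, with ieff = FDI·ieff_avg·ieff_bf the exact
  triple product. ieff_avg is the FPC-weighted mean of the oxygen-scaled
  per-PFT efficiencies and may exceed 1 at high O₂ (it is a ratio); the
  expected-count formulation tolerates that, so the product is never capped.
  Fires are counted whether or not they spread; burned area requires spread.
- *ieff_bf*: ignition attenuation by recently burned area. A calendar-year
  reset proved hemisphere-biased (southern cells have their wet season
  before their fire season within a calendar year, northern after), so the
  implementation uses a burn-scar memory that decays with a 150-day
  e-folding: scars stop blocking ignitions as fuels regrow. The *hard* cap
  — burned fraction per calendar year ≤ 1 — is enforced separately and
  absolutely.
- *Spread*: Rothermel-style. Load-weighted bed moisture (1000-h logs
  excluded) against the load-weighted effective extinction moisture gives
  the cubic damping η(r) = 1 − 2.59r + 5.11r² − 3.52r³ (exactly 0 at
  r ≥ 1 — the extinction contract); a linear wind factor and a packing
  attenuation in bulk density complete ros = 8·η·(1+0.5·wind)/(1+ρ/20)
  m·min⁻¹. Oxygen enters only through the extinction scaling.
- *Intensity*: Byram, I = h_avg·w·(ros/60) kW·m⁻¹, with consumption per
  fuel class damped linearly by moisture relative to its effective
  extinction. Fires below 50 kW·m⁻¹ self-extinguish (standard
  surviving-fire threshold).
- *Burned area*: per-fire ellipse from the forward run ros × 240 min with a
  wind-dependent length-to-breadth ratio, times the expected fire count,
  capped at the cell's remaining unburned fraction for the year.
- *Mortality*: kill = susceptibility·(1 − e^(−I/600)) applied to the burned
  fraction daily; killed tree cover becomes dead fuel, grasses are
  top-killed but recover within a season.
- *Fuel moisture*: both pools relax exponentially (ω_nl τ = 2 d, ω_o
  τ = 15 d) toward an equilibrium 5 + 220·rh² % set by the humidity proxy.
  The quadratic keeps seasonally dry cells in the fire-prone range while
  humid cells sit far above even the 35 %-O₂ extinction moisture.

## Vegetation (module `vegetation`)

Nine PFTs (2 tropical, 3 temperate, 2 boreal trees, 2 grasses) with
LPJ-family bioclimatic limits (coldest-month window, GDD₅ minimum). Annual
precipitation sets carrying capacities (trees need >250 mm/yr, full canopy
by 550 mm/yr; values config-exposed); trees pre-empt space, grasses fill
the climatically allowed remainder. Growth uses the *exact* one-year
integration of the logistic ODE, so constant-climate trajectories equal the
closed form — the growth oracle in the tests. With fire off the layer
converges to its climate potential, the denominator of the suppression
metric; fire only removes cover, so no-fire cover bounds every fire run
cell by cell.

## Synthetic world (module `world`)

A seedable latitude-band world standing in for real half-degree forcing.
Four archetypes — wet tropics, arid subtropics, winter-wet mid latitudes,
cold humid high latitudes — plus two longitude variants that real-Earth
structure demands: a lightning-rich, seasonally desiccated **savanna**
sector occupying a third of the tropical band (fire-maintained grassland at
PAL, the present-day burning baseline), and a **maritime** sector occupying
a third of the mid-latitude band (humid year-round; never burns at any
swept O₂, like oceanic temperate forest). Precipitation occurrence is a
two-state Markov chain (stationary wet probability, persistence 0.3,
seasonally modulated) with gamma amounts; temperature and humidity carry
sinusoidal cycles plus white noise; lightning follows a warm-season
climatology with a convective wet-day boost. One seeded generator drives
everything, so a fixed seed reproduces the forcing bit for bit and every
O₂ level runs against identical weather.

What the generator does *not* emulate: interannual modes (ENSO-like
variability), spatial weather correlation between cells, orography, dew and
snow, and real lightning's spatial intermittency. Passing tests therefore
show that the oxygen pathways behave correctly *given* a latitudinally
structured climate, not that the model reproduces any observed fire regime.

## Experiment (module `experiment`)

The sweep runs O₂ ∈ {20.95, 21, …, 35} % vol. plus a fire-off baseline.
Spin-up is 200 years (scaled down from the reference 1500-year protocol;
the final-decade drift check warns if the global tree cover is still moving
by more than 0.02) and the last 10 years are averaged as output. Totals use
cosine-of-latitude (spherical) area weights. Diagnostics: global fire
counts and burned area, tree cover, forest area (cells with tree cover
> 0.60), suppression = 100·(1 − forest/forest_no_fire) floored at 0 (and
reported undefined if the no-fire world has no forest), and mean rate of
spread per fuel-moisture band ({<20, 20–40, 40–60, >60} % dry mass,
config-exposed edges), with cells binned once by their PAL-run mean bed
moisture and empty bands reported missing rather than zero.

## Scales and numerical choices

The default analysis world is the 6 × 3 archetype grid (cells at ±15°,
±45°, ±75°); the full 36 × 18 grid runs identically but ~30× slower, and
nothing in the oxygen response depends on resolution — the bands are
homogeneous by construction. A 16-run sweep at 200 years on the small grid
takes a few minutes on one core. Engine constants were calibrated once so
the PAL run reproduces a present-day-like geography — savanna burning
~25 %/yr, a few percent of the world burned annually, mid-latitude,
tropical and boreal forests intact — and then frozen; the oxygen response
is emergent, not fitted. Degenerate inputs are handled explicitly: bare
ground is non-flammable (never NaN), empty fuel beds report infinite bed
moisture and zero spread, and zero-capacity logistic steps return zero.

## Known limitations

- Absolute global numbers (fire counts, burned km², suppression
  percentages) depend on the synthetic world's geography and the
  placeholder per-PFT constants; only shapes, orderings and normalisations
  are meaningful.
- Oxygen does not modify residence time, fuel-consumption completeness
  beyond the extinction damping, or plant physiology; only the ignition,
  extinction and heat pathways are modelled.
- No crown fire, spotting, human ignition or suppression; lightning is the
  only ignition source.
- The savanna/forest boundary is bistable in this model; trajectories from
  bare ground decide which state a cell occupies, so initial conditions
  matter near the boundary.
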