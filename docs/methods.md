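# Methods

This note documents the model as implemented: its structure, the
parameters that matter, what the synthetic-weather generator does and
does not emulate, the numerical choices, and the limits of what the
tests demonstrate.

## Scope and design

The package simulates monoculture stands of a frost-sensitive summer
annual (common ragweed) on a daily time step, one calendar year per
replicate, to estimate a site's asymptotic population growth rate Λ and
seasonal pollen production under a given climate. It deliberately
excludes inter-specific canopy competition, nitrogen dynamics, pollen
dispersal/atmospheric transport, seed dispersal between sites, and
land-use filtering: the quantity computed is the *potential* climatic
niche under the most favourable growing conditions, not the realised
distribution.

## Synthetic weather

The generator stands in for a station-trained stochastic weather
generator. Inputs per site: latitude and twelve monthly values each of
mean daily tmin and tmax, wet-day probability and mean wet-day rainfall,
plus residual parameters.

* **Temperature.** A single AR(1) residual (sd default 2 °C, lag-1
  autocorrelation 0.6) is added to both tmin and tmax around their
  seasonal cycles, preserving the diurnal range. The seasonal cycle
  interpolates mid-month anchors linearly, with the anchors solved from
  a 12×12 linear system so that the *monthly means of the daily curve
  equal the configured normals exactly* (naive mid-month interpolation
  biases each month toward its neighbours by several tenths of a
  degree, which is large relative to the 0.9 °C phenological base).
* **Precipitation.** First-order two-state Markov occurrence whose
  stationary wet fraction equals the monthly probability (persistence
  default 0.3), with wet-day amounts gamma-distributed (shape 0.8, scale
  set by the monthly mean).
* **Radiation.** Extraterrestrial radiation from standard solar
  geometry, × 0.75 clear-sky transmittance, × 0.75 (dry) or 0.45 (wet)
  cloud factor. Latitudes beyond ±66° are rejected rather than
  mis-handled.
* **Reference ET.** Hargreaves (temperature + extraterrestrial
  radiation), clamped at zero. Chosen because it needs no humidity or
  wind inputs, which the site descriptors do not carry.
* **Scenarios.** Additive monthly temperature offsets and multiplicative
  rainfall factors. All random streams are drawn in a fixed order
  independent of parameter values, so same-seed runs are exactly paired
  across scenarios (a +2 °C offset shifts every day by exactly 2 °C).

Not emulated: observed spell-length and extreme-value distributions of
any real generator, humidity/wind, radiation persistence, and spatial
correlation between sites. Consequently, passing tests show the biology
responds correctly to *plausible* daily forcing, not that any specific
station's climate is reproduced.

## Seed biology

* **Dormancy release** integrates a daily rate with a triangular
  temperature response: peak 1/84 d⁻¹ at 4 °C (full release after 12
  weeks there), zero at −5 °C and 20 °C. The triangle is the simplest
  shape consistent with a single optimum and slower release when colder
  or warmer; the bounds are configurable. Because replicates are single
  calendar years but seed is shed the previous autumn, each replicate
  first integrates dormancy over October–December of its own weather
  year (autumn spin-up) before the January-onwards daily loop; without
  this, cold-winter sites could never chill their seeds in time.
* **Germination** follows `Y(θ) = M(1 − e^{−k(θ−a)^c})` with
  `θ̇ = (T − 3.6 °C)(ψ + 0.8 MPa)` when both factors are positive. The
  curve parameters default to `M = 95 %, k = 0.002, a = 120, c = 2`:
  the bases are empirical constants, while the curve constants are
  calibrated placeholders chosen so that median germination falls in a
  plausible spring window — mid-April under the favourable temperate
  archetype (after the worst frost risk), early July at the cold
  margin. All four are configuration-exposed.
* **Emergence** of the germinable pool is logit-normal with location
  logit(0.26) — the median is exactly 26% for any spread — and spread
  0.75. The distribution is markedly skewed; the direction of skew is a
  known ambiguity and nothing downstream depends on it.
* **Predation** draws are Normal(0.9, 0.1); the raw draw is exposed
  (clamping shifts moments) and the clamped value applied.
* **Seedbank decay** is exponential with a 17-year half-life: annual
  survival `2^{−1/17} ≈ 0.9600`, exactly halving after 17 applications.

The stand emerges on the day cumulative germination first reaches half
of M (the cohort's median germination day); plant density is the
emerged seed density capped at 200 plants m⁻² (self-thinning ceiling).
Germinated-but-not-emerged seed is removed from the bank (fatal
germination). Seed germinating after 1 August cannot found a cohort
that year and is likewise lost. Secondary (re-induced) dormancy is not
modelled.

## Soil water

A single bucket (plant-available capacity per soil preset: 100 mm loam,
150 mm deep loam, 80 mm shallow soil) with overflow drainage. Water
potential is log-linear in relative content between −1.5 MPa (empty) and
−0.01 MPa (full). Transpiration demand is `cover × ET0` with
`cover = 1 − e^{−k·LAI}`; supply is unrestricted above half fill and
declines linearly to zero at empty; bare-soil evaporation takes
0.3 × ET0 from the uncovered fraction under the same supply limit. The
daily budget closes exactly (property-tested). The bucket starts full
on 1 January (winter-wet profile).

## Growth and phenology

Daily biomass increment
`ΔW = RUE · R · (1 − e^{−k·LAI}) · f_T · (E_a/E_p)` with RUE 1.5 g MJ⁻¹,
k = 0.6, and `f_T` the triangular thermal response (base 0.9 °C, optimum
31.7 °C, assumed ceiling 40 °C — the ceiling is invented; the base and
optimum are empirical) normalised to [0, 1]. Allocation: vegetative
25/20/55/0 and flowering 5/10/5/80 percent to root/stem/leaf/
reproductive (the source field data are not published; fractions are
placeholders that conserve the increment exactly). LAI = leaf mass ×
SLA (0.02 m² g⁻¹). Seedlings start at 0.01 g per plant so Beer's-law
interception is non-zero on day one.

Flowering begins on 1 August (a calendar date — regional biotypes
synchronise flowering, so no photoperiod or latitude term). The season
ends at the first of: (1) thermal time since flowering ≥ maturity
requirement, (2) a night strictly below 0 °C, (3) 5-day mean minimum
below 7 °C, (4) 10-day mean transpiration ratio below 0.1 — evaluated
in that priority order on same-day collisions, windowed rules only once
enough history exists. Kill rules (from emergence): frost at tmin ≤ 0 °C
(inclusive, vs the strict < 0 °C of the senescence rule — both
implemented exactly as stated despite the asymmetry) and the same
10-day drought rule. Death during flowering terminates the season with
the biomass and maturation accrued to that day; death before flowering
zeroes the year's seed and pollen. Terminated and dead states are
absorbing. A season still open on 31 December is closed with reason
`year_end` (reachable only in frost-free, drought-free climates).

## Reproduction and the annual budget

Pollen = 10⁶ grains g⁻¹ × biomass; seed = 300 seeds g⁻¹ × biomass ×
maturation discount, both computed from total stand biomass at season
end. The maturation discount is `min(1, tt_f / maturity_tt)` with a
floor: below 0.2 no seed ripens (the mechanism behind the cold northern
limit). `maturity_tt` defaults to 1200 °Cd, i.e. 1 August to mid-October
at ~15 °Cd d⁻¹ in a favourable climate, so full maturation is possible
in the established core but unreachable where frosts end the season in
September. The two allometric coefficients are order-of-magnitude
placeholders: the seed coefficient is set so that a healthy stand
(~10³ g m⁻²) returns enough seed to overcome 90% predation and the
germination outflow from a 10⁴ seeds m⁻² bank (absolute λ values share
the coefficients' uncertainty; pollen *ratios* across scenarios are
scale-free, which is why scenario impact is reported as a log ratio).

Annual budget:
`seed_out = (seed_in − germinated) · 2^{−1/17} + matured_seed · (1 − predation)`,
`λ = seed_out / seed_in`. λ is strictly positive (at most M = 95% of the
bank germinates and the remainder survives with positive probability),
so Λ = mean log λ is always finite.

## Ensembles, suitability, scenarios

Replicates are independent one-year simulations: one weather year drawn
uniformly from a 100-year generated pool, fresh emergence and predation
draws, a fixed 10⁴ seeds m⁻² starting bank (chaining bank state across
years is the obvious alternative; independence was chosen because each
replicate then estimates the same quantity and Λ's standard error is
interpretable). Exactly two stochastic draws are consumed per replicate
in fixed order, keeping replicate streams aligned across scenarios.

Suitability cut points on Λ default to (−2, −1, −0.5, 0, 0.5) with
lower-inclusive intervals; they are invented (a real calibration needs
observed distribution data) and configuration-first-class. Pollen
change is `log10(P_future/P_baseline)`; where baseline pollen is at or
below a floor (1 grain m⁻²) but the future is not, the capped sentinel
0.85 (> 0.8) marks new colonisation; both at the floor is undefined
(NaN).

## Archetype presets and calibration

Three site presets span the niche limits: `temperate_favourable`
(Po-valley-like, 45°N, deep loam), `mediterranean_dry` (interior
southern Iberia, 38°N, shallow soil, near-rainless summers) and
`boreal_cold` (northern Fennoscandia, 65°N). They were fixed once from
climate normals. The free placeholder constants (germination curve,
maturity_tt, seed coefficient) were calibrated by closed-form reasoning
plus pilot runs so that the favourable archetype sustains an established
population while the dry and cold archetypes fail by their respective
mechanisms — the same role calibration against observed pollen seasons
and distribution played for the unpublished constants of the original
parameterisation. After calibration the defaults were frozen; tests and
the acceptance checks were not used to tune them further.

## Numerical choices

* Seeding: one master seed; per-year weather streams and the replicate
  stream derive from it via spawned `SeedSequence`s; identical inputs
  give bit-identical outputs.
* Dormancy release tolerates 1e-9 float round-off at full release (84
  additions of 1/84 must count as released).
* Threshold recoveries in tests and the acceptance script use
  decimal-exact grids (integers scaled by powers of ten) so grid points
  coincide exactly with printed thresholds.
* Ensemble sizes: tests use 150–300 replicates per site (Λ standard
  error ≈ 0.1 there, far smaller than the class widths and orderings
  asserted); the default for production runs is 1000.
* Degenerate inputs: zero-rain sites, zero-noise climates and empty
  seasons are exercised in tests; polar latitudes and inverted
  temperature inputs raise typed errors rather than propagating NaNs.

## Known limitations

* Absolute pollen and λ magnitudes inherit the placeholder allometry and
  allocation constants; only thresholds, orderings, ratios and
  classifications are robust outputs.
* One soil bucket and no snow model: winter soil is assumed wet and
  unfrozen for germination bookkeeping.
* The emergence distribution's skew direction, the dormancy-response
  bounds, and the growth ceiling are assumptions, all exposed in
  configuration.
* Single-species stands at a fixed density cap; no size hierarchy, no
  competition, no adaptation of flowering date at the range edge.
* Weather realism is limited to first- and second-order statistics of
  temperature and rainfall; heat waves and multi-year drought structure
  are not represented.
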