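# Methods

This note documents the model, its parameters and the numerical and design
choices behind `invasim`, and states what the synthetic test scenarios do
and do not show about real-data applications.

## Model structure

One simulated year proceeds as:

1. **Correlative step.** The previous year's productive agents are the
   presence records. Background points (up to 10 000, at most one per draw,
   cell centres with replacement) are sampled uniformly from the unmasked
   cells of the current extent. Predictors are the trailing long-term
   bioclimatic layers (BCL) with the window ending the year *before* the
   projected year — the model is trained only on information available
   before the year it projects. The fitted model is transferred to the
   current year's yearly layers (BCY) to give the bioclimatic suitability
   surface (BCS). Training AUC is recorded each step.
2. **Climatic window.** Pre-productive seeds (fresh and banked) pass iff
   their cell's accumulated chilling hours meet the threshold; failures are
   banked (once, by default) or discarded. Survivors face an independent
   Bernoulli establishment draw with probability BCS(cell).
3. **Occupancy cap.** Productive candidates (persistent initial agents
   first) are thinned to `sample_per_cell` per grid cell. This is the only
   density regulation in the model; cell counts are scaled, not literal
   population sizes.
4. **Propagule step.** Each productive agent releases `propagule_count`
   seeds at its own location; each seed moves by a uniform random direction
   and a truncated negative-exponential distance, then must satisfy all
   landscape filters (elevation, slope, pH, agricultural cover) at once to
   become next year's pre-productive cohort.
5. The range extent for the next year is the floor/ceil-rounded bounding
   box of the productive coordinates plus a margin.

The first step starts from the grid-sampled initial occurrences and goes
straight to the propagule step (there are no seeds to evaluate yet), so the
first banking happens in step 2 and the first banked re-evaluation in
step 3. Initial agents are persistent: they are productive in every step,
which makes extinction impossible under default settings (the extinction
path exists for configurations that disable persistence).

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `ach_threshold` | 720 | hours | chilling needed to break dormancy (30 full days) |
| ACH window | doy 32–90 | — | February–March accumulation period |
| chilling band | (0, 5] | °C | hourly temperatures that count as chilling |
| `seed_banking_duration` | 1 | steps | retries granted to a failed seed |
| `sample_per_cell` | 1 | agents | productive occupancy cap per 0.25° cell |
| `propagule_count` | 50 | seeds | per productive agent per year |
| `mean_dispersal` | 5 | km | kernel mean (rate parameter 1/5 km⁻¹) |
| `max_dispersal` | 38 | km | hard kernel truncation |
| `max_elevation` | 1000 | m | topographic limit |
| `max_slope` | 20 | degrees | topographic limit |
| `ph_min, ph_max` | 4.5, 7.7 | pH | edaphic tolerance |
| `max_agri_fraction` | 0.8 | fraction | land-use limit |
| `bcl_window` | 30 | years | trailing mean for training layers |
| extent margin | 2 | degrees | padding around the occupied bounding box |

All threshold comparisons are inclusive, so the printed limits are
themselves admissible; the boundaries are configurable.

## The suitability engine

The maximum-entropy presence-background model is implemented in its
penalized-logistic-regression equivalent form: linear + quadratic features
(optionally hinge, off by default) of min-max-normalized predictors,
presence-vs-background labels, an L1 penalty of 0.05 per feature scaled by
the feature's training standard deviation, and a complementary log-log link
`1 − exp(−exp(η))` mapping the linear predictor to [0, 1]. The penalty is
scaled to the presence count so that the fit is invariant to duplicating
training rows and does not wash out under presence/background imbalance.
The engine sits behind a small model contract so alternative engines can be
substituted. Deliberate simplifications relative to the classic MaxEnt
software: no product/threshold feature classes, no cumulative/raw output
formats, and variable selection (permutation importance on training data)
is a pre-simulation configuration step rather than part of the loop;
spatial block cross-validation is out of scope.

## Climate derivation

* **Linear scaling.** Per cell and calendar month, temperatures are
  corrected additively by the observed-minus-model mean difference over the
  overlap years and precipitation multiplicatively by the ratio of means
  (model mean guarded at 0.01 mm/day); corrected precipitation is clipped
  at zero and tmin capped at tmax where independent corrections cross.
* **BIOCLIM.** Monthly mean temperature is (tmax+tmin)/2; quarters are
  running 3-month windows wrapping December–January; wettest/driest
  quarters by precipitation sum, warmest/coldest by mean temperature, ties
  broken by the earliest start month; BIO4 = 100 × population sd of monthly
  means; BIO15 = 100 × sd/(1 + mean) of monthly precipitation.
* **Diurnal downscaling.** A single cosine with fixed extrema (minimum at
  05:00, maximum at 17:00) reconstructs 24 hourly temperatures from the
  daily extremes. This deviates from sunrise-dependent interpolation used
  by chilling packages: it is deterministic, latitude-free and exact at
  tmin/tmax, and chilling accumulation only needs band membership.
* **Chilling.** An hour chills when its temperature lies in (floor, base]
  with floor 0 °C and base 5 °C: hours at or below freezing do not count.
  Whether frozen hours should count is a genuine convention choice; the
  floor is configurable.
* Calendar: proleptic Gregorian with leap years; day-of-year 32 is
  February 1 in non-leap years.

## Spatial conventions

Coordinates are WGS84 degrees. Grids are lower-left anchored with half-open
cells and row index increasing northward. Slope uses Horn's 8-neighbour
stencil with the east–west cell dimension scaled by cos(latitude) and
nearest-valid-neighbour padding at borders and masked cells. Finer-grained
fields are evaluated at agent locations by nearest-cell lookup rather than
pre-aggregated. Dispersal converts kilometres to degrees with a local
equirectangular approximation (111.32 km/degree) and raises beyond ±89°
latitude. Agents landing on masked cells or outside all layers are
discarded as off-habitat. Band membership and the moderate-agreement cut
are half-open/strict: a cell at exactly 50% agreement is excluded, a cell
centre exactly on a band edge belongs to the upper band. "Invaded in a
period" means invaded in any year of the period. Foci are connected
components under queen (8-neighbour) adjacency. Known-irresponsive foci can
be excluded through an optional cell mask rather than automatically.

## Synthetic scenarios

The generator imposes: daily mid temperature = southern-edge annual mean −
lapse × Δlatitude + warming × Δyear − seasonal cosine (amplitude 10 °C,
coldest mid-January) + Gaussian noise (sd 0.5 °C); a diurnal range of 6 °C
with mild longitudinal modulation; smooth positive precipitation with a
seasonal cycle and lognormal noise; an elevation plain with a western
Gaussian ridge; and soil pH and agricultural-cover gradients that vary with
longitude only, so the latitudinal dynamics are driven purely by climate.
Occurrences are rejection-sampled around uniformly placed cluster centres
from cells whose noise-free annual mean temperature lies in the suitable
band and which pass the default landscape filters.

Defaults (100×100 cells at 0.25°, latitudes 35–60° N, lapse 0.8 °C/deg,
300 occurrences) were chosen so that a 30-step, 10-simulation ensemble
completes in a few minutes on one CPU and so that the chilling window and
the occurrence band are concentric: the band (BIO1 ∈ [8.8, 10.0] °C,
≈1.5° of latitude) sits centred inside the chilling-admissible zone with
≈1.4° of slack on each side. Centring matters for the stationary control —
if the band sits asymmetrically inside the chilling zone, range overshoot
is clipped on one side only and the control itself drifts poleward. The
`moving_band` preset warms at 0.05 °C/yr, translating the band by
≈0.06° latitude per year, well below the colonization speed afforded by 50
propagules on a 5 km kernel, so the population tracks the band. Because the
training layers are a 30-year trailing mean, they lag current climate by
≈15 × warming; transferring the model to current-year layers displaces the
predicted suitable zone poleward of the occupied band, which is the main
mechanism pulling the front north.

What the synthetic tests do **not** show: realistic spatial covariance of
weather, interannual variability beyond white noise, dispersal vectors
(rivers, roads, trade), biotic interactions, or the behaviour of the model
on real heterogeneous landscapes. Passing them demonstrates the coupled
machinery — training/transfer, gating, dispersal, filtering, ensemble
statistics — behaves correctly and reproducibly under controlled forcing,
not that projections for any particular species or region are accurate.

## Numerical choices

* Background sampling uses cell centres; drawing with replacement keeps the
  sample size independent of extent size.
* The logistic solver (liblinear) runs at tolerance 1e-4 by default —
  indistinguishable training AUC at a fraction of the cost; a tighter
  tolerance can be passed where near-exact coefficient reproducibility is
  needed. The solver seed is fixed, making the whole loop deterministic
  under the per-simulation RNG stream (seeds derived as master + index,
  one stream per simulation, fixed call order).
* With fewer than two presences the correlative step is skipped and
  establishment left to the remaining gates (degenerate configurations
  only).
* Permutation importance floors negative AUC drops at zero and normalizes
  each repetition to 100%; if every drop is zero the repetition is split
  uniformly.
* Zero-variance predictors raise rather than silently dropping columns.

## Limitations

Annual life history is hard-coded (only initial agents persist across
years); density dependence beyond the occupancy cap, long-distance and
vector-mediated dispersal, and biotic interactions are not modelled.
Reprojection between coordinate systems is out of scope; all layers must
share one geographic grid per run.
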