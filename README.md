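# invasim

Hybrid, spatially explicit simulation of invasive plant range expansion,
coupling a correlative species distribution model with an agent-based
population model in a yearly loop.

## The problem

Correlative species distribution models (SDMs) assume equilibrium with
climate and unlimited dispersal — assumptions an ongoing invasion violates.
`invasim` couples the two standard approaches so that neither has to carry
the projection alone:

* **Correlative component (CC).** Each simulated year a presence-background
  suitability model is trained on the *simulated* occurrences of the
  previous year against background points sampled inside the current range
  extent, using trailing 30-year mean bioclimatic layers (BCL) as
  predictors, and is transferred to the current year's bioclimatic layers
  (BCY) to produce a bioclimatic suitability surface (BCS) in [0, 1].
* **Agent-based component (ABC).** Individual plants of an annual species
  live on the map. Ungerminated seeds must accumulate enough winter
  chilling (ACH ≥ 720 h in the February–March window, hourly temperatures
  in (0, 5] °C) to break dormancy, survive a Bernoulli establishment draw
  with probability BCS(cell), and pass through a per-cell occupancy cap
  (1 productive agent per 0.25° cell). Mature plants each release 50
  propagules that disperse with a uniform random direction and a truncated
  negative-exponential distance (mean 5 km, maximum 38 km, inverse-CDF
  sampling `d = −μ ln(1 − u(1 − e^{−D/μ}))`), and each seed establishes
  only where elevation ≤ 1000 m, slope ≤ 20°, soil pH ∈ [4.5, 7.7] and
  agricultural cover ≤ 80%. Seeds that fail chilling are banked for one
  year; the initial (occurrence-derived) agents persist throughout.

Ensembles of stochastic simulations are summarized as inter-simulation
agreement maps (the fraction of runs invading each cell), invaded-cell
counts per latitudinal/longitudinal band (ICC) with inter-period increments
(IPI), range centroid and boundary shifts, and connected invasion foci.

A seeded synthetic-scenario generator (daily climate with a latitudinal
lapse, optional warming trend, elevation ridge, soil and land-use
gradients, clustered occurrences) makes the entire loop runnable and
testable with no external data.

## Worked example

`examples/04_dispersal_and_filters.py` probes the behavioural thresholds:

```
dispersal: empirical mean 4.981 km vs analytic 4.981 km, max 38.00 km (truncation 38 km)
dormancy breaks after 30 fully chilling days = 720 hours
warmest still-chilling constant temperature: 5.0 C
max elevation among filter survivors on a 0-3000 gradient: 1000.00 m
max agri among filter survivors on a 0-1 gradient: 0.80 fraction
max ph among filter survivors on a 3-9 gradient: 7.70 pH
```

A million kernel draws reproduce the analytic truncated-exponential mean;
the landscape filter admits exactly the documented inclusive limits; thirty
full chilling days (720 hours) break dormancy.

`examples/05_coupled_ensemble.py` runs a small warming ensemble
(40×40 cells, 15 steps, 3 simulations, ~0.1 °C/yr):

```
simulation 0, per-year productive agents and training AUC:
  2020:   69 productive, AUC 0.880
  ...
  2032:  167 productive, AUC 0.851

moderate-agreement (>50%) cells: 149 initial period, 197 final period
centroid latitude shift: +0.17 deg (positive = northward, tracking the warming-displaced band)
northern boundary shift: +0.50 deg
```

The population grows, the retrained suitability model keeps discriminating
occupied from unoccupied climate (AUC ≈ 0.85–0.88), and the invaded range
expands northward as warming displaces the suitable band — the qualitative
signature of a climate-tracking invasion.

The other examples cover the synthetic scenario (`01`), BIOCLIM/chilling
derivation (`02`), suitability fitting and permutation importance (`03`)
and one-factor-at-a-time sensitivity (`06`).

## Command line

```bash
invasim synth --preset moving_band --out fixtures/     # input bundle
invasim simulate --config run.yaml --out results/ [--seed N] [--n-sims K]
invasim analyze --results results/ --out analysis/
invasim ofat --config run.yaml --parameter mean_dispersal \
             --values 2,5,8,11,14 --out ofat.csv
```

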