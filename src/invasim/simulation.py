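"""The coupled yearly loop: correlative training + agent procedures.

Each simulated year:

1. The correlative component trains the suitability model on the previous
   step's productive agents (presences) against background points sampled
   within the current extent, using the trailing long-term bioclimatic
   layers (BCL, window ending the year before), and transfers the model to
   the current year's yearly layers (BCY) to produce the emergent
   bioclimatic-suitability layer (BCS).
2. Pre-productive and banked agents face the Climatic Window procedure
   (chilling-hour check with seed banking, then the Bernoulli BCS gate),
   join the persistent initial agents, and are thinned to the per-cell cap
   to form the year's productive population.
3. Productive agents release propagules, which disperse and face the
   Landscape Suitability procedure to become next year's pre-productive
   agents.
4. The extent is rebuilt from the productive coordinates (floor/ceil plus
   margin) for the next step.

The first step starts from the grid-sampled initial occurrences and goes
straight to the Propagule procedure: there are no seeds to chill or gate
yet.  Initial agents are persistent — productive in every step — so a
simulation cannot go extinct unless persistence is disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abm
from .abm import ABMConfig, AgentSet
from .landscape import Extent, GridSpec, Layer, OccurrenceSet, constant_layer, crop, make_extent
from .suitability import (DEFAULT_BACKGROUND_N, FittedSuitabilityModel, PresenceBackground,
                          fit_suitability, sample_background, training_auc)

logger = logging.getLogger(__name__)


@dataclass
class CCConfig:
    """Correlative-component settings."""

    variables: list[str] | None = None  # None = every available BIOCLIM layer
    reg: float = 0.05                   # L1 penalty per feature
    background_n: int = DEFAULT_BACKGROUND_N
    hinge: bool = False
    enabled: bool = True                # if False, BCS is 1 everywhere


@dataclass
class SimulationConfig:
    start_year: int = 2020
    end_year: int = 2050
    abm: ABMConfig = field(default_factory=ABMConfig)
    cc: CCConfig = field(default_factory=CCConfig)
    bcl_window: int = 30
    margin: float = 2.0
    n_simulations: int = 50
    seed: int = 0
    record_agents: bool = False  # keep per-year productive snapshots

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be at least 1")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass
class SimulationState:
    step: int
    productive: AgentSet
    pre_productive: AgentSet
    banked: AgentSet
    extent: Extent
    bcs_layer: Layer | None = None
    trained_model: FittedSuitabilityModel | None = None
    next_id: int = 0


@dataclass
class SimulationRecord:
    """Per-year outputs of one simulation."""

    sim_index: int
    grid: GridSpec
    invaded: dict[int, np.ndarray] = field(default_factory=dict)  # year -> flat cell ids
    auc: dict[int, float] = field(default_factory=dict)
    counts: list[dict] = field(default_factory=list)
    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)
    extinct_year: int | None = None

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts)


@dataclass
class EnsembleResult:
    grid: GridSpec
    years: list[int]
    records: list[SimulationRecord]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_simulations(self) -> int:
        return len(self.records)


def initialize(occurrences: OccurrenceSet, config: SimulationConfig,
               grid: GridSpec, rng: np.random.Generator) -> SimulationState:
    """Grid-sample the occurrences into persistent initial productive agents."""
    if len(occurrences) == 0:
        raise ValueError("no occurrences: nothing to initialize from")
    agents = AgentSet.create(occurrences.lon, occurrences.lat, abm.PRODUCTIVE)
    agents = abm.grid_sample(agents, grid, config.abm.sample_per_cell, rng)
    if len(agents) == 0:
        raise ValueError("no occurrences fall inside the working grid")
    agents.persistent = np.ones(len(agents), bool)
    agents.ids = np.arange(len(agents), dtype=np.int64)
    extent = make_extent((agents.lon, agents.lat), config.margin)
    return SimulationState(
        step=config.start_year,
        productive=agents,
        pre_productive=AgentSet(),
        banked=AgentSet(),
        extent=extent,
        next_id=len(agents),
    )


def _cc_predict(state: SimulationState, provider, config: SimulationConfig,
                rng: np.random.Generator, year: int) -> tuple[Layer, FittedSuitabilityModel | None, float]:
    """Train on previous productive agents + BCL, transfer to current BCY."""
    cc = config.cc
    if not cc.enabled:
        bcs = crop(constant_layer(provider.grid, 1.0, "BCS", "emergent"), state.extent)
        return bcs, None, float("nan")
    if len(state.productive) < 2:
        # too few presences to train: leave establishment to the other gates
        logger.warning("year %d: <2 presences, skipping CC training", year)
        bcs = crop(constant_layer(provider.grid, 1.0, "BCS", "emergent"), state.extent)
        return bcs, None, float("nan")
    bcl = provider.bcl(year - 1)
    variables = cc.variables if cc.variables is not None else list(bcl.layers)
    train_layers = {v: crop(bcl[v], state.extent) for v in variables}
    unmasked = int((~next(iter(train_layers.values())).mask).sum())
    n_bg = min(cc.background_n, unmasked)
    background = sample_background(state.extent, train_layers, n_bg, rng)
    presences = np.column_stack([state.productive.lon, state.productive.lat])
    data = PresenceBackground.from_layers(presences, background, train_layers)
    model = fit_suitability(data, reg=cc.reg, hinge=cc.hinge)
    auc_val = training_auc(model, data)
    bcy = provider.bcy(year)
    predict_layers = {v: crop(bcy[v], state.extent) for v in variables}
    bcs = model.predict(predict_layers)
    return bcs, model, auc_val


def step(state: SimulationState, provider, config: SimulationConfig,
         rng: np.random.Generator, first: bool = False) -> SimulationState:
    """Advance one year; ``state.step`` is the year being simulated."""
    year = state.step
    grid = provider.grid
    cfg_abm = config.abm

    bcs, model, auc_val = _cc_predict(state, provider, config, rng, year)

    if first:
        productive = state.productive
        banked_next = state.banked
    else:
        candidates = AgentSet.concat([state.pre_productive, state.banked])
        passed, banked_next, _ = abm.chilling_check(candidates, provider.ach(year), cfg_abm)
        established = abm.bioclimatic_gate(passed, bcs, rng).with_stage(abm.PRODUCTIVE)
        keepers = state.productive.subset(state.productive.persistent)
        productive = abm.grid_sample(AgentSet.concat([keepers, established]),
                                     grid, cfg_abm.sample_per_cell, rng)

    if len(productive) == 0 and len(banked_next) == 0:
        logger.warning("simulation extinct in year %d", year)
        return SimulationState(year + 1, productive, AgentSet(), banked_next,
                               state.extent, bcs, model, state.next_id)

    propagules = abm.produce_propagules(productive, cfg_abm, step=year,
                                        id_start=state.next_id)
    next_id = state.next_id + len(propagules)
    dispersed = abm.disperse(propagules, cfg_abm.kernel, rng)
    pre_next = abm.landscape_filter(dispersed, provider.elevation, provider.slope,
                                    provider.ph, provider.agri(year), cfg_abm)

    if len(productive):
        extent = make_extent((productive.lon, productive.lat), config.margin)
    else:
        extent = state.extent
    new_state = SimulationState(year + 1, productive, pre_next, banked_next,
                                extent, bcs, model, next_id)
    new_state._auc = auc_val  # type: ignore[attr-defined]
    return new_state


def invaded_cells(productive: AgentSet, grid: GridSpec) -> np.ndarray:
    """Sorted flat indices of base-grid cells holding >= 1 productive agent."""
    if len(productive) == 0:
        return np.empty(0, np.int64)
    r, c = grid.cell_of(productive.lon, productive.lat)
    inside = r >= 0
    return np.unique(grid.flat_index(r[inside], c[inside]))


def run_simulation(occurrences: OccurrenceSet, provider, config: SimulationConfig,
                   seed: int, sim_index: int = 0) -> SimulationRecord:
    """One full trajectory over ``config.years``."""
    rng = np.random.default_rng(seed)
    grid = provider.grid
    state = initialize(occurrences, config, grid, rng)
    record = SimulationRecord(sim_index=sim_index, grid=grid)
    for i, year in enumerate(config.years):
        state.step = year
        state = step(state, provider, config, rng, first=(i == 0))
        record.invaded[year] = invaded_cells(state.productive, grid)
        record.auc[year] = getattr(state, "_auc", float("nan"))
        if config.record_agents:
            record.snapshots[year] = state.productive.to_dataframe()
        record.counts.append({
            "year": year,
            "productive": len(state.productive),
            "pre_productive": len(state.pre_productive),
            "banked": len(state.banked),
            "auc": record.auc[year],
        })
        if (len(state.productive) == 0 and len(state.pre_productive) == 0
                and len(state.banked) == 0):
            record.extinct_year = year
            logger.warning("simulation %d extinct in %d", sim_index, year)
            break
    return record


def run_ensemble(occurrences: OccurrenceSet, provider,
                 config: SimulationConfig) -> EnsembleResult:
    """Independent simulations with per-simulation seeds ``seed + index``.

    A failure in one simulation is recorded and the ensemble continues.
    """
    records: list[SimulationRecord] = []
    failures: list[tuple[int, str]] = []
    for i in range(config.n_simulations):
        try:
            records.append(run_simulation(occurrences, provider, config,
                                          seed=config.seed + i, sim_index=i))
        except Exception as exc:  # noqa: BLE001 - ensemble must survive one bad run
            logger.exception("simulation %d failed", i)
            failures.append((i, str(exc)))
    return EnsembleResult(provider.grid, list(config.years), records, failures)
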