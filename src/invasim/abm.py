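"""Agent-based component: agent life cycle and the three yearly procedures.

Agents are point individuals of an annual plant.  Each simulated year a
pre-productive agent (an ungerminated seed) must pass the Climatic Window
procedure — enough accumulated chilling hours to break dormancy, then a
Bernoulli establishment draw against the bioclimatic suitability layer —
before it matures.  Mature (productive) agents are thinned to a per-cell cap,
release a fixed number of propagules that disperse with a uniform direction
and a truncated negative-exponential distance, and the dispersed seeds face
the Landscape Suitability procedure (elevation, slope, soil pH, agricultural
cover).  Seeds that fail chilling are banked for a limited number of steps.

The container is vectorized (struct-of-arrays) so populations of 10^5-10^6
agents stay cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .landscape import KM_PER_DEG, GridSpec, Layer

logger = logging.getLogger(__name__)

# life-cycle stage codes
PRODUCTIVE = 0
POST_GENERATION = 1
PRE_PRODUCTIVE = 2
BANKED = 3

STAGE_NAMES = {
    PRODUCTIVE: "productive",
    POST_GENERATION: "post_generation",
    PRE_PRODUCTIVE: "pre_productive",
    BANKED: "banked",
}


@dataclass
class ABMConfig:
    """Ecological thresholds and kernel parameters of the agent component.

    Threshold comparisons are inclusive: an agent at exactly the printed
    limit (1000 m, 20 deg, pH 7.7, 80% cover, 720 h) is admissible.
    """

    ach_threshold: float = 720.0       # chilling hours to break dormancy
    seed_banking_duration: int = 1     # steps a failed seed is retained
    sample_per_cell: int = 1           # productive agents kept per cell
    propagule_count: int = 50          # seeds per productive agent
    mean_dispersal: float = 5.0        # km, kernel mean before truncation
    max_dispersal: float = 38.0        # km, kernel truncation
    max_elevation: float = 1000.0      # m
    max_slope: float = 20.0            # degrees
    ph_min: float = 4.5
    ph_max: float = 7.7
    max_agri_fraction: float = 0.8     # proportion of agricultural cover

    def __post_init__(self) -> None:
        if self.ph_min >= self.ph_max:
            raise ValueError("ph_min must be below ph_max")
        if not (0 < self.mean_dispersal < self.max_dispersal):
            raise ValueError("require 0 < mean_dispersal < max_dispersal")
        if self.seed_banking_duration < 0 or self.sample_per_cell < 1:
            raise ValueError("invalid banking duration or per-cell sample size")

    @property
    def kernel(self) -> "DispersalKernel":
        return DispersalKernel(self.mean_dispersal, self.max_dispersal)


def permissive_config(**overrides) -> ABMConfig:
    """An ABMConfig whose every filter is trivially satisfiable.

    Growth under this configuration is limited only by the per-cell
    sampling cap (useful as an upper-bound control).
    """
    base = dict(
        ach_threshold=0.0,
        max_elevation=np.inf,
        max_slope=90.0,
        ph_min=-np.inf,
        ph_max=np.inf,
        max_agri_fraction=1.0,
    )
    base.update(overrides)
    return ABMConfig(**base)


@dataclass(frozen=True)
class DispersalKernel:
    """Truncated negative-exponential dispersal distance distribution.

    ``mean`` is the rate-defining mean of the untruncated exponential (km);
    ``truncation`` the hard maximum distance.  Sampling is by inverse CDF:
    ``d = -mu * ln(1 - u * (1 - exp(-D/mu)))``.
    """

    mean: float
    truncation: float

    def __post_init__(self) -> None:
        if not (0 < self.mean < self.truncation):
            raise ValueError("require 0 < mean < truncation")

    @property
    def rate(self) -> float:
        return 1.0 / self.mean

    def quantile(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        mu, D = self.mean, self.truncation
        return -mu * np.log1p(-u * (1.0 - np.exp(-D / mu)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.quantile(rng.random(n))

    @property
    def analytic_mean(self) -> float:
        """Mean of the truncated distribution: mu - D e^{-D/mu}/(1 - e^{-D/mu})."""
        mu, D = self.mean, self.truncation
        q = np.exp(-D / mu)
        return mu - D * q / (1.0 - q)


@dataclass
class AgentSet:
    """Vectorized collection of agents (struct of arrays)."""

    ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    lon: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    lat: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    stage: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    bank_age: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    born_step: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    persistent: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def __len__(self) -> int:
        return self.ids.size

    @classmethod
    def create(cls, lon, lat, stage, ids=None, bank_age=0, born_step=0,
               persistent=False) -> "AgentSet":
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        n = lon.size
        if ids is None:
            ids = np.arange(n, dtype=np.int64)
        return cls(
            ids=np.asarray(ids, np.int64),
            lon=lon,
            lat=np.atleast_1d(np.asarray(lat, dtype=float)),
            stage=np.full(n, stage, np.int8),
            bank_age=np.broadcast_to(np.asarray(bank_age, np.int32), (n,)).copy(),
            born_step=np.broadcast_to(np.asarray(born_step, np.int32), (n,)).copy(),
            persistent=np.broadcast_to(np.asarray(persistent, bool), (n,)).copy(),
        )

    def subset(self, idx) -> "AgentSet":
        return AgentSet(self.ids[idx], self.lon[idx], self.lat[idx], self.stage[idx],
                        self.bank_age[idx], self.born_step[idx], self.persistent[idx])

    @staticmethod
    def concat(sets: list["AgentSet"]) -> "AgentSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return AgentSet()
        return AgentSet(*(np.concatenate([getattr(s, f) for s in sets])
                          for f in ("ids", "lon", "lat", "stage", "bank_age",
                                    "born_step", "persistent")))

    def with_stage(self, stage: int) -> "AgentSet":
        out = self.subset(slice(None))
        out.stage = np.full(len(self), stage, np.int8)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "id": self.ids, "lon": self.lon, "lat": self.lat,
            "stage": [STAGE_NAMES[s] for s in self.stage],
            "bank_age": self.bank_age, "born_step": self.born_step,
            "persistent": self.persistent,
        })


def chilling_check(agents: AgentSet, ach: Layer, config: ABMConfig
                   ) -> tuple[AgentSet, AgentSet, AgentSet]:
    """Climatic Window, chilling + seed-banking sub-procedures.

    Returns ``(passed, banked, discarded)``: agents on cells with at least
    ``ach_threshold`` chilling hours pass; failing agents are banked with
    incremented ``bank_age`` until the banking duration is exhausted, then
    discarded.  Agents off the layer (or on masked cells) are discarded.
    """
    vals, valid = ach.sample(agents.lon, agents.lat)
    if (~valid).any():
        logger.warning("%d agents off the ACH layer discarded", int((~valid).sum()))
    passed = valid & (vals >= config.ach_threshold)
    fail = valid & ~passed
    bankable = fail & (agents.bank_age < config.seed_banking_duration)
    discarded = (~valid) | (fail & ~bankable)

    banked = agents.subset(bankable).with_stage(BANKED)
    banked.bank_age = banked.bank_age + 1
    return agents.subset(passed), banked, agents.subset(discarded)


def bioclimatic_gate(agents: AgentSet, bcs: Layer, rng: np.random.Generator) -> AgentSet:
    """Bernoulli establishment: each agent survives with probability BCS(cell).

    Agents on masked cells are discarded.
    """
    p, valid = bcs.sample(agents.lon, agents.lat)
    p = np.where(valid, p, 0.0)
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ValueError("BCS values outside [0, 1]")
    u = rng.random(len(agents))
    return agents.subset(u < p)


def grid_sample(agents: AgentSet, grid: GridSpec, sample_per_cell: int,
                rng: np.random.Generator) -> AgentSet:
    """Cap the number of agents per grid cell.

    Persistent agents are retained first; remaining slots are filled by a
    uniform random subset of the rest.  Cells at or under the cap are
    returned unchanged.  Agents outside the grid are dropped.
    """
    if len(agents) == 0:
        return agents
    r, c = grid.cell_of(agents.lon, agents.lat)
    inside = r >= 0
    cell = grid.flat_index(r, c)
    # sort by (cell, persistent-first, random key); keep first k per cell
    key = rng.random(len(agents))
    order = np.lexsort((key, ~agents.persistent, cell))
    cell_sorted = cell[order]
    new_cell = np.ones(len(agents), bool)
    new_cell[1:] = cell_sorted[1:] != cell_sorted[:-1]
    group_start = np.maximum.accumulate(np.where(new_cell, np.arange(len(agents)), 0))
    rank = np.arange(len(agents)) - group_start
    keep_sorted = rank < sample_per_cell
    keep = np.zeros(len(agents), bool)
    keep[order] = keep_sorted
    keep &= inside
    return agents.subset(keep)


def produce_propagules(productive: AgentSet, config: ABMConfig, step: int,
                       id_start: int = 0) -> AgentSet:
    """Each productive agent yields ``propagule_count`` post-generation agents
    at the parent's coordinates with fresh ids."""
    k = config.propagule_count
    n = len(productive) * k
    return AgentSet.create(
        lon=np.repeat(productive.lon, k),
        lat=np.repeat(productive.lat, k),
        stage=POST_GENERATION,
        ids=id_start + np.arange(n, dtype=np.int64),
        born_step=step,
    )


def disperse(agents: AgentSet, kernel: DispersalKernel,
             rng: np.random.Generator) -> AgentSet:
    """Move each agent by a uniform random direction and a kernel distance.

    Displacement uses the local equirectangular approximation
    (111.32 km per degree of latitude, scaled by cos(lat) for longitude);
    invalid near the poles.
    """
    if np.any(np.abs(agents.lat) >= 89.0):
        raise ValueError("dispersal approximation invalid at |lat| >= 89 degrees")
    n = len(agents)
    theta = rng.random(n) * 2.0 * np.pi
    d = kernel.quantile(rng.random(n))
    out = agents.subset(slice(None))
    out.lat = agents.lat + d * np.cos(theta) / KM_PER_DEG
    out.lon = agents.lon + d * np.sin(theta) / (KM_PER_DEG * np.cos(np.radians(agents.lat)))
    return out


def landscape_filter(agents: AgentSet, elev: Layer, slope: Layer, ph: Layer,
                     agri: Layer, config: ABMConfig) -> AgentSet:
    """Landscape Suitability procedure: all conditions must hold at once.

    Survivors become pre-productive with ``bank_age`` 0.  Agents outside any
    layer (or on masked cells) are discarded; the sub-procedure order is
    immaterial since the conditions are conjunctive.
    """
    e, ok_e = elev.sample(agents.lon, agents.lat)
    s, ok_s = slope.sample(agents.lon, agents.lat)
    p, ok_p = ph.sample(agents.lon, agents.lat)
    a, ok_a = agri.sample(agents.lon, agents.lat)
    valid = ok_e & ok_s & ok_p & ok_a
    if (~valid).any():
        logger.warning("%d agents outside the landscape layers discarded",
                       int((~valid).sum()))
    good = (
        valid
        & (e <= config.max_elevation)
        & (s <= config.max_slope)
        & (p >= config.ph_min) & (p <= config.ph_max)
        & (a <= config.max_agri_fraction)
    )
    out = agents.subset(good).with_stage(PRE_PRODUCTIVE)
    out.bank_age = np.zeros(len(out), np.int32)
    return out
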