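"""Small single-factor experiments probing the agent filters and kernels.

Each routine builds a minimal synthetic input (a one-cell daily series, a
one-dimensional landscape gradient), runs the relevant package code path
(chilling accumulation + chilling check, landscape filter, dispersal
kernel) and measures the behavioural threshold it exposes.  They exist so
that configuration values are exercised as behaviour rather than read back
from a config object.
"""

from __future__ import annotations

import numpy as np

from . import abm
from .abm import ABMConfig, AgentSet
from .climate import DailyClimate, accumulated_chilling_hours, days_in_year
from .landscape import GridSpec, Layer, constant_layer


def _one_cell_daily(temps: np.ndarray, year: int = 2021) -> DailyClimate:
    g = GridSpec(1.0, 0.0, 0.0, 1, 1)
    arr = np.asarray(temps, dtype=float)[:, None, None]
    dc = DailyClimate(g)
    dc.add_year(year, arr.copy(), arr.copy(), np.zeros_like(arr))
    return dc


def minimal_chilling_days(config: ABMConfig | None = None,
                          chill_temp: float = 2.0, hot_temp: float = 30.0,
                          doy_start: int = 32, doy_end: int = 90,
                          year: int = 2021) -> tuple[int, float]:
    """Fewest consecutive fully-chilling days that break dormancy.

    Builds daily series with ``d`` days at ``chill_temp`` (inside the
    chilling band all 24 hours) at the start of the accumulation window and
    ``hot_temp`` elsewhere, and finds the minimal ``d`` for which a fresh
    pre-productive agent passes the chilling check.  Returns ``(d, ach)``
    with ``ach`` the accumulated hours at that ``d``.
    """
    config = ABMConfig() if config is None else config
    window = doy_end - doy_start + 1
    for d in range(0, window + 1):
        temps = np.full(days_in_year(year), hot_temp)
        temps[doy_start - 1:doy_start - 1 + d] = chill_temp
        dc = _one_cell_daily(temps, year)
        ach = accumulated_chilling_hours(dc, year, doy_start, doy_end)
        agent = AgentSet.create([0.5], [0.5], abm.PRE_PRODUCTIVE)
        passed, _, _ = abm.chilling_check(agent, ach, config)
        if len(passed):
            return d, float(ach.values[0, 0])
    raise RuntimeError("chilling threshold not reachable within the window")


def max_chilling_temperature(step: float = 0.5, t_lo: float = -5.0,
                             t_hi: float = 10.0, year: int = 2021) -> float:
    """Highest constant temperature (on a ``step`` grid) that still chills."""
    best = None
    for t in np.arange(t_lo, t_hi + step / 2, step):
        dc = _one_cell_daily(np.full(days_in_year(year), t), year)
        ach = accumulated_chilling_hours(dc, year)
        if ach.values[0, 0] > 0:
            best = float(t)
    if best is None:
        raise RuntimeError("no probed temperature accumulates chilling hours")
    return best


def _gradient_setup(field: str, lo: float, hi: float, n_cells: int):
    """One-row landscape with a west-east gradient in one field, the rest benign."""
    g = GridSpec(0.1, 0.0, 0.0, 1, n_cells)
    gradient = np.linspace(lo, hi, n_cells)[None, :]
    benign = {"elevation": 100.0, "slope": 0.0, "ph": 6.5, "agri": 0.1}
    layers = {k: constant_layer(g, v, k) for k, v in benign.items()}
    layers[field] = Layer(g, gradient, np.zeros(g.shape, bool), field, "static")
    return g, layers


def gradient_filter_max(field: str, lo: float, hi: float,
                        rng: np.random.Generator, n_cells: int = 301,
                        n_agents: int = 3000,
                        config: ABMConfig | None = None) -> float:
    """Maximum gradient value among cells hosting landscape-filter survivors.

    Scatters post-generation agents uniformly over the gradient, applies the
    Landscape Suitability procedure with ``config`` (defaults) and returns
    the maximum value of ``field`` at the survivors' cells.
    """
    config = ABMConfig() if config is None else config
    g, layers = _gradient_setup(field, lo, hi, n_cells)
    lon = rng.uniform(0.0, g.lon_max, n_agents)
    lat = np.full(n_agents, 0.05)
    agents = AgentSet.create(lon, lat, abm.POST_GENERATION)
    survivors = abm.landscape_filter(agents, layers["elevation"], layers["slope"],
                                     layers["ph"], layers["agri"], config)
    if len(survivors) == 0:
        raise RuntimeError(f"no survivors on the {field} gradient")
    vals, _ = layers[field].sample(survivors.lon, survivors.lat)
    return float(np.max(vals))


def dispersal_statistics(mean: float = 5.0, truncation: float = 38.0,
                         n_draws: int = 1_000_000,
                         rng: np.random.Generator | None = None) -> dict[str, float]:
    """Empirical moments of the truncated negative-exponential kernel."""
    rng = np.random.default_rng() if rng is None else rng
    kernel = abm.DispersalKernel(mean, truncation)
    d = kernel.sample(rng, n_draws)
    return {
        "empirical_max": float(d.max()),
        "empirical_mean": float(d.mean()),
        "analytic_mean": kernel.analytic_mean,
    }
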