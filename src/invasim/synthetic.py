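"""Seeded synthetic landscapes, daily climates and occurrences.

The generator emulates the minimal structure the hybrid loop needs from real
inputs: a daily climate with a latitudinal temperature gradient, an annual
cycle, an optional linear warming trend and small Gaussian noise; smooth
positive precipitation; an elevation field with a western mountain ridge; a
soil-pH field; an agricultural-cover gradient; and clustered occurrence
points inside the climatically and edaphically suitable region.  All fields
other than temperature vary with longitude only, so the latitudinal
behaviour of a simulation is driven purely by climate.

Everything is deterministic under the scenario seed; the per-year weather
stream is keyed by ``(seed, year)`` so any year can be regenerated in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from collections import deque

import numpy as np

from .abm import ABMConfig
from .climate import (BIO_NAMES, BioclimSet, DailyClimate, accumulated_chilling_hours,
                      biovars, daily_to_monthly, days_in_year)
from .landscape import GridSpec, Layer, OccurrenceSet, slope_from_elevation

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study region.

    Temperature: annual-mean temperature is ``t_south`` at the southern grid
    edge, decreasing northward by ``lapse`` degC per degree of latitude, plus
    ``warming`` degC per year relative to ``base_year``, an annual cosine of
    amplitude ``seasonal_amplitude`` (coldest mid-January), a fixed diurnal
    range and per-day Gaussian noise.
    """

    n_rows: int = 100
    n_cols: int = 100
    resolution: float = 0.25
    lon_origin: float = -110.0
    lat_origin: float = 35.0
    t_south: float = 18.0            # degC annual mean at the southern edge
    lapse: float = 0.8               # degC per degree latitude
    warming: float = 0.0             # degC per simulated year
    base_year: int = 2020
    seasonal_amplitude: float = 10.0  # degC, annual cycle half-range
    coldest_doy: int = 15             # day-of-year of the coldest day
    diurnal_range: float = 6.0        # degC between tmin and tmax
    noise_sd: float = 0.5             # degC daily noise
    prcp_mean: float = 2.0            # mm/day base rate
    prcp_noise_sd: float = 0.3        # lognormal sd of daily precip noise
    plain_elevation: float = 200.0    # m
    ridge_height: float = 1400.0      # m added on the western ridge
    ridge_lon: float = -107.0
    ridge_width: float = 1.5          # degrees
    ph_west: float = 5.2
    ph_east: float = 7.2
    agri_west: float = 0.0
    agri_east: float = 1.0
    bio1_band: tuple[float, float] = (8.8, 10.0)  # degC suitable annual mean
    n_occurrences: int = 300
    cluster_sd_lon: float = 1.5       # degrees, occurrence cluster spread
    cluster_sd_lat: float = 0.6
    n_clusters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bio1_band[0] >= self.bio1_band[1]:
            raise ValueError("suitable band interval is empty")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.resolution, self.lon_origin, self.lat_origin,
                        self.n_rows, self.n_cols)

    def annual_mean_temperature(self, lat, year: int) -> np.ndarray:
        """Noise-free annual-mean temperature at latitude(s) for a year."""
        lat = np.asarray(lat, dtype=float)
        return (self.t_south - self.lapse * (lat - self.lat_origin)
                + self.warming * (year - self.base_year))


def preset(name: str) -> ScenarioConfig:
    """Named study conditions.

    ``stationary``: no warming, mid-grid suitable band — the no-shift control.
    ``moving_band``: 0.05 degC/yr warming translating the band poleward over
    a 30-step run (the northward-shift testbed).
    ``permissive``: weak gradients and benign landscape fields so that, with
    a permissive agent configuration, growth is limited only by the per-cell
    sampling cap.
    """
    if name == "stationary":
        return ScenarioConfig()
    if name == "moving_band":
        return ScenarioConfig(warming=0.05)
    if name == "permissive":
        return ScenarioConfig(
            t_south=11.5, lapse=0.2, warming=0.0,
            ridge_height=0.0, ph_west=6.0, ph_east=7.0,
            agri_west=0.0, agri_east=0.5,
        )
    raise ValueError(f"unknown preset {name!r}; expected stationary, moving_band or permissive")


def synth_static_layers(cfg: ScenarioConfig) -> dict[str, Layer]:
    """Elevation, slope, soil pH and agricultural-fraction layers."""
    g = cfg.grid
    lon = g.lon_centers()[None, :]
    ones = np.ones(g.shape)
    elev = cfg.plain_elevation + cfg.ridge_height * np.exp(
        -(((lon - cfg.ridge_lon) / cfg.ridge_width) ** 2)) * ones
    lon_frac = (lon - g.lon_origin) / (g.lon_max - g.lon_origin)
    ph = (cfg.ph_west + (cfg.ph_east - cfg.ph_west) * lon_frac) * ones
    agri = np.clip(cfg.agri_west + (cfg.agri_east - cfg.agri_west) * lon_frac, 0, 1) * ones
    nomask = np.zeros(g.shape, bool)
    elev_layer = Layer(g, elev, nomask.copy(), "elevation", "static")
    return {
        "elevation": elev_layer,
        "slope": slope_from_elevation(elev_layer),
        "ph": Layer(g, ph, nomask.copy(), "ph", "static"),
        "agri": Layer(g, agri, nomask.copy(), "agricultural_fraction", "static"),
    }


def synth_daily_year(cfg: ScenarioConfig, year: int) -> DailyClimate:
    """One year of daily tmax/tmin/precipitation for the scenario."""
    g = cfg.grid
    nd = days_in_year(year)
    rng = np.random.default_rng([abs(int(cfg.seed)), int(year)])
    d = np.arange(nd)[:, None, None]
    lat = g.lat_centers()[None, :, None]
    lon = g.lon_centers()[None, None, :]

    season = -cfg.seasonal_amplitude * np.cos(2 * np.pi * (d - (cfg.coldest_doy - 1)) / nd)
    tmid = (cfg.annual_mean_temperature(lat, year) + season
            + rng.normal(0.0, cfg.noise_sd, (nd,) + g.shape))
    # diurnal range: longitudinal modulation (drier interiors, wider range)
    # plus small multiplicative noise; always positive so tmin <= tmax holds
    lon_mod = 1.0 + 0.15 * np.sin(2 * np.pi * (lon - g.lon_origin) / (g.lon_max - g.lon_origin))
    half = (cfg.diurnal_range / 2.0) * lon_mod * np.exp(
        rng.normal(0.0, 0.05, (nd,) + g.shape))
    tmax = tmid + half
    tmin = tmid - half

    lon_factor = 1.0 + 0.4 * np.sin(2 * np.pi * (lon - g.lon_origin) / (g.lon_max - g.lon_origin))
    season_p = 1.0 + 0.5 * np.sin(2 * np.pi * (d - 200) / nd)
    prcp = (cfg.prcp_mean * lon_factor * season_p
            * np.exp(rng.normal(0.0, cfg.prcp_noise_sd, (nd,) + g.shape)))
    prcp = np.clip(prcp, 0.0, None)

    out = DailyClimate(g)
    out.add_year(year, tmax, tmin, prcp)
    return out


def synth_landscape(cfg: ScenarioConfig, years) -> tuple[dict[str, Layer], DailyClimate]:
    """Static layers plus a multi-year daily climate cube.

    Convenience for small scenarios and round-trip tests; for long runs use
    :class:`ScenarioLayers`, which streams the daily data year by year
    instead of holding it all in memory.
    """
    static = synth_static_layers(cfg)
    daily = DailyClimate(cfg.grid)
    for y in years:
        one = synth_daily_year(cfg, y)
        daily.add_year(y, one.tmax[y], one.tmin[y], one.prcp[y])
    return static, daily


def synth_occurrences(cfg: ScenarioConfig, static: dict[str, Layer] | None = None,
                      abm_config: ABMConfig | None = None) -> OccurrenceSet:
    """Clustered occurrence points inside the suitable region.

    Points are rejection-sampled from cells whose (noise-free) annual-mean
    temperature at ``base_year`` lies in ``bio1_band`` and whose landscape
    values pass the default agent filters, around cluster centres drawn
    uniformly from the admissible cells — a crude stand-in for the spatial
    sampling bias of real occurrence archives.
    """
    static = synth_static_layers(cfg) if static is None else static
    abm_config = ABMConfig() if abm_config is None else abm_config
    g = cfg.grid
    lat_c = g.lat_centers()[:, None]
    t_ann = cfg.annual_mean_temperature(lat_c, cfg.base_year) * np.ones(g.shape)
    lo, hi = cfg.bio1_band
    admissible = (
        (t_ann >= lo) & (t_ann <= hi)
        & (static["elevation"].values <= abm_config.max_elevation)
        & (static["slope"].values <= abm_config.max_slope)
        & (static["ph"].values >= abm_config.ph_min)
        & (static["ph"].values <= abm_config.ph_max)
        & (static["agri"].values <= abm_config.max_agri_fraction)
    )
    cells = np.flatnonzero(admissible)
    if cells.size == 0:
        raise ValueError("no admissible cells for occurrence generation")
    rng = np.random.default_rng([abs(int(cfg.seed)), 986_527])
    if cfg.n_occurrences == 0:
        return OccurrenceSet.from_points([], [], [])
    centers = rng.choice(cells, size=min(cfg.n_clusters, cells.size), replace=False)
    cr, cc = np.divmod(centers, g.n_cols)
    clon, clat = g.center_of(cr, cc)

    lons, lats = [], []
    while len(lons) < cfg.n_occurrences:
        k = rng.integers(len(centers))
        lon = clon[k] + rng.normal(0.0, cfg.cluster_sd_lon)
        lat = clat[k] + rng.normal(0.0, cfg.cluster_sd_lat)
        r, c = g.cell_of(lon, lat)
        if r >= 0 and admissible[r, c]:
            lons.append(float(lon))
            lats.append(float(lat))
    years = np.full(cfg.n_occurrences, cfg.base_year)
    return OccurrenceSet.from_points(lons, lats, years)


class ScenarioLayers:
    """Layer provider for the simulation loop, built from a scenario.

    Precomputes, streaming year by year: yearly BIOCLIM sets (BCY) for the
    simulated years, trailing-window means (BCL) labelled by their last year,
    and chilling-hour layers (ACH), while holding at most ``bcl_window``
    yearly sets in the running-mean buffer.
    """

    def __init__(self, cfg: ScenarioConfig, start_year: int, end_year: int,
                 bcl_window: int = 30,
                 ach_kwargs: dict | None = None) -> None:
        self.cfg = cfg
        self.grid = cfg.grid
        self.start_year = start_year
        self.end_year = end_year
        self.bcl_window = bcl_window
        self.static = synth_static_layers(cfg)
        self._bcy: dict[int, BioclimSet] = {}
        self._bcl: dict[int, BioclimSet] = {}
        self._ach: dict[int, Layer] = {}
        ach_kwargs = ach_kwargs or {}

        first_needed = start_year - bcl_window
        window: deque[BioclimSet] = deque(maxlen=bcl_window)
        running = {name: np.zeros(self.grid.shape) for name in BIO_NAMES}
        for year in range(first_needed, end_year + 1):
            daily = synth_daily_year(cfg, year)
            monthly = daily_to_monthly(daily)
            bcy = biovars(monthly, year)
            if start_year <= year <= end_year:
                self._bcy[year] = bcy
                self._ach[year] = accumulated_chilling_hours(daily, year, **ach_kwargs)
            if len(window) == bcl_window:
                dropped = window[0]
                for name in BIO_NAMES:
                    running[name] -= dropped[name].values
            window.append(bcy)
            for name in BIO_NAMES:
                running[name] += bcy[name].values
            if len(window) == bcl_window and year >= start_year - 1:
                layers = {
                    name: Layer(self.grid, running[name] / bcl_window,
                                np.zeros(self.grid.shape, bool), name, f"year {year}")
                    for name in BIO_NAMES
                }
                self._bcl[year] = BioclimSet(layers, year=year, label=f"BCL_{year}")
        logger.info("scenario layers ready: BCY %d-%d, %d BCL windows",
                    start_year, end_year, len(self._bcl))

    # -- provider protocol ---------------------------------------------
    def bcy(self, year: int) -> BioclimSet:
        return self._bcy[year]

    def bcl(self, end_year: int) -> BioclimSet:
        return self._bcl[end_year]

    def ach(self, year: int) -> Layer:
        return self._ach[year]

    @property
    def elevation(self) -> Layer:
        return self.static["elevation"]

    @property
    def slope(self) -> Layer:
        return self.static["slope"]

    @property
    def ph(self) -> Layer:
        return self.static["ph"]

    def agri(self, year: int) -> Layer:
        return self.static["agri"]
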