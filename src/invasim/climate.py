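"""Climate-derived layers: bias correction, BIOCLIM variables, chilling hours.

The pipeline mirrors standard practice in climate-driven distribution
modelling: daily maximum/minimum temperature and precipitation are
bias-corrected (linear scaling), aggregated to monthly summaries, and turned
into the 19 BIOCLIM variables per year (BCY).  Trailing multi-year means of
the yearly sets give the long-term layers (BCL) used for model training.
Accumulated chilling hours (ACH) — the dormancy-break driver — are counted
on an hourly series reconstructed from the daily extremes with a cosine
diurnal curve.

Calendar convention: proleptic Gregorian with leap years; day-of-year 32 is
February 1 in non-leap years.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np

from .landscape import GridSpec, Layer

#: month lengths for a non-leap year
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: hour of day at which the diurnal cosine attains the daily minimum
HOUR_OF_MINIMUM = 5

#: guard for the precipitation ratio in linear scaling (mm/day)
PRECIP_RATIO_EPS = 0.01


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def month_lengths(year: int) -> np.ndarray:
    md = _MONTH_DAYS.copy()
    if calendar.isleap(year):
        md[1] = 29
    return md


def month_of_day(year: int) -> np.ndarray:
    """0-based month index for each day-of-year (0-based) of ``year``."""
    return np.repeat(np.arange(12), month_lengths(year))


@dataclass
class DailyClimate:
    """Daily tmax/tmin (degC) and precipitation (mm/day) cubes, per year.

    Arrays are keyed by calendar year with shape ``(n_days, n_rows, n_cols)``.
    """

    grid: GridSpec
    tmax: dict[int, np.ndarray] = field(default_factory=dict)
    tmin: dict[int, np.ndarray] = field(default_factory=dict)
    prcp: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.tmax)

    def add_year(self, year: int, tmax, tmin, prcp) -> None:
        nd = days_in_year(year)
        for name, arr in (("tmax", tmax), ("tmin", tmin), ("prcp", prcp)):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (nd,) + self.grid.shape:
                raise ValueError(f"{name} for {year}: expected shape {(nd,) + self.grid.shape}, "
                                 f"got {arr.shape}")
        if np.any(np.asarray(tmin) > np.asarray(tmax)):
            raise ValueError(f"tmin exceeds tmax in year {year}")
        if np.any(np.asarray(prcp) < 0):
            raise ValueError(f"negative precipitation in year {year}")
        self.tmax[year] = np.asarray(tmax, dtype=float)
        self.tmin[year] = np.asarray(tmin, dtype=float)
        self.prcp[year] = np.asarray(prcp, dtype=float)


@dataclass
class MonthlyClimate:
    """Monthly mean tmax/tmin (degC) and total precipitation (mm), per year."""

    grid: GridSpec
    tmax_mean: dict[int, np.ndarray] = field(default_factory=dict)
    tmin_mean: dict[int, np.ndarray] = field(default_factory=dict)
    prcp_total: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.tmax_mean)


#: canonical BIOCLIM variable names
BIO_NAMES = tuple(f"BIO{i}" for i in range(1, 20))


@dataclass
class BioclimSet:
    """The 19 BIOCLIM layers for one year (BCY) or period mean (BCL)."""

    layers: dict[str, Layer]
    year: int | None = None
    label: str = ""

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid


def daily_to_monthly(daily: DailyClimate) -> MonthlyClimate:
    """Aggregate daily cubes to monthly means (temperature) and sums (precip)."""
    out = MonthlyClimate(daily.grid)
    for year in daily.years:
        nd = days_in_year(year)
        if daily.tmax[year].shape[0] != nd:
            raise ValueError(f"year {year} incomplete: expected {nd} days")
        md = month_lengths(year)
        edges = np.concatenate(([0], np.cumsum(md)[:-1]))
        tmax_sum = np.add.reduceat(daily.tmax[year], edges, axis=0)
        tmin_sum = np.add.reduceat(daily.tmin[year], edges, axis=0)
        prcp_sum = np.add.reduceat(daily.prcp[year], edges, axis=0)
        out.tmax_mean[year] = tmax_sum / md[:, None, None]
        out.tmin_mean[year] = tmin_sum / md[:, None, None]
        out.prcp_total[year] = prcp_sum
    return out


def linear_scaling(model_daily: DailyClimate, obs_daily: DailyClimate,
                   overlap_years) -> DailyClimate:
    """Monthly linear-scaling bias correction of a model series to observations.

    Temperatures are corrected additively by the per-cell, per-calendar-month
    difference of means over the overlap years; precipitation multiplicatively
    by the ratio of means (model monthly mean guarded at
    :data:`PRECIP_RATIO_EPS`).  Corrections are applied to every model year;
    corrected precipitation is clipped at zero and, where the independent
    temperature corrections cross, tmin is capped at tmax.
    """
    overlap = [int(y) for y in overlap_years]
    if not overlap:
        raise ValueError("empty overlap period")
    for y in overlap:
        if y not in model_daily.tmax or y not in obs_daily.tmax:
            raise ValueError(f"overlap year {y} missing from model or observations")

    shape = (12,) + model_daily.grid.shape

    def monthly_means(dc: DailyClimate, attr: str) -> np.ndarray:
        acc = np.zeros(shape)
        cnt = np.zeros(12)
        for y in overlap:
            md = month_lengths(y)
            edges = np.concatenate(([0], np.cumsum(md)[:-1]))
            acc += np.add.reduceat(getattr(dc, attr)[y], edges, axis=0) / md[:, None, None]
            cnt += 1
        return acc / cnt[:, None, None]

    d_tmax = monthly_means(obs_daily, "tmax") - monthly_means(model_daily, "tmax")
    d_tmin = monthly_means(obs_daily, "tmin") - monthly_means(model_daily, "tmin")
    m_p = np.maximum(monthly_means(model_daily, "prcp"), PRECIP_RATIO_EPS)
    r_p = monthly_means(obs_daily, "prcp") / m_p

    out = DailyClimate(model_daily.grid)
    for y in model_daily.years:
        mo = month_of_day(y)
        tmax = model_daily.tmax[y] + d_tmax[mo]
        tmin = model_daily.tmin[y] + d_tmin[mo]
        tmin = np.minimum(tmin, tmax)
        prcp = np.clip(model_daily.prcp[y] * r_p[mo], 0.0, None)
        out.add_year(y, tmax, tmin, prcp)
    return out


def _quarter_stack(monthly: np.ndarray) -> np.ndarray:
    """Sums over the 12 wrapped 3-month windows, indexed by start month."""
    ext = np.concatenate([monthly, monthly[:2]], axis=0)
    return np.lib.stride_tricks.sliding_window_view(ext, 3, axis=0).sum(axis=-1)


def biovars(monthly: MonthlyClimate, year: int) -> BioclimSet:
    """The 19 BIOCLIM variables for one year.

    Quarters are running three-consecutive-month windows wrapping across
    December-January; wettest/driest quarters are selected by precipitation
    sum and warmest/coldest by mean temperature, ties broken by the earliest
    start month.  BIO4 is 100 x the population standard deviation of monthly
    mean temperature; BIO15 is 100 x sd(monthly precip) / (1 + mean).
    """
    if year not in monthly.tmax_mean:
        raise ValueError(f"year {year} not present in monthly climate")
    tmax = monthly.tmax_mean[year]
    tmin = monthly.tmin_mean[year]
    prcp = monthly.prcp_total[year]
    if tmax.shape[0] != 12:
        raise ValueError("12 months are required")
    tmean = (tmax + tmin) / 2.0

    qt = _quarter_stack(tmean) / 3.0   # quarter mean temperature by start month
    qp = _quarter_stack(prcp)          # quarter precipitation sum

    wettest = qp.argmax(axis=0)
    driest = qp.argmin(axis=0)
    warmest = qt.argmax(axis=0)
    coldest = qt.argmin(axis=0)

    def pick(stack, idx):
        return np.take_along_axis(stack, idx[None], axis=0)[0]

    b: dict[str, np.ndarray] = {}
    b["BIO1"] = tmean.mean(axis=0)
    b["BIO2"] = (tmax - tmin).mean(axis=0)
    b["BIO4"] = 100.0 * tmean.std(axis=0)
    b["BIO5"] = tmax.max(axis=0)
    b["BIO6"] = tmin.min(axis=0)
    b["BIO7"] = b["BIO5"] - b["BIO6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        b["BIO3"] = np.where(b["BIO7"] > 0, 100.0 * b["BIO2"] / b["BIO7"], 0.0)
    b["BIO8"] = pick(qt, wettest)
    b["BIO9"] = pick(qt, driest)
    b["BIO10"] = pick(qt, warmest)
    b["BIO11"] = pick(qt, coldest)
    b["BIO12"] = prcp.sum(axis=0)
    b["BIO13"] = prcp.max(axis=0)
    b["BIO14"] = prcp.min(axis=0)
    b["BIO15"] = 100.0 * prcp.std(axis=0) / (1.0 + prcp.mean(axis=0))
    b["BIO16"] = pick(qp, wettest)
    b["BIO17"] = pick(qp, driest)
    b["BIO18"] = pick(qp, warmest)
    b["BIO19"] = pick(qp, coldest)

    layers = {
        name: Layer(monthly.grid, b[name], np.zeros(monthly.grid.shape, bool),
                    name, f"year {year}")
        for name in BIO_NAMES
    }
    return BioclimSet(layers, year=year, label=f"BCY_{year}")


def long_term_mean(bcy_sets: list[BioclimSet], window: int = 30) -> BioclimSet:
    """Cell-wise mean over the trailing ``window`` yearly sets (BCL).

    The result is labelled by the last year of the window, following the
    convention that e.g. ``BCL_2020`` is the mean of the 1991-2020 yearly
    layers.
    """
    if len(bcy_sets) < window:
        raise ValueError(f"need at least {window} yearly sets, got {len(bcy_sets)}")
    tail = sorted(bcy_sets, key=lambda s: s.year)[-window:]
    grid = tail[0].grid
    last = tail[-1].year
    layers = {}
    for name in BIO_NAMES:
        vals = np.mean([s[name].values for s in tail], axis=0)
        layers[name] = Layer(grid, vals, np.zeros(grid.shape, bool), name, f"year {last}")
    return BioclimSet(layers, year=last, label=f"BCL_{last}")


def daily_to_hourly(tmin, tmax) -> np.ndarray:
    """24 hourly temperatures from daily extremes via a cosine diurnal curve.

    ``T(h) = mid - amp * cos(2*pi*(h - h_min)/24)`` with the minimum at
    ``h_min = 5`` (early morning) and the maximum twelve hours later, so the
    daily extremes are reproduced exactly.  Inputs broadcast; the hour axis
    is appended last.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    hours = np.arange(24)
    curve = np.cos(2.0 * np.pi * (hours - HOUR_OF_MINIMUM) / 24.0)
    return mid[..., None] - amp[..., None] * curve


def accumulated_chilling_hours(daily: DailyClimate, year: int,
                               doy_start: int = 32, doy_end: int = 90,
                               base: float = 5.0, floor: float = 0.0) -> Layer:
    """Count hourly temperatures in the chilling band over a day-of-year window.

    An hour chills when ``floor < T <= base`` (default band (0, 5] degC: hours
    at or below freezing do not count).  The window is inclusive, 1-based
    day-of-year; the default 32-90 covers February-March.
    """
    if year not in daily.tmax:
        raise ValueError(f"year {year} not present in daily climate")
    nd = days_in_year(year)
    if not (1 <= doy_start <= doy_end <= nd):
        raise ValueError(f"day window [{doy_start}, {doy_end}] outside year of {nd} days")
    sl = slice(doy_start - 1, doy_end)
    tmin = daily.tmin[year][sl]
    tmax = daily.tmax[year][sl]
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    # accumulate hour by hour rather than materializing the hourly cube
    counts = np.zeros(daily.grid.shape)
    for h in range(24):
        t = mid - amp * np.cos(2.0 * np.pi * (h - HOUR_OF_MINIMUM) / 24.0)
        counts += ((t > floor) & (t <= base)).sum(axis=0)
    return Layer(daily.grid, counts, np.zeros(daily.grid.shape, bool),
                 f"ACH_{year}", f"year {year}")
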