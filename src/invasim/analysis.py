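"""Ensemble post-processing: agreement maps, band statistics, shifts, foci.

The unit of analysis is the *invaded cell*: a base-grid cell holding at
least one productive agent.  An ensemble of simulations yields agreement
maps (the fraction of simulations invading each cell in a year or 5-year
period); downstream statistics are computed on the moderate-agreement cells
(strictly above 50% by default): invaded-cell counts per longitudinal or
latitudinal band (ICC) and their inter-period increments (IPI), range
centroids and north/south boundary latitudes, and connected invasion foci.
A one-factor-at-a-time (OFAT) driver reruns small ensembles over a value
grid for a single agent parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .abm import ABMConfig
from .landscape import GridSpec, Layer
from .simulation import EnsembleResult, SimulationConfig, run_ensemble


def _period_years(period, years: list[int]) -> list[int]:
    if isinstance(period, (int, np.integer)):
        sel = [int(period)]
    else:
        lo, hi = period
        sel = [y for y in years if lo <= y <= hi]
    missing = [y for y in sel if y not in years] if isinstance(period, (int, np.integer)) else []
    if not sel or missing:
        raise ValueError(f"period {period!r} outside the simulated years {years[0]}-{years[-1]}")
    return sel


def period_cells(record, period, years: list[int]) -> np.ndarray:
    """Cells invaded in ANY year of the period, for one simulation."""
    sel = _period_years(period, years)
    parts = [record.invaded.get(y, np.empty(0, np.int64)) for y in sel]
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.int64)


def agreement(ensemble: EnsembleResult, period) -> Layer:
    """Fraction of simulations invading each cell during the period.

    ``period`` is a single year or an inclusive ``(start, end)`` window; a
    cell counts for a simulation if it holds a productive agent in at least
    one year of the period.
    """
    if ensemble.n_simulations == 0:
        raise ValueError("empty ensemble")
    grid = ensemble.grid
    counts = np.zeros(grid.n_rows * grid.n_cols)
    for rec in ensemble.records:
        counts[period_cells(rec, period, ensemble.years)] += 1
    frac = (counts / ensemble.n_simulations).reshape(grid.shape)
    return Layer(grid, frac, np.zeros(grid.shape, bool), "agreement", "emergent")


def moderate_cells(agreement_map: Layer, cut: float = 0.5) -> np.ndarray:
    """Flat indices of cells whose agreement is strictly above ``cut``."""
    vals = np.where(agreement_map.mask, 0.0, agreement_map.values)
    return np.flatnonzero(vals.ravel() > cut)


@dataclass(frozen=True)
class Band:
    axis: str          # "longitudinal" or "latitudinal"
    lower: float       # degrees, inclusive
    upper: float       # degrees, exclusive

    @property
    def label(self) -> str:
        return f"{self.lower:g}..{self.upper:g}"


def make_bands(axis: str, start: float, stop: float, width: float) -> list[Band]:
    """Half-open bands [lower, upper) tiling [start, stop)."""
    edges = np.arange(start, stop + 1e-9, width)
    return [Band(axis, float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])]


def _band_members(cells: np.ndarray, grid: GridSpec, band: Band) -> np.ndarray:
    r, c = np.divmod(cells, grid.n_cols)
    lon, lat = grid.center_of(r, c)
    coord = lon if band.axis == "longitudinal" else lat
    return cells[(coord >= band.lower) & (coord < band.upper)]


def icc_ipi(cell_sets: dict, grid: GridSpec, bands: list[Band]) -> pd.DataFrame:
    """Invaded-cell counts and inter-period increments per band.

    ``cell_sets`` maps ordered period labels to flat-index arrays.  The first
    period's ICC is the initially invaded count; IPI is defined from the
    second period on (``NaN`` before that).
    """
    if len(cell_sets) < 2:
        raise ValueError("at least two periods are required")
    rows = []
    for band in bands:
        prev = None
        for label, cells in cell_sets.items():
            icc = int(_band_members(np.asarray(cells, np.int64), grid, band).size)
            rows.append({
                "axis": band.axis, "band": band.label, "period": label,
                "icc": icc, "ipi": (np.nan if prev is None else icc - prev),
            })
            prev = icc
    return pd.DataFrame(rows)


def _centroid(cells: np.ndarray, grid: GridSpec) -> tuple[float, float]:
    r, c = np.divmod(cells, grid.n_cols)
    lon, lat = grid.center_of(r, c)
    return float(lat.mean()), float(lon.mean())


def centroid_and_boundaries(initial: np.ndarray, final: np.ndarray, grid: GridSpec,
                            scopes: dict[str, tuple[float, float]] | None = None,
                            band_width: float = 10.0) -> pd.DataFrame:
    """Range-shift summary between an initial and a final period.

    For the entire range, each configured longitude scope, and each
    ``band_width``-degree longitudinal band: the unweighted invaded-cell
    centroid and the northern/southern extreme latitudes, initial and final,
    with deltas (final - initial; positive = northward).  Scopes or bands
    empty in either period are reported with NaN deltas rather than raised.
    """
    initial = np.asarray(initial, np.int64)
    final = np.asarray(final, np.int64)
    if initial.size == 0 or final.size == 0:
        raise ValueError("both periods must contain invaded cells")

    lon_all = grid.lon_centers()
    lon_lo = np.floor(lon_all.min() / band_width) * band_width
    lon_hi = np.ceil(lon_all.max() / band_width) * band_width
    entries: list[tuple[str, Band | None]] = [("entire", None)]
    for name, (lo, hi) in (scopes or {}).items():
        entries.append((name, Band("longitudinal", lo, hi)))
    for band in make_bands("longitudinal", lon_lo, lon_hi, band_width):
        entries.append((f"band {band.label}", band))

    rows = []
    for name, band in entries:
        ini = initial if band is None else _band_members(initial, grid, band)
        fin = final if band is None else _band_members(final, grid, band)
        row: dict = {"scope": name, "n_initial": ini.size, "n_final": fin.size}
        if ini.size and fin.size:
            lat_i, lon_i = _centroid(ini, grid)
            lat_f, lon_f = _centroid(fin, grid)
            ri, _ = np.divmod(ini, grid.n_cols)
            rf, _ = np.divmod(fin, grid.n_cols)
            _, lat_ci = grid.center_of(ri, np.zeros_like(ri))
            _, lat_cf = grid.center_of(rf, np.zeros_like(rf))
            row.update(
                centroid_lat_initial=lat_i, centroid_lon_initial=lon_i,
                centroid_lat_final=lat_f, centroid_lon_final=lon_f,
                centroid_lat_shift=lat_f - lat_i,
                north_initial=float(lat_ci.max()), north_final=float(lat_cf.max()),
                north_shift=float(lat_cf.max() - lat_ci.max()),
                south_initial=float(lat_ci.min()), south_final=float(lat_cf.min()),
                south_shift=float(lat_cf.min() - lat_ci.min()),
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Focus:
    cells: np.ndarray       # flat indices
    size: int
    bbox: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max


def detect_foci(cells: np.ndarray, grid: GridSpec) -> list[Focus]:
    """Connected components of invaded cells under queen (8-neighbour) adjacency."""
    binary = np.zeros(grid.shape, bool)
    cells = np.asarray(cells, np.int64)
    r, c = np.divmod(cells, grid.n_cols)
    binary[r, c] = True
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), int))
    foci = []
    for k in range(1, n + 1):
        rr, cc = np.where(labels == k)
        lon, lat = grid.center_of(rr, cc)
        foci.append(Focus(
            cells=grid.flat_index(rr, cc),
            size=rr.size,
            bbox=(float(lon.min()), float(lon.max()), float(lat.min()), float(lat.max())),
        ))
    return sorted(foci, key=lambda f: -f.size)


def five_year_periods(years: list[int]) -> dict[str, tuple[int, int]]:
    """Consecutive 5-year windows covering the simulated years."""
    periods = {}
    for start in range(years[0], years[-1] + 1, 5):
        end = min(start + 4, years[-1])
        periods[f"{start}-{end}"] = (start, end)
    return periods


def ofat(occurrences, provider, base_config: SimulationConfig, parameter: str,
         values, n_sims: int = 10) -> pd.DataFrame:
    """One-factor-at-a-time sensitivity of the final-period invaded count.

    For each value the named ABM parameter is set with all others at nominal
    and a fresh ensemble of ``n_sims`` simulations is run; the response is
    the per-simulation invaded-cell count in the final 5-year period.
    Returns a long-format table (parameter, value, sim, final_icc).
    """
    if not hasattr(base_config.abm, parameter):
        valid = sorted(ABMConfig.__dataclass_fields__)
        raise ValueError(f"unknown ABM parameter {parameter!r}; valid names: {valid}")
    rows = []
    years = list(base_config.years)
    final_period = (max(years[0], years[-1] - 4), years[-1])
    for value in values:
        cfg = replace(base_config,
                      abm=replace(base_config.abm, **{parameter: value}),
                      n_simulations=n_sims)
        ens = run_ensemble(occurrences, provider, cfg)
        for rec in ens.records:
            cells = period_cells(rec, final_period, ens.years)
            rows.append({"parameter": parameter, "value": value,
                         "sim": rec.sim_index, "final_icc": int(cells.size)})
    return pd.DataFrame(rows)


def ofat_summary(table: pd.DataFrame) -> pd.DataFrame:
    return (table.groupby(["parameter", "value"])["final_icc"]
            .agg(["mean", "std", "median"]).reset_index())
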