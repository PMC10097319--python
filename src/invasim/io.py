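"""Reading and writing layers and occurrence tables.

Rasters travel as CF-style NetCDF (via xarray, scipy backend) with one or
more variables on ``(lat, lon)`` coordinates at cell centres; grid geometry
is reconstructed from the coordinate vectors.  Occurrence points travel as
CSV (columns ``lon, lat, year[, basis]``) or GeoJSON point collections.
Masked cells are stored as NaN.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .landscape import GridSpec, Layer, OccurrenceSet


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    if lat.size < 2 or lon.size < 2:
        raise ValueError("need at least 2 coordinates per axis to infer the grid")
    res_lat = float(np.diff(lat).mean())
    res_lon = float(np.diff(lon).mean())
    if res_lat <= 0:
        raise ValueError("latitude coordinates must increase")
    if abs(res_lat - res_lon) > 1e-9:
        raise ValueError(f"anisotropic grid (dlat={res_lat}, dlon={res_lon}) not supported")
    return GridSpec(res_lat, float(lon[0] - res_lon / 2), float(lat[0] - res_lat / 2),
                    lat.size, lon.size)


def write_layers(path, layers: list[Layer] | Layer) -> None:
    """Write one or more layers (one grid) to a NetCDF file."""
    if isinstance(layers, Layer):
        layers = [layers]
    g = layers[0].grid
    data = {}
    for i, lyr in enumerate(layers):
        if lyr.grid != g:
            raise ValueError("all layers must share one grid")
        name = lyr.name or f"layer_{i}"
        vals = np.where(lyr.mask, np.nan, lyr.values)
        data[name] = xr.DataArray(vals, dims=("lat", "lon"),
                                  attrs={"temporal_tag": lyr.temporal_tag})
    ds = xr.Dataset(
        data,
        coords={"lat": g.lat_centers(), "lon": g.lon_centers()},
        attrs={"resolution": g.resolution,
               "lon_origin": g.lon_origin, "lat_origin": g.lat_origin},
    )
    ds.to_netcdf(Path(path), engine="scipy")


def read_layers(path) -> dict[str, Layer]:
    """Read every variable of a NetCDF file as a Layer."""
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        ds = ds.load()
    for coord in ("lat", "lon"):
        if coord not in ds.coords:
            raise ValueError(f"NetCDF file lacks coordinate {coord!r}")
    grid = _grid_from_coords(ds["lat"].values.astype(float), ds["lon"].values.astype(float))
    out = {}
    for name, da in ds.data_vars.items():
        if da.dims != ("lat", "lon"):
            raise ValueError(f"variable {name!r} has dims {da.dims}, expected ('lat', 'lon')")
        vals = da.values.astype(float)
        out[str(name)] = Layer(grid, vals, ~np.isfinite(vals), str(name),
                               str(da.attrs.get("temporal_tag", "static")))
    return out


def read_layer(path, name: str | None = None) -> Layer:
    layers = read_layers(path)
    if name is None:
        if len(layers) != 1:
            raise ValueError(f"file holds {sorted(layers)}; specify a variable name")
        return next(iter(layers.values()))
    if name not in layers:
        raise ValueError(f"variable {name!r} not in file (has {sorted(layers)})")
    return layers[name]


def write_daily_climate(path, daily) -> None:
    """Write a multi-year daily climate cube (tmax/tmin/prcp) to NetCDF."""
    g = daily.grid
    years = daily.years
    if not years:
        raise ValueError("daily climate holds no years")
    time = np.concatenate([
        np.datetime64(f"{y}-01-01") + np.arange(daily.tmax[y].shape[0])
        for y in years
    ])
    data = {}
    for name in ("tmax", "tmin", "prcp"):
        cube = np.concatenate([getattr(daily, name)[y] for y in years], axis=0)
        data[name] = xr.DataArray(cube, dims=("time", "lat", "lon"))
    ds = xr.Dataset(data, coords={"time": time, "lat": g.lat_centers(),
                                  "lon": g.lon_centers()},
                    attrs={"resolution": g.resolution})
    ds.to_netcdf(Path(path), engine="scipy")


def read_daily_climate(path):
    """Read a NetCDF daily cube written by :func:`write_daily_climate`."""
    from .climate import DailyClimate, days_in_year

    with xr.open_dataset(Path(path), engine="scipy") as ds:
        ds = ds.load()
    for v in ("tmax", "tmin", "prcp"):
        if v not in ds.data_vars:
            raise ValueError(f"daily climate file lacks variable {v!r}")
    grid = _grid_from_coords(ds["lat"].values.astype(float), ds["lon"].values.astype(float))
    out = DailyClimate(grid)
    years = np.unique(ds["time"].dt.year.values)
    for y in years:
        sel = ds.sel(time=ds["time"].dt.year == y)
        if sel.sizes["time"] != days_in_year(int(y)):
            raise ValueError(f"year {y}: {sel.sizes['time']} days present, "
                             f"expected {days_in_year(int(y))}")
        out.add_year(int(y), sel["tmax"].values, sel["tmin"].values, sel["prcp"].values)
    return out


def write_monthly_climate(path, monthly) -> None:
    """Write a multi-year monthly climate cube to NetCDF."""
    g = monthly.grid
    years = monthly.years
    if not years:
        raise ValueError("monthly climate holds no years")
    data = {}
    for src, name in (("tmax_mean", "tmax_mean"), ("tmin_mean", "tmin_mean"),
                      ("prcp_total", "prcp_total")):
        cube = np.stack([getattr(monthly, src)[y] for y in years], axis=0)
        data[name] = xr.DataArray(cube, dims=("year", "month", "lat", "lon"))
    ds = xr.Dataset(data, coords={"year": np.asarray(years), "month": np.arange(1, 13),
                                  "lat": g.lat_centers(), "lon": g.lon_centers()},
                    attrs={"resolution": g.resolution})
    ds.to_netcdf(Path(path), engine="scipy")


def read_monthly_climate(path):
    """Read a NetCDF monthly cube written by :func:`write_monthly_climate`."""
    from .climate import MonthlyClimate

    with xr.open_dataset(Path(path), engine="scipy") as ds:
        ds = ds.load()
    for v in ("tmax_mean", "tmin_mean", "prcp_total"):
        if v not in ds.data_vars:
            raise ValueError(f"monthly climate file lacks variable {v!r}")
    grid = _grid_from_coords(ds["lat"].values.astype(float), ds["lon"].values.astype(float))
    out = MonthlyClimate(grid)
    for i, y in enumerate(ds["year"].values):
        out.tmax_mean[int(y)] = ds["tmax_mean"].values[i]
        out.tmin_mean[int(y)] = ds["tmin_mean"].values[i]
        out.prcp_total[int(y)] = ds["prcp_total"].values[i]
    return out


def write_occurrences_csv(path, occ: OccurrenceSet) -> None:
    occ.df.to_csv(Path(path), index=False)


def read_occurrences_csv(path, basis_value: str | None = None) -> OccurrenceSet:
    """Read and clean an occurrence CSV (drops duplicates and no-coordinate rows)."""
    df = pd.read_csv(Path(path))
    missing = {"lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV lacks columns: {sorted(missing)}")
    return OccurrenceSet(df).clean(basis_value=basis_value)


def write_occurrences_geojson(path, occ: OccurrenceSet) -> None:
    features = []
    for _, row in occ.df.iterrows():
        props = {"year": None if pd.isna(row.get("year")) else int(row["year"])}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(row["lon"]), float(row["lat"])]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def save_ensemble(outdir, ensemble) -> None:
    """Persist an ensemble: per-simulation invaded-cell CSVs plus metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = ensemble.grid
    meta = {
        "grid": {"resolution": g.resolution, "lon_origin": g.lon_origin,
                 "lat_origin": g.lat_origin, "n_rows": g.n_rows, "n_cols": g.n_cols},
        "years": [int(y) for y in ensemble.years],
        "n_simulations": ensemble.n_simulations,
        "failures": ensemble.failures,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    for rec in ensemble.records:
        rows = [(y, int(cell)) for y in ensemble.years
                for cell in rec.invaded.get(y, [])]
        pd.DataFrame(rows, columns=["year", "cell"]).to_csv(
            outdir / f"invaded_sim{rec.sim_index:03d}.csv", index=False)
        rec.counts_frame().to_csv(outdir / f"log_sim{rec.sim_index:03d}.csv", index=False)
        for year, frame in rec.snapshots.items():
            frame.to_csv(outdir / f"agents_sim{rec.sim_index:03d}_{year}.csv", index=False)


def load_ensemble(outdir):
    """Rebuild an :class:`~invasim.simulation.EnsembleResult` saved by
    :func:`save_ensemble` (invaded cells and step logs; no agent snapshots)."""
    from .simulation import EnsembleResult, SimulationRecord

    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    grid = GridSpec(**meta["grid"])
    years = meta["years"]
    records = []
    for f in sorted(outdir.glob("invaded_sim*.csv")):
        idx = int(f.stem.replace("invaded_sim", ""))
        df = pd.read_csv(f)
        rec = SimulationRecord(sim_index=idx, grid=grid)
        for y in years:
            rec.invaded[y] = np.sort(df.loc[df["year"] == y, "cell"].to_numpy(np.int64))
        logf = outdir / f"log_sim{idx:03d}.csv"
        if logf.exists():
            rec.counts = pd.read_csv(logf).to_dict("records")
            rec.auc = {int(r["year"]): r.get("auc", float("nan")) for r in rec.counts}
        records.append(rec)
    return EnsembleResult(grid, years, records,
                          [tuple(f) for f in meta.get("failures", [])])


def read_occurrences_geojson(path) -> OccurrenceSet:
    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise ValueError("GeoJSON root must be a FeatureCollection")
    rows = []
    for i, feat in enumerate(obj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"feature {i}: geometry must be a Point")
        coords = geom.get("coordinates", [])
        if len(coords) < 2:
            raise ValueError(f"feature {i}: Point lacks coordinates")
        rows.append({"lon": coords[0], "lat": coords[1],
                     "year": (feat.get("properties") or {}).get("year")})
    df = pd.DataFrame(rows, columns=["lon", "lat", "year"])
    return OccurrenceSet(df).clean()
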