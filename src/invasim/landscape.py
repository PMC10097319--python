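"""Spatial substrate: grids, extents, layers, occurrence tables and terrain.

Everything downstream (climate derivation, suitability modelling, the
agent-based loop) operates on the types defined here.  Conventions:

* Coordinates are geographic WGS84 degrees.
* A grid is anchored at the *edge* of its lower-left (south-west) cell;
  cell ``(r, c)`` covers the half-open box
  ``[lon_origin + c*res, lon_origin + (c+1)*res) x
  [lat_origin + r*res, lat_origin + (r+1)*res)``.
  Row index increases northward.
* Layer masks follow the numpy masked-array convention: ``True`` = missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metres per degree of latitude (equirectangular approximation).
M_PER_DEG = 111_320.0
#: kilometres per degree of latitude, used for dispersal conversions.
KM_PER_DEG = 111.32


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid, lower-left anchored, half-open cells."""

    resolution: float
    lon_origin: float
    lat_origin: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.lon_origin + self.n_cols * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_origin + self.n_rows * self.resolution

    @property
    def extent(self) -> "Extent":
        return Extent(self.lon_origin, self.lon_max, self.lat_origin, self.lat_max)

    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        return self.lat_origin + (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) arrays; out-of-grid points get -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        c = np.floor((lon - self.lon_origin) / self.resolution).astype(np.int64)
        r = np.floor((lat - self.lat_origin) / self.resolution).astype(np.int64)
        bad = (r < 0) | (r >= self.n_rows) | (c < 0) | (c >= self.n_cols)
        r = np.where(bad, -1, r)
        c = np.where(bad, -1, c)
        return r, c

    def center_of(self, row, col):
        """Centre coordinates (lon, lat) of cell (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_origin + (col + 0.5) * self.resolution
        lat = self.lat_origin + (row + 0.5) * self.resolution
        return lon, lat

    def flat_index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)


@dataclass(frozen=True)
class Extent:
    """Geographic bounding box in degrees."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("extent must have positive width and height")

    def contains(self, lon, lat):
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def union(self, other: "Extent") -> "Extent":
        return Extent(
            min(self.lon_min, other.lon_min),
            max(self.lon_max, other.lon_max),
            min(self.lat_min, other.lat_min),
            max(self.lat_max, other.lat_max),
        )


@dataclass
class Layer:
    """2-D gridded field with missing-value mask.

    ``temporal_tag`` distinguishes static layers (elevation, pH), yearly
    layers (climate, land use; tag ``"year <Y>"``) and emergent layers
    produced inside the simulation loop (bioclimatic suitability).
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    name: str = ""
    temporal_tag: str = "static"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values/mask shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    def copy(self) -> "Layer":
        return Layer(self.grid, self.values.copy(), self.mask.copy(), self.name, self.temporal_tag)

    def sample(self, lon, lat):
        """Nearest-cell lookup at point locations.

        Returns ``(values, valid)`` where ``valid`` is False for points
        falling outside the grid or on masked cells.
        """
        r, c = self.grid.cell_of(lon, lat)
        inside = r >= 0
        vals = np.full(np.shape(r), np.nan, dtype=float)
        rr = np.where(inside, r, 0)
        cc = np.where(inside, c, 0)
        vals = np.where(inside & ~self.mask[rr, cc], self.values[rr, cc], np.nan)
        valid = inside & ~self.mask[rr, cc]
        return vals, valid


@dataclass
class OccurrenceSet:
    """Point occurrence records (lon, lat, year), pandas-backed."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["lon", "lat", "year"]))

    def __post_init__(self) -> None:
        missing = {"lon", "lat"} - set(self.df.columns)
        if missing:
            raise ValueError(f"occurrence table lacks columns: {sorted(missing)}")
        if "year" not in self.df.columns:
            self.df = self.df.assign(year=pd.NA)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lon(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)

    @classmethod
    def from_points(cls, lon, lat, year=None) -> "OccurrenceSet":
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if year is None:
            year = np.full(lon.shape, pd.NA)
        return cls(pd.DataFrame({"lon": lon, "lat": lat, "year": year}))

    def clean(self, basis_value: str | None = None) -> "OccurrenceSet":
        """Drop records lacking coordinates and exact duplicates.

        If ``basis_value`` is given and a ``basis`` column exists, only rows
        whose basis equals the value are kept (basis-of-record filtering).
        """
        df = self.df.copy()
        if basis_value is not None and "basis" in df.columns:
            df = df[df["basis"] == basis_value]
        df = df.dropna(subset=["lon", "lat"])
        df = df[np.isfinite(df["lon"].astype(float)) & np.isfinite(df["lat"].astype(float))]
        subset = [c for c in ("lon", "lat", "year") if c in df.columns]
        df = df.drop_duplicates(subset=subset).reset_index(drop=True)
        return OccurrenceSet(df)


def make_extent(points, margin: float = 2.0) -> Extent:
    """Minimum bounding rectangle of points, floor/ceil-rounded, plus margin.

    ``points`` may be an :class:`OccurrenceSet` or a pair of coordinate
    arrays ``(lon, lat)``.
    """
    if isinstance(points, OccurrenceSet):
        lon, lat = points.lon, points.lat
    else:
        lon, lat = (np.asarray(p, dtype=float) for p in points)
    if lon.size == 0:
        raise ValueError("cannot build an extent from an empty point set: no propagule source")
    return Extent(
        math.floor(lon.min()) - margin,
        math.ceil(lon.max()) + margin,
        math.floor(lat.min()) - margin,
        math.ceil(lat.max()) + margin,
    )


def crop(layer: Layer, extent: Extent) -> Layer:
    """Restrict a layer to the cells whose centres fall inside ``extent``."""
    g = layer.grid
    lon_c = g.lon_centers()
    lat_c = g.lat_centers()
    cols = np.where((lon_c >= extent.lon_min) & (lon_c <= extent.lon_max))[0]
    rows = np.where((lat_c >= extent.lat_min) & (lat_c <= extent.lat_max))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("extent does not overlap the layer grid")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = GridSpec(
        g.resolution,
        g.lon_origin + c0 * g.resolution,
        g.lat_origin + r0 * g.resolution,
        r1 - r0,
        c1 - c0,
    )
    return Layer(sub, layer.values[r0:r1, c0:c1].copy(), layer.mask[r0:r1, c0:c1].copy(),
                 layer.name, layer.temporal_tag)


def _fill_nearest(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked cells by their nearest valid neighbour's value."""
    if not mask.any():
        return values
    from scipy import ndimage

    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def slope_from_elevation(elev: Layer) -> Layer:
    """Terrain slope (degrees from horizontal) by Horn's 8-neighbour method.

    Cell dimensions are metres per degree, with the east-west spacing scaled
    by cos(latitude).  Border cells are handled by edge padding and masked
    input cells by nearest-valid-neighbour filling; the output mask equals
    the input mask.
    """
    g = elev.grid
    if elev.mask.all():
        return Layer(g, np.full(g.shape, np.nan), np.ones(g.shape, bool), "slope", "static")
    z = _fill_nearest(elev.values, elev.mask)
    zp = np.pad(z, 1, mode="edge")

    a = zp[2:, :-2]; b = zp[2:, 1:-1]; c = zp[2:, 2:]       # northern neighbours
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]                     # west / east
    gg = zp[:-2, :-2]; h = zp[:-2, 1:-1] ; i = zp[:-2, 2:]  # southern neighbours

    lat = g.lat_centers()[:, None]
    dx = 8.0 * g.resolution * M_PER_DEG * np.cos(np.radians(lat))
    dy = 8.0 * g.resolution * M_PER_DEG
    dzdx = ((c + 2 * f + i) - (a + 2 * d + gg)) / dx
    dzdy = ((a + 2 * b + c) - (gg + 2 * h + i)) / dy
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope = np.where(elev.mask, np.nan, slope)
    return Layer(g, slope, elev.mask.copy(), "slope", "static")


def composite_agricultural_fraction(class_layers: list[Layer]) -> Layer:
    """Sum per-class agricultural fraction layers, clipped to [0, 1].

    A cell masked in any class layer is masked in the composite.
    """
    if len(class_layers) == 0:
        raise ValueError("no class layers given")
    g = class_layers[0].grid
    for lyr in class_layers[1:]:
        if lyr.grid != g:
            raise ValueError("class layers are not on a common grid")
    total = np.zeros(g.shape)
    mask = np.zeros(g.shape, bool)
    for lyr in class_layers:
        total += np.where(lyr.mask, 0.0, lyr.values)
        mask |= lyr.mask
    total = np.clip(total, 0.0, 1.0)
    total[mask] = np.nan
    tag = class_layers[0].temporal_tag
    return Layer(g, total, mask, "agricultural_fraction", tag)


def constant_layer(grid: GridSpec, value: float, name: str = "", tag: str = "static") -> Layer:
    """Convenience: an unmasked layer with a single value everywhere."""
    return Layer(grid, np.full(grid.shape, float(value)), np.zeros(grid.shape, bool), name, tag)
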