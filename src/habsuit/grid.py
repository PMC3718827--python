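"""Grid and vector data model plus the geometry primitives shared by all stages.

Conventions
-----------
* Grids are regular lon/lat rasters. ``values[0, :]`` is the northernmost row.
* ``origin_lon`` is the western cell edge of column 0 and ``origin_lat`` the
  northern cell edge of row 0 (cell-edge origin).
* A point is assigned to a cell by flooring:
  ``col = floor((lon - origin_lon) / cell_size)`` and
  ``row = floor((origin_lat - lat) / cell_size)``, i.e. cells are half-open.
* The Earth is a sphere of radius 6371.0 km for all distances and areas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of a great circle, 2*pi*R/360 (~111.1949)
KM_PER_DEGREE = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0


class GridError(ValueError):
    """Raised for malformed or geometrically inconsistent grid data."""


@dataclass
class GridLayer:
    """One environmental variable on a regular lon/lat grid.

    Parameters
    ----------
    name
        Variable identifier, e.g. ``"temperature"``.
    values
        2-D array, row 0 = northernmost row.
    nodata_mask
        Boolean array of the same shape; True marks missing cells.
    origin_lon, origin_lat
        Western / northern cell edges in decimal degrees.
    cell_size
        Cell size in degrees (square cells).
    units
        Free-text unit label.
    """

    name: str
    values: np.ndarray
    nodata_mask: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float = 0.005
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.ndim != 2:
            raise GridError(f"layer {self.name!r}: values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise GridError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= nodata_mask shape {self.nodata_mask.shape}"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def geometry(self) -> tuple[float, float, float, tuple[int, int]]:
        return (self.origin_lon, self.origin_lat, self.cell_size, self.shape)

    def same_geometry(self, other: "GridLayer", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def lon_centres(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.ncols) + 0.5) * self.cell_size

    def lat_centres(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing the given points.

        Flooring convention; indices may fall outside the grid — callers
        check bounds with :meth:`in_bounds`.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def copy(self, **changes) -> "GridLayer":
        base = dict(
            name=self.name,
            values=self.values.copy(),
            nodata_mask=self.nodata_mask.copy(),
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            units=self.units,
        )
        if isinstance(self, CategoricalGridLayer):
            base["legend"] = dict(self.legend)
        base.update(changes)
        return type(self)(**base)


@dataclass
class CategoricalGridLayer(GridLayer):
    """Grid layer whose values are non-negative integer class codes."""

    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            vals = np.asarray(self.values, dtype=float)
            if np.any(vals[~self.nodata_mask] != np.round(vals[~self.nodata_mask])):
                raise GridError(f"layer {self.name!r}: categorical values must be integers")
            self.values = vals.astype(int)
        codes = np.unique(self.values[~self.nodata_mask])
        if codes.size and codes.min() < 0:
            raise GridError(f"layer {self.name!r}: class codes must be non-negative")
        missing = [int(c) for c in codes if int(c) not in self.legend]
        if missing:
            raise GridError(f"layer {self.name!r}: codes {missing} absent from legend")


class LayerStack:
    """Named collection of layers on identical geometry plus a land mask.

    ``land_mask`` is boolean with True = land/excluded. Construction fails if
    any member layer disagrees on origin, cell size or shape.
    """

    def __init__(self, layers: dict[str, GridLayer], land_mask: np.ndarray | None = None):
        if not layers:
            raise GridError("LayerStack needs at least one layer")
        self.layers = dict(layers)
        ref = next(iter(self.layers.values()))
        for name, lyr in self.layers.items():
            if not ref.same_geometry(lyr):
                raise GridError(
                    f"layer {name!r} geometry {lyr.geometry} does not match "
                    f"{ref.name!r} geometry {ref.geometry}"
                )
        if land_mask is None:
            land_mask = np.zeros(ref.shape, dtype=bool)
        land_mask = np.asarray(land_mask, dtype=bool)
        if land_mask.shape != ref.shape:
            raise GridError(f"land_mask shape {land_mask.shape} != layer shape {ref.shape}")
        self.land_mask = land_mask

    # -- mapping-ish access ----------------------------------------------
    def __getitem__(self, name: str) -> GridLayer:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"stack has no layer {name!r}; available: {sorted(self.layers)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self):
        return iter(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> GridLayer:
        return next(iter(self.layers.values()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape

    def valid_mask(self) -> np.ndarray:
        """Sea cells that carry data in every layer."""
        ok = ~self.land_mask
        for lyr in self.layers.values():
            ok &= ~lyr.nodata_mask
        return ok

    def continuous_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if not isinstance(l, CategoricalGridLayer)]

    def categorical_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if isinstance(l, CategoricalGridLayer)]

    def replace_layer(self, layer: GridLayer) -> "LayerStack":
        layers = dict(self.layers)
        layers[layer.name] = layer
        return LayerStack(layers, self.land_mask.copy())


@dataclass
class OccurrenceSet:
    """Presence-only occurrence records (decimal-degree WGS84 lon/lat)."""

    lons: np.ndarray
    lats: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if not (self.lons.shape == self.lats.shape == (len(self.ids),)):
            raise GridError("lons, lats and ids must have equal length")
        if np.any((self.lons < -180) | (self.lons > 180)):
            raise GridError("longitude out of [-180, 180]")
        if np.any((self.lats < -90) | (self.lats > 90)):
            raise GridError("latitude out of [-90, 90]")
        if len(set(self.ids)) != len(self.ids):
            raise GridError("occurrence ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "OccurrenceSet":
        idx = np.asarray(idx)
        return OccurrenceSet(self.lons[idx], self.lats[idx], [self.ids[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lon": self.lons, "lat": self.lats, "id": self.ids})


@dataclass
class RegionSet:
    """Named, simple (non-self-intersecting) lon/lat polygons."""

    regions: dict[str, Polygon]

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise GridError("RegionSet needs at least one region")
        for name, poly in self.regions.items():
            if not poly.is_valid:
                raise GridError(f"region {name!r} polygon is not simple/valid")

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def cell_area_km2(layer: GridLayer) -> GridLayer:
    """Per-cell area grid: (cell_size * KM_PER_DEGREE)^2 * cos(centre latitude).

    Constant along rows; the nodata mask of the input is preserved.
    """
    lat_c = np.radians(layer.lat_centres())
    row_area = (layer.cell_size * KM_PER_DEGREE) ** 2 * np.cos(lat_c)
    values = np.broadcast_to(row_area[:, None], layer.shape).copy()
    return GridLayer(
        name="cell_area",
        values=values,
        nodata_mask=layer.nodata_mask.copy(),
        origin_lon=layer.origin_lon,
        origin_lat=layer.origin_lat,
        cell_size=layer.cell_size,
        units="km2",
    )


def slope_percent(bathy: GridLayer) -> GridLayer:
    """Percent slope from a 3x3 Horn kernel on a bathymetry grid in metres.

    Cell spacing is converted to metres with the spherical convention used by
    :func:`cell_area_km2` (east-west spacing scaled by cos latitude). Cells
    with any nodata neighbour, including the grid border, are nodata.
    """
    if bathy.nrows < 3 or bathy.ncols < 3:
        raise GridError(f"slope needs a grid of at least 3x3, got {bathy.shape}")
    z = np.asarray(bathy.values, dtype=float)
    bad = bathy.nodata_mask

    dy_m = bathy.cell_size * KM_PER_DEGREE * 1000.0
    dx_m = dy_m * np.cos(np.radians(bathy.lat_centres()))  # per-row

    # Horn 1981 weights; indices: z[r-1,c-1] .. z[r+1,c+1]
    c = slice(1, -1)
    n, s = slice(0, -2), slice(2, None)
    w, e = slice(0, -2), slice(2, None)
    dzdx = ((z[n, e] + 2 * z[c, e] + z[s, e]) - (z[n, w] + 2 * z[c, w] + z[s, w])) / (
        8.0 * dx_m[1:-1, None]
    )
    dzdy = ((z[n, w] + 2 * z[n, c] + z[n, e]) - (z[s, w] + 2 * z[s, c] + z[s, e])) / (8.0 * dy_m)
    grad = np.hypot(dzdx, dzdy) * 100.0

    out = np.full(bathy.shape, np.nan)
    out[1:-1, 1:-1] = grad
    mask = np.ones(bathy.shape, dtype=bool)
    any_bad = (
        bad[n, w] | bad[n, c] | bad[n, e]
        | bad[c, w] | bad[c, c] | bad[c, e]
        | bad[s, w] | bad[s, c] | bad[s, e]
    )
    mask[1:-1, 1:-1] = any_bad
    out[mask] = np.nan
    return GridLayer(
        name="slope",
        values=out,
        nodata_mask=mask,
        origin_lon=bathy.origin_lon,
        origin_lat=bathy.origin_lat,
        cell_size=bathy.cell_size,
        units="%",
    )


# ---------------------------------------------------------------------------
# point-grid plumbing
# ---------------------------------------------------------------------------

def extract_values(stack: LayerStack, points: OccurrenceSet) -> pd.DataFrame:
    """Per-point variable values by containing-cell lookup.

    Returns a DataFrame indexed by occurrence id with one column per layer;
    categorical layers yield integer codes. Points outside the grid extent
    raise an error listing the offending ids.
    """
    ref = stack.reference
    row, col = ref.cell_index(points.lons, points.lats)
    inside = ref.in_bounds(row, col)
    if not np.all(inside):
        bad = [points.ids[i] for i in np.flatnonzero(~inside)]
        raise GridError(f"points outside grid extent: {bad}")
    data = {}
    for name, lyr in stack.layers.items():
        vals = lyr.values[row, col]
        if isinstance(lyr, CategoricalGridLayer):
            data[name] = vals.astype(int)
        else:
            vals = np.asarray(vals, dtype=float).copy()
            vals[lyr.nodata_mask[row, col]] = np.nan
            data[name] = vals
    return pd.DataFrame(data, index=pd.Index(points.ids, name="id"))


def filter_to_coverage(occ: OccurrenceSet, stack: LayerStack) -> OccurrenceSet:
    """Retain records on cells valid (non-nodata, non-land) in every layer.

    Records falling off the grid are also dropped. The exclusion count is
    logged at INFO level.
    """
    ref = stack.reference
    row, col = ref.cell_index(occ.lons, occ.lats)
    inside = ref.in_bounds(row, col)
    keep = inside.copy()
    valid = stack.valid_mask()
    keep[inside] = valid[row[inside], col[inside]]
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("filter_to_coverage: excluded %d of %d records", n_excluded, len(occ))
    return occ.subset(np.flatnonzero(keep))
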