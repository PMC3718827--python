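"""Raster, occurrence-CSV, region-GeoJSON and stack-directory I/O.

Two raster dialects are supported:

* ESRI ASCII grid (``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``
  header followed by north-to-south rows). Values are written with ``repr``
  so a read/write cycle is byte-identical.
* Single-band float32 GeoTIFF carrying ModelPixelScale/ModelTiepoint and
  GDAL_NODATA tags, handled through :mod:`tifffile`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from habsuit.grid import CategoricalGridLayer, GridLayer, LayerStack, OccurrenceSet, RegionSet

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class FormatError(ValueError):
    """Raised when an input file does not parse under the expected dialect."""


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, name: str | None = None) -> GridLayer:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing ASCII grid header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    for line in lines[i:]:
        if not line.strip():
            continue
        row = np.array(line.split(), dtype=float)
        if row.size != ncols:
            raise FormatError(f"{path}: row has {row.size} values, header ncols is {ncols}")
        rows.append(row)
    if len(rows) != nrows:
        raise FormatError(f"{path}: found {len(rows)} rows, header nrows is {nrows}")
    values = np.vstack(rows) if rows else np.empty((0, ncols))
    mask = (values == nodata) | ~np.isfinite(values)
    cell = header["cellsize"]
    return GridLayer(
        name=name or path.stem,
        values=values,
        nodata_mask=mask,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + nrows * cell,
        cell_size=cell,
    )


def _fmt(x: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_ascii_grid(layer: GridLayer, path: str | Path, nodata: float = DEFAULT_NODATA) -> None:
    path = Path(path)
    vals = np.asarray(layer.values, dtype=float).copy()
    vals[layer.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {layer.ncols}\n")
        fh.write(f"nrows {layer.nrows}\n")
        fh.write(f"xllcorner {_fmt(layer.origin_lon)}\n")
        fh.write(f"yllcorner {_fmt(layer.origin_lat - layer.nrows * layer.cell_size)}\n")
        fh.write(f"cellsize {_fmt(layer.cell_size)}\n")
        fh.write(f"NODATA_value {_fmt(nodata)}\n")
        for r in range(layer.nrows):
            fh.write(" ".join(_fmt(v) for v in vals[r]) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF (single band, float32)
# ---------------------------------------------------------------------------

def read_geotiff(path: str | Path, name: str | None = None) -> GridLayer:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tag ({exc})") from None
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single-band raster, got shape {values.shape}")
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy):
        raise FormatError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
    # tiepoint maps raster (0,0) corner to (lon, lat) of the top-left edge
    origin_lon = float(tie[3]) - float(tie[0]) * sx
    origin_lat = float(tie[4]) + float(tie[1]) * sy
    mask = np.zeros(values.shape, dtype=bool) if nodata is None else (values == nodata)
    mask |= ~np.isfinite(values)
    return GridLayer(
        name=name or path.stem,
        values=values,
        nodata_mask=mask,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=sx,
    )


def write_geotiff(layer: GridLayer, path: str | Path, nodata: float = DEFAULT_NODATA) -> None:
    import tifffile

    vals = np.asarray(layer.values, dtype=np.float32).copy()
    vals[layer.nodata_mask] = np.float32(nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (layer.cell_size, layer.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, layer.origin_lon, layer.origin_lat, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_raster(path: str | Path, dialect: str = "ascii_grid", name: str | None = None) -> GridLayer:
    """Read a single-band raster under the named dialect.

    dialect is one of ``"ascii_grid"`` or ``"geotiff"``.
    """
    if dialect == "ascii_grid":
        return read_ascii_grid(path, name=name)
    if dialect == "geotiff":
        return read_geotiff(path, name=name)
    raise ValueError(f"unknown raster dialect {dialect!r}")


def write_raster(layer: GridLayer, path: str | Path, dialect: str = "ascii_grid", nodata: float = DEFAULT_NODATA) -> None:
    if dialect == "ascii_grid":
        write_ascii_grid(layer, path, nodata=nodata)
    elif dialect == "geotiff":
        write_geotiff(layer, path, nodata=nodata)
    else:
        raise ValueError(f"unknown raster dialect {dialect!r}")


# ---------------------------------------------------------------------------
# occurrences / regions
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a lon,lat[,id] CSV; out-of-range rows are dropped with a warning."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise FormatError(f"{path}: occurrence CSV must have 'lon' and 'lat' columns, got {list(df.columns)}")
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce")
    ok = lon.between(-180, 180) & lat.between(-90, 90)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("read_occurrences: dropped %d rows with out-of-range coordinates", n_bad)
    if "id" in cols:
        ids = df.loc[ok, cols["id"]].astype(str).tolist()
    else:
        ids = [f"occ_{i}" for i in np.flatnonzero(ok.to_numpy())]
    return OccurrenceSet(lon[ok].to_numpy(), lat[ok].to_numpy(), ids)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=False)


def read_regions(path: str | Path) -> RegionSet:
    """Read a GeoJSON FeatureCollection with a 'name' property per feature."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = {}
    for i, feat in enumerate(doc.get("features", [])):
        name = feat.get("properties", {}).get("name", f"region_{i}")
        regions[name] = shape(feat["geometry"])
    return RegionSet(regions)


def write_regions(rs: RegionSet, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": name}, "geometry": mapping(poly)}
            for name, poly in rs.regions.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# stack directories
# ---------------------------------------------------------------------------

def write_stack(stack: LayerStack, outdir: str | Path) -> None:
    """Write every layer as an ASCII grid plus JSON sidecars for legends/mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict = {"layers": {}, "land_mask": "land_mask.asc"}
    for name, lyr in stack.layers.items():
        write_ascii_grid(lyr, outdir / f"{name}.asc")
        entry = {"file": f"{name}.asc", "units": lyr.units}
        if isinstance(lyr, CategoricalGridLayer):
            entry["legend"] = {str(k): v for k, v in lyr.legend.items()}
        meta["layers"][name] = entry
    ref = stack.reference
    land = GridLayer(
        name="land_mask",
        values=stack.land_mask.astype(float),
        nodata_mask=np.zeros(ref.shape, dtype=bool),
        origin_lon=ref.origin_lon,
        origin_lat=ref.origin_lat,
        cell_size=ref.cell_size,
    )
    write_ascii_grid(land, outdir / "land_mask.asc")
    with open(outdir / "stack.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_stack(indir: str | Path) -> LayerStack:
    indir = Path(indir)
    with open(indir / "stack.json") as fh:
        meta = json.load(fh)
    layers: dict[str, GridLayer] = {}
    for name, entry in meta["layers"].items():
        lyr = read_ascii_grid(indir / entry["file"], name=name)
        lyr.units = entry.get("units", "")
        if "legend" in entry:
            legend = {int(k): v for k, v in entry["legend"].items()}
            lyr = CategoricalGridLayer(
                name=name,
                values=lyr.values,
                nodata_mask=lyr.nodata_mask,
                origin_lon=lyr.origin_lon,
                origin_lat=lyr.origin_lat,
                cell_size=lyr.cell_size,
                units=lyr.units,
                legend=legend,
            )
        layers[name] = lyr
    land = read_ascii_grid(indir / meta["land_mask"])
    return LayerStack(layers, land.values.astype(bool))
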