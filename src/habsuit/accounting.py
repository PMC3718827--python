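"""Suitability banding, band/category area accounting per region, percent-loss
tables and envelope-vs-model comparison statistics.

Probabilities are split into ten width-0.1 bands (1.0 closing the top band)
and three categories: "most suitable" (MS) = [0.5, 1.0], "less suitable"
(LS) = [0.1, 0.5) and "unsuitable" (US) = [0.0, 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from habsuit.grid import GridError, GridLayer, RegionSet, cell_area_km2

CATEGORIES = ("MS", "LS", "US")
N_BANDS = 10


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def categorize(p: float) -> tuple[int, str]:
    """Band index 0-9 and habitat category of a probability.

    Bands are half-open ``[k/10, (k+1)/10)`` with 1.0 assigned to band 9.
    MS covers the top five bands, US is band 0, LS is bands 1-4.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability outside [0, 1]: {p}")
    # the epsilon keeps decimal boundaries exact (0.7 * 10 is 6.999... in IEEE)
    band = min(int(math.floor(p * N_BANDS + 1e-9)), N_BANDS - 1)
    cat = "MS" if band >= 5 else ("US" if band == 0 else "LS")
    return band, cat


def _band_grid(values: np.ndarray) -> np.ndarray:
    bands = np.floor(values * N_BANDS + 1e-9).astype(int)
    return np.clip(bands, 0, N_BANDS - 1)


def _region_membership(layer: GridLayer, regions: RegionSet) -> dict[str, np.ndarray]:
    """Boolean cell masks per region by centre-in-polygon."""
    lon_c, lat_c = np.meshgrid(layer.lon_centres(), layer.lat_centres())
    out = {}
    for name, poly in regions.regions.items():
        inside = shapely.contains_xy(poly, lon_c.ravel(), lat_c.ravel()).reshape(layer.shape)
        out[name] = inside
    return out


def band_areas(suitability: GridLayer, regions: RegionSet | None = None) -> pd.DataFrame:
    """Summed cell areas per probability band and category, optionally per
    region (plus an "ALL" row set covering the whole map).

    Returns a tidy DataFrame with columns region, band, category, area_km2.
    Regions that do not intersect the grid produce zero-area rows.
    """
    vals = suitability.values
    valid = ~suitability.nodata_mask
    if np.any((vals[valid] < 0) | (vals[valid] > 1)):
        raise ValueError("suitability values outside [0, 1]")
    areas = cell_area_km2(suitability).values
    bands = np.where(valid, _band_grid(np.nan_to_num(vals)), -1)

    memberships: dict[str, np.ndarray] = {"ALL": np.ones(suitability.shape, dtype=bool)}
    if regions is not None:
        memberships.update(_region_membership(suitability, regions))

    rows = []
    for region, member in memberships.items():
        sel = member & valid
        for band in range(N_BANDS):
            in_band = sel & (bands == band)
            cat = "MS" if band >= 5 else ("US" if band == 0 else "LS")
            rows.append(
                {
                    "region": region,
                    "band": band,
                    "category": cat,
                    "area_km2": float(areas[in_band].sum()),
                }
            )
    return pd.DataFrame(rows)


def category_areas(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a band-area table to category areas per region."""
    return (
        table.groupby(["region", "category"], as_index=False)["area_km2"]
        .sum()
        .sort_values(["region", "category"])
        .reset_index(drop=True)
    )


def percent_loss(a0: float, at: float):
    """Integer percent loss from a baseline area; "n/a" when the baseline is
    zero, negative (a gain) when the later area exceeds the baseline."""
    if a0 < 0 or at < 0:
        raise ValueError("areas must be non-negative")
    if a0 == 0:
        return "n/a"
    return _round_half_up((a0 - at) / a0 * 100.0)


@dataclass
class ComparisonStats:
    envelope_area_km2: float
    category_area_km2: dict[str, float]
    overlap_percent: dict[str, int]  # per category, envelope∩category / category
    combined_overlap_percent: int  # envelope∩(MS∪LS) / (MS∪LS)
    over_prediction_percent: int  # ((MS∪LS) − envelope) / (MS∪LS)


def combined_overlap_percent(category_areas_km2: dict[str, float], overlap_fractions: dict[str, float]) -> int:
    """Area-weighted envelope overlap of MS∪LS, as an integer percent.

    ``overlap_fractions`` holds the per-category fraction (0-1) of the
    category's area overlapped by the envelope.
    """
    total = sum(category_areas_km2[c] for c in ("MS", "LS"))
    if total == 0:
        raise ValueError("MS and LS areas are both zero")
    overlapped = sum(overlap_fractions[c] * category_areas_km2[c] for c in ("MS", "LS"))
    return _round_half_up(overlapped / total * 100.0)


def over_prediction_percent(envelope_area_km2: float, category_areas_km2: dict[str, float]) -> int:
    """Integer percent by which the model's MS∪LS area exceeds the envelope."""
    total = sum(category_areas_km2[c] for c in ("MS", "LS"))
    if total == 0:
        raise ValueError("MS and LS areas are both zero")
    return _round_half_up((total - envelope_area_km2) / total * 100.0)


def overlap_stats(envelope_mask: GridLayer, suitability: GridLayer) -> ComparisonStats:
    """Envelope-vs-model comparison on shared geometry."""
    if not envelope_mask.same_geometry(suitability):
        raise GridError("envelope mask and suitability map geometry mismatch")
    valid = ~suitability.nodata_mask & ~envelope_mask.nodata_mask
    areas = cell_area_km2(suitability).values
    env = (envelope_mask.values > 0) & valid
    bands = _band_grid(np.nan_to_num(suitability.values))
    cat_grid = np.where(bands >= 5, 0, np.where(bands >= 1, 1, 2))  # MS, LS, US

    cat_area = {}
    overlap_pct = {}
    overlap_frac = {}
    for ci, cat in enumerate(CATEGORIES):
        sel = valid & (cat_grid == ci)
        a = float(areas[sel].sum())
        o = float(areas[sel & env].sum())
        cat_area[cat] = a
        overlap_frac[cat] = (o / a) if a > 0 else 0.0
        overlap_pct[cat] = _round_half_up(overlap_frac[cat] * 100.0) if a > 0 else 0
    env_area = float(areas[env].sum())
    return ComparisonStats(
        envelope_area_km2=env_area,
        category_area_km2=cat_area,
        overlap_percent=overlap_pct,
        combined_overlap_percent=combined_overlap_percent(cat_area, overlap_frac),
        over_prediction_percent=over_prediction_percent(env_area, cat_area),
    )


def loss_table(tables_by_epoch: dict[int, pd.DataFrame], baseline_epoch: int) -> pd.DataFrame:
    """Per region x epoch MS area and integer percent loss vs the baseline.

    ``tables_by_epoch`` maps epoch year to a band-area table from
    :func:`band_areas`; every epoch must cover the same regions.
    """
    if baseline_epoch not in tables_by_epoch:
        raise ValueError(f"baseline epoch {baseline_epoch} missing from tables")
    ms = {
        epoch: category_areas(tab).query("category == 'MS'").set_index("region")["area_km2"]
        for epoch, tab in tables_by_epoch.items()
    }
    base = ms[baseline_epoch]
    for epoch, series in ms.items():
        if set(series.index) != set(base.index):
            raise ValueError(f"epoch {epoch} covers different regions than the baseline")
    rows = []
    for region in base.index:
        for epoch in sorted(ms):
            rows.append(
                {
                    "region": region,
                    "epoch": epoch,
                    "ms_area_km2": round(float(ms[epoch][region]), 2),
                    "percent_loss": percent_loss(float(base[region]), float(ms[epoch][region])),
                }
            )
    return pd.DataFrame(rows)
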