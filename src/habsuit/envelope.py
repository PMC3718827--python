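"""Environmental envelope analysis.

Occurrences are grouped into populations by single-linkage proximity, each
population is buffered into a bed footprint, per-variable preferred ranges
are the interquartile ranges of values at occurrence cells, and landscape
classes are preferred when inhabited by at least the median (positive)
fraction of populations. The envelope is the cellwise conjunction of all
preferred ranges and classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from habsuit.grid import (
    CategoricalGridLayer,
    GridError,
    GridLayer,
    LayerStack,
    OccurrenceSet,
    KM_PER_DEGREE,
    cell_area_km2,
    extract_values,
    haversine_km,
)

logger = logging.getLogger(__name__)

DEFAULT_LINKAGE_KM = 10.0
DEFAULT_BUFFER_KM = 1.0


@dataclass
class Population:
    pid: str
    member_idx: np.ndarray  # indices into the grouped OccurrenceSet
    member_ids: list[str]
    footprint_cells: np.ndarray | None = None  # boolean grid, sea-clipped
    footprint_area_km2: float | None = None  # analytic union-of-disks area, unclipped


@dataclass
class PopulationSet:
    occurrences: OccurrenceSet
    populations: list[Population]
    linkage_km: float

    def __len__(self) -> int:
        return len(self.populations)


@dataclass
class EnvelopeSpec:
    """Per-variable preferred intervals plus preferred landscape classes."""

    continuous_ranges: dict[str, tuple[float, float]]
    preferred_landscape: frozenset[int]
    landscape_fractions: dict[int, float] = field(default_factory=dict)
    landscape_median: float = float("nan")
    landscape_max: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.continuous_ranges.items():
            if lo > hi:
                raise ValueError(f"envelope range for {var!r} has lo > hi: [{lo}, {hi}]")
        self.preferred_landscape = frozenset(int(c) for c in self.preferred_landscape)

    def to_table(self, legend: dict[int, str] | None = None) -> pd.DataFrame:
        """Preferred-range report, one row per environmental layer entry."""
        rows = [
            {"layer": var, "preferred_range": f"{lo:g} to {hi:g}"}
            for var, (lo, hi) in self.continuous_ranges.items()
        ]
        for code in sorted(self.preferred_landscape):
            label = legend.get(code, str(code)) if legend else str(code)
            rows.append({"layer": "landscape", "preferred_range": label})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "continuous_ranges": {k: list(v) for k, v in self.continuous_ranges.items()},
            "preferred_landscape": sorted(self.preferred_landscape),
            "landscape_fractions": {str(k): v for k, v in self.landscape_fractions.items()},
            "landscape_median": self.landscape_median,
            "landscape_max": self.landscape_max,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvelopeSpec":
        return cls(
            continuous_ranges={k: tuple(v) for k, v in d["continuous_ranges"].items()},
            preferred_landscape=frozenset(d["preferred_landscape"]),
            landscape_fractions={int(k): v for k, v in d.get("landscape_fractions", {}).items()},
            landscape_median=d.get("landscape_median", float("nan")),
            landscape_max=d.get("landscape_max", float("nan")),
            provenance=d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# population grouping
# ---------------------------------------------------------------------------

def _chord_crosses_land(lon1, lat1, lon2, lat2, stack: LayerStack) -> bool:
    """Sample the straight lon/lat chord at half-cell steps against land."""
    ref = stack.reference
    d_deg = max(abs(lon2 - lon1), abs(lat2 - lat1))
    n = max(2, int(np.ceil(d_deg / (0.5 * ref.cell_size))) + 1)
    lons = np.linspace(lon1, lon2, n)
    lats = np.linspace(lat1, lat2, n)
    rows, cols = ref.cell_index(lons, lats)
    inb = ref.in_bounds(rows, cols)
    return bool(np.any(stack.land_mask[rows[inb], cols[inb]]))


def group_populations(
    occ: OccurrenceSet,
    linkage_km: float = DEFAULT_LINKAGE_KM,
    land_barrier_stack: LayerStack | None = None,
) -> PopulationSet:
    """Single-linkage connected components under haversine distance.

    Two records link when within ``linkage_km`` of each other; optionally a
    link is vetoed when its connecting chord crosses land in the supplied
    stack. Population ids are ordered by their southernmost member.
    """
    n = len(occ)
    if n == 0:
        raise GridError("need at least one occurrence to group")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        d = haversine_km(occ.lons[i], occ.lats[i], occ.lons[i + 1 :], occ.lats[i + 1 :])
        for off in np.flatnonzero(np.atleast_1d(d) <= linkage_km):
            j = i + 1 + int(off)
            if land_barrier_stack is not None and _chord_crosses_land(
                occ.lons[i], occ.lats[i], occ.lons[j], occ.lats[j], land_barrier_stack
            ):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    # order by the southernmost member latitude
    groups = sorted(comps.values(), key=lambda idx: (min(occ.lats[i] for i in idx), min(idx)))
    pops = [
        Population(
            pid=f"P{k + 1}",
            member_idx=np.array(idx),
            member_ids=[occ.ids[i] for i in idx],
        )
        for k, idx in enumerate(groups)
    ]
    return PopulationSet(occ, pops, linkage_km)


def buffer_populations(
    pops: PopulationSet,
    stack: LayerStack,
    radius_km: float = DEFAULT_BUFFER_KM,
) -> PopulationSet:
    """Attach a buffered bed footprint to every population.

    The footprint is the union of per-occurrence disks of ``radius_km``:
    grid cells whose centre lies within ``radius_km`` of any member point,
    clipped to sea; the analytic (unclipped) union-of-disks area is computed
    in a local planar frame for reporting.
    """
    ref = stack.reference
    sea = stack.valid_mask()
    lon_c = ref.lon_centres()
    lat_c = ref.lat_centres()
    occ = pops.occurrences
    for pop in pops.populations:
        lons = occ.lons[pop.member_idx]
        lats = occ.lats[pop.member_idx]
        # bounding window in degrees, padded by the radius
        pad_lat = radius_km / KM_PER_DEGREE + ref.cell_size
        pad_lon = radius_km / (KM_PER_DEGREE * np.cos(np.radians(lats.mean()))) + ref.cell_size
        rsel = np.flatnonzero((lat_c >= lats.min() - pad_lat) & (lat_c <= lats.max() + pad_lat))
        csel = np.flatnonzero((lon_c >= lons.min() - pad_lon) & (lon_c <= lons.max() + pad_lon))
        cells = np.zeros(ref.shape, dtype=bool)
        if rsel.size and csel.size:
            glon, glat = np.meshgrid(lon_c[csel], lat_c[rsel])
            within = np.zeros(glon.shape, dtype=bool)
            for plon, plat in zip(lons, lats):
                within |= haversine_km(plon, plat, glon, glat) <= radius_km
            cells[np.ix_(rsel, csel)] = within
        cells &= sea
        pop.footprint_cells = cells
        # analytic area: equirectangular plane about the population centroid
        lat0 = float(lats.mean())
        kx = KM_PER_DEGREE * np.cos(np.radians(lat0))
        disks = [
            Point((lo - lons.mean()) * kx, (la - lat0) * KM_PER_DEGREE).buffer(radius_km, quad_segs=128)
            for lo, la in zip(lons, lats)
        ]
        pop.footprint_area_km2 = float(unary_union(disks).area)
        if not cells.any():
            logger.warning("population %s footprint is entirely on land/nodata cells", pop.pid)
    return pops


# ---------------------------------------------------------------------------
# preferred ranges
# ---------------------------------------------------------------------------

def preferred_range(values) -> tuple[float, float]:
    """Interquartile [Q1, Q3] with type-7 (linear interpolation) quartiles."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("preferred_range needs at least one finite value")
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # numpy default is type 7
    return float(q1), float(q3)


def landscape_preference(pops: PopulationSet, landscape: CategoricalGridLayer) -> frozenset[int]:
    """Landscape codes inhabited by at least the median (positive) fraction
    of populations.

    For each code t, ``f_t`` is the fraction of populations whose buffered
    footprint overlaps at least one cell of t; preferred codes are those with
    ``f_t > 0`` and ``f_t >= median of the positive fractions``.
    """
    fracs, _, _ = landscape_inhabitation(pops, landscape)
    if not fracs:
        return frozenset()
    pos = np.array([f for f in fracs.values() if f > 0])
    med = float(np.median(pos))
    return frozenset(t for t, f in fracs.items() if f > 0 and f >= med)


def landscape_inhabitation(
    pops: PopulationSet, landscape: CategoricalGridLayer
) -> tuple[dict[int, float], float, float]:
    """Inhabitation fraction per code, plus the median and max of the
    positive fractions (the maximum is reported but plays no role in
    selection)."""
    for pop in pops.populations:
        if pop.footprint_cells is None:
            raise GridError("populations must be buffered before landscape_preference")
        if pop.footprint_cells.shape != landscape.shape:
            raise GridError(
                f"landscape layer shape {landscape.shape} does not match "
                f"footprint shape {pop.footprint_cells.shape}"
            )
    codes = np.unique(landscape.values[~landscape.nodata_mask])
    n_pop = len(pops.populations)
    fracs: dict[int, float] = {}
    for t in codes:
        is_t = (landscape.values == t) & ~landscape.nodata_mask
        hit = sum(1 for pop in pops.populations if np.any(pop.footprint_cells & is_t))
        fracs[int(t)] = hit / n_pop
    pos = [f for f in fracs.values() if f > 0]
    med = float(np.median(pos)) if pos else float("nan")
    mx = float(max(pos)) if pos else float("nan")
    return fracs, med, mx


def build_envelope(
    stack: LayerStack,
    occ: OccurrenceSet,
    linkage_km: float = DEFAULT_LINKAGE_KM,
    buffer_km: float = DEFAULT_BUFFER_KM,
    land_barrier: bool = False,
) -> EnvelopeSpec:
    """Full envelope construction from a coverage-filtered occurrence set.

    Continuous preferred ranges pool values over all occurrence cells; the
    1 km buffers enter only through the landscape-overlap step.
    """
    values = extract_values(stack, occ)
    ranges = {var: preferred_range(values[var]) for var in stack.continuous_names()}
    pops = group_populations(
        occ, linkage_km, land_barrier_stack=stack if land_barrier else None
    )
    pops = buffer_populations(pops, stack, buffer_km)
    cat_names = stack.categorical_names()
    preferred: frozenset[int] = frozenset()
    fracs: dict[int, float] = {}
    med = mx = float("nan")
    if cat_names:
        landscape = stack[cat_names[0]]
        fracs, med, mx = landscape_inhabitation(pops, landscape)
        pos = np.array([f for f in fracs.values() if f > 0])
        preferred = frozenset(t for t, f in fracs.items() if f > 0 and f >= np.median(pos))
    return EnvelopeSpec(
        continuous_ranges=ranges,
        preferred_landscape=preferred,
        landscape_fractions=fracs,
        landscape_median=med,
        landscape_max=mx,
        provenance={
            "n_occurrences": len(occ),
            "n_populations": len(pops),
            "linkage_km": linkage_km,
            "buffer_km": buffer_km,
        },
    )


def envelope_mask(stack: LayerStack, env: EnvelopeSpec) -> GridLayer:
    """Boolean grid: cell is in-envelope iff every continuous value lies in
    its closed interval, the landscape code is preferred, and the cell is a
    valid sea cell. Values are 1.0/0.0 with nodata where the stack is invalid.
    """
    missing = [v for v in env.continuous_ranges if v not in stack]
    if missing:
        raise GridError(f"stack is missing enveloped variable(s): {missing}")
    valid = stack.valid_mask()
    ok = valid.copy()
    for var, (lo, hi) in env.continuous_ranges.items():
        lyr = stack[var]
        with np.errstate(invalid="ignore"):
            ok &= (lyr.values >= lo) & (lyr.values <= hi)
    cat_names = stack.categorical_names()
    if env.preferred_landscape and cat_names:
        codes = stack[cat_names[0]].values
        ok &= np.isin(codes, sorted(env.preferred_landscape))
    ref = stack.reference
    return GridLayer(
        name="envelope",
        values=ok.astype(float),
        nodata_mask=~valid,
        origin_lon=ref.origin_lon,
        origin_lat=ref.origin_lat,
        cell_size=ref.cell_size,
        units="bool",
    )


def envelope_area_km2(mask_layer: GridLayer) -> float:
    """Total area of in-envelope cells."""
    areas = cell_area_km2(mask_layer).values
    sel = (mask_layer.values > 0) & ~mask_layer.nodata_mask
    return float(areas[sel].sum())
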