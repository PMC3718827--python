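"""Synthetic environmental stacks, occurrences and regions with known truth.

Continuous fields are Gaussian-filtered white noise (the ``smoothness``
parameter is the filter sigma in cells), temperature additionally carries a
configurable latitudinal gradient, and the land mask and landscape classes
come from thresholded smooth fields so patches are spatially contiguous.
Occurrences are drawn by rejection sampling inside a known "true" envelope,
clustered into spatially separated populations. Everything is deterministic
under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from habsuit.grid import (
    CategoricalGridLayer,
    GridLayer,
    GridError,
    LayerStack,
    OccurrenceSet,
    RegionSet,
    KM_PER_DEGREE,
    haversine_km,
    slope_percent,
)

CONTINUOUS_VARIABLES = ("temperature", "bathymetry", "slope", "salinity", "current_speed")
LANDSCAPE = "landscape"

_UNITS = {
    "temperature": "degC",
    "bathymetry": "m",
    "slope": "%",
    "salinity": "PSS",
    "current_speed": "m/s",
}


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic domain. Defaults give a desk-scale 200x200 grid."""

    lon_min: float = -4.0
    lon_max: float = 6.0
    lat_min: float = 50.0
    lat_max: float = 60.0
    cell_size: float = 0.05
    seed: int = 0
    smoothness: float = 8.0
    n_landscape_classes: int = 4
    n_populations: int = 3
    pop_spread_km: float = 6.0
    pts_per_pop: int = 30
    contamination: float = 0.0
    land_fraction: float = 0.1
    linkage_km: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination < 0.5):
            raise ValueError(f"contamination must be in [0, 0.5), got {self.contamination}")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("extent is degenerate")
        if self.n_landscape_classes < 2:
            raise ValueError("need at least 2 landscape classes")

    @property
    def shape(self) -> tuple[int, int]:
        nrows = int(round((self.lat_max - self.lat_min) / self.cell_size))
        ncols = int(round((self.lon_max - self.lon_min) / self.cell_size))
        return nrows, ncols

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSpec:
    """Generating envelope: per-variable intervals plus preferred landscape codes."""

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "temperature": (8.0, 10.0),
            "bathymetry": (-40.0, -5.0),
            "slope": (0.0, 5.0),
            "salinity": (33.5, 35.0),
            "current_speed": (0.3, 1.2),
        }
    )
    preferred_landscape: frozenset[int] = frozenset({0, 1})
    temperature_gradient: float = -0.6  # degC per degree latitude, negative northwards

    def __post_init__(self) -> None:
        for var, (a, b) in self.intervals.items():
            if not a < b:
                raise ValueError(f"truth interval for {var!r} must satisfy a < b, got [{a}, {b}]")
        if not self.preferred_landscape:
            raise ValueError("preferred landscape set must be non-empty")
        self.preferred_landscape = frozenset(int(c) for c in self.preferred_landscape)

    def to_dict(self) -> dict:
        return {
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "preferred_landscape": sorted(self.preferred_landscape),
            "temperature_gradient": self.temperature_gradient,
        }


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_environment(config: SyntheticConfig, truth: TruthSpec) -> LayerStack:
    """Five continuous layers plus one categorical landscape layer.

    Temperature carries the configured latitudinal gradient; slope is derived
    from bathymetry with :func:`habsuit.grid.slope_percent`, so its border
    cells are nodata.
    """
    rng = np.random.default_rng([config.seed, 0])
    nrows, ncols = config.shape
    shape = (nrows, ncols)
    origin_lon, origin_lat = config.lon_min, config.lat_max
    lat_c = origin_lat - (np.arange(nrows) + 0.5) * config.cell_size
    no_mask = np.zeros(shape, dtype=bool)

    def make(name: str, values: np.ndarray, mask: np.ndarray | None = None) -> GridLayer:
        return GridLayer(
            name=name,
            values=values,
            nodata_mask=no_mask.copy() if mask is None else mask,
            origin_lon=origin_lon,
            origin_lat=origin_lat,
            cell_size=config.cell_size,
            units=_UNITS.get(name, ""),
        )

    # land along the warmest/noisiest corner of one smooth field
    land_field = _smooth_field(rng, shape, config.smoothness)
    if config.land_fraction > 0:
        thr = np.quantile(land_field, 1.0 - config.land_fraction)
        land = land_field >= thr
    else:
        land = np.zeros(shape, dtype=bool)

    mid_lat = 0.5 * (config.lat_min + config.lat_max)
    t_lo, t_hi = truth.intervals["temperature"]
    t_mid, t_w = 0.5 * (t_lo + t_hi), 0.5 * (t_hi - t_lo)
    temperature = (
        t_mid
        + truth.temperature_gradient * (lat_c[:, None] - mid_lat)
        + 0.5 * t_w * _smooth_field(rng, shape, config.smoothness)
    )

    def spanned(var: str, widen: float = 1.5) -> np.ndarray:
        lo, hi = truth.intervals[var]
        mid, w = 0.5 * (lo + hi), 0.5 * (hi - lo)
        return mid + widen * w * _smooth_field(rng, shape, config.smoothness)

    bathymetry = spanned("bathymetry")
    salinity = spanned("salinity")
    current = spanned("current_speed")

    bathy_layer = make("bathymetry", bathymetry)
    slope_layer = slope_percent(bathy_layer)
    slope_layer.name = "slope"

    ls_field = _smooth_field(rng, shape, config.smoothness)
    edges = np.quantile(ls_field, np.linspace(0, 1, config.n_landscape_classes + 1)[1:-1])
    codes = np.digitize(ls_field, edges)
    landscape = CategoricalGridLayer(
        name=LANDSCAPE,
        values=codes,
        nodata_mask=no_mask.copy(),
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=config.cell_size,
        legend={i: f"class_{i}" for i in range(config.n_landscape_classes)},
    )

    layers = {
        "temperature": make("temperature", temperature),
        "bathymetry": bathy_layer,
        "slope": slope_layer,
        "salinity": make("salinity", salinity),
        "current_speed": make("current_speed", current),
        LANDSCAPE: landscape,
    }
    return LayerStack(layers, land)


def truth_mask(stack: LayerStack, truth: TruthSpec) -> np.ndarray:
    """Boolean grid of cells satisfying every truth interval and code, at sea."""
    ok = stack.valid_mask()
    for var, (lo, hi) in truth.intervals.items():
        lyr = stack[var]
        with np.errstate(invalid="ignore"):
            ok &= (lyr.values >= lo) & (lyr.values <= hi)
    codes = stack[LANDSCAPE].values
    ok &= np.isin(codes, sorted(truth.preferred_landscape))
    return ok


def _jitter_in_cell(rng: np.random.Generator, layer: GridLayer, rows, cols):
    """Uniform random positions strictly inside the given cells."""
    u = rng.uniform(0.0, 1.0, size=np.shape(rows))
    v = rng.uniform(0.0, 1.0, size=np.shape(rows))
    lon = layer.origin_lon + (np.asarray(cols) + u) * layer.cell_size
    lat = layer.origin_lat - (np.asarray(rows) + v) * layer.cell_size
    return lon, lat


def generate_occurrences(stack: LayerStack, truth: TruthSpec, config: SyntheticConfig) -> OccurrenceSet:
    """Occurrences clustered into separated populations inside the truth region.

    Population centres are placed at least ``3 * linkage_km`` apart on
    truth-satisfying cells; members scatter within ``pop_spread_km`` of their
    centre (resampled until they land on a truth cell). A ``contamination``
    fraction is placed uniformly at random on sea cells, ignoring truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    ref = stack.reference
    ok = truth_mask(stack, truth)
    cand = np.flatnonzero(ok.ravel())
    if cand.size == 0:
        raise GridError(
            "truth region is empty on this stack; widen the truth intervals "
            "or the preferred landscape set"
        )
    rows, cols = np.unravel_index(cand, ok.shape)
    lat_c = ref.origin_lat - (rows + 0.5) * ref.cell_size
    lon_c = ref.origin_lon + (cols + 0.5) * ref.cell_size

    min_sep = 3.0 * config.linkage_km
    order = rng.permutation(cand.size)
    centres: list[int] = []
    for idx in order:
        if all(
            haversine_km(lon_c[idx], lat_c[idx], lon_c[j], lat_c[j]) > min_sep for j in centres
        ):
            centres.append(idx)
        if len(centres) == config.n_populations:
            break
    if len(centres) < config.n_populations:
        raise GridError(
            f"could only place {len(centres)} of {config.n_populations} population "
            f"centres at {min_sep:.0f} km separation; enlarge the extent or truth region"
        )

    n_total = config.n_populations * config.pts_per_pop
    lons = np.empty(n_total)
    lats = np.empty(n_total)
    k = 0
    for c in centres:
        clon, clat = lon_c[c], lat_c[c]
        placed = 0
        attempts = 0
        while placed < config.pts_per_pop:
            attempts += 1
            if attempts > 20000:
                raise GridError("rejection sampling stalled; increase pop_spread_km or truth region")
            # uniform in a disk of radius pop_spread_km around the centre
            r = config.pop_spread_km * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            dlat = (r * np.sin(theta)) / KM_PER_DEGREE
            dlon = (r * np.cos(theta)) / (KM_PER_DEGREE * np.cos(np.radians(clat)))
            lon, lat = clon + dlon, clat + dlat
            rr, cc = ref.cell_index(lon, lat)
            if not ref.in_bounds(rr, cc) or not ok[rr, cc]:
                continue
            lons[k], lats[k] = lon, lat
            placed += 1
            k += 1

    # contamination: uniform over sea cells, truth ignored
    n_contam = int(round(config.contamination * n_total))
    if n_contam:
        sea = np.flatnonzero(stack.valid_mask().ravel())
        pick = rng.choice(sea.size, size=n_contam, replace=True)
        srows, scols = np.unravel_index(sea[pick], ok.shape)
        clons, clats = _jitter_in_cell(rng, ref, srows, scols)
        swap = rng.choice(n_total, size=n_contam, replace=False)
        lons[swap] = clons
        lats[swap] = clats

    ids = [f"occ_{i:04d}" for i in range(n_total)]
    return OccurrenceSet(lons, lats, ids)


def generate_regions(config: SyntheticConfig, n_regions: int) -> RegionSet:
    """Rectangular tiling of the extent into ``n_regions`` named tiles.

    Uses the most square a x b factorization of ``n_regions`` (falling back
    to a single strip when prime). Names are "R1".."Rn", row-major from the
    north-west corner.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    a = max(d for d in range(1, int(np.sqrt(n_regions)) + 1) if n_regions % d == 0)
    b = n_regions // a  # a rows x b cols, a <= b
    dlat = (config.lat_max - config.lat_min) / a
    dlon = (config.lon_max - config.lon_min) / b
    regions = {}
    k = 1
    for i in range(a):
        top = config.lat_max - i * dlat
        for j in range(b):
            left = config.lon_min + j * dlon
            regions[f"R{k}"] = box(left, top - dlat, left + dlon, top)
            k += 1
    return RegionSet(regions)
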