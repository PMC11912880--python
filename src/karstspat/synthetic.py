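"""Synthetic occurrence, landscape, protected-area and raster generator.

Downstream stages (cleaning, gridded diversity indices, hotspot and gap
analysis, driver ordination) are tested against data with *planted*
structure: species with heavy-tailed range sizes, spatially clustered
occurrences, richness/endemism hotspots at known locations, a patchy
karst polygon layer covering a minority of the domain, protected areas
covering a controlled share of the planted hotspot cells, and smooth
environmental gradients whose karst/non-karst mean difference is set by
an effect size. Everything is driven by one integer seed and is
byte-reproducible.

Statistical choices mirror compiled occurrence datasets of tropical
ferns and lycophytes: most species are narrow-ranged (Pareto-tailed
range radii), sampling is dominated by database records, and a small
fraction of rows is deliberately dirty (out-of-bounds coordinates,
exact duplicates, blank names) to exercise every cleaning rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .grid import Cell, GridSpec
from .rasters import Raster

#: layers emulating the driver set: seven bioclimatic variables plus
#: depth to bedrock, elevation, organic carbon and clay content.
#: (mean, noise SD, gradient amplitude in noise-SD units) per layer.
DEFAULT_LAYERS: dict[str, tuple[float, float, float]] = {
    "BIO1": (26.0, 1.0, 2.0),       # annual mean temperature, degC
    "BIO4": (150.0, 30.0, 1.5),     # temperature seasonality
    "BIO7": (10.0, 1.5, 1.5),       # annual temperature range, degC
    "BIO12": (2500.0, 400.0, 2.0),  # annual precipitation, mm
    "BIO15": (60.0, 12.0, 1.5),     # precipitation seasonality
    "BIO17": (200.0, 60.0, 1.5),    # precipitation of driest quarter, mm
    "BIO19": (500.0, 120.0, 1.5),   # precipitation of coldest quarter, mm
    "BDTICM": (2000.0, 500.0, 1.0), # absolute depth to bedrock, cm
    "elevation": (500.0, 250.0, 2.0),  # m
    "ORC": (30.0, 8.0, 1.0),        # soil organic carbon, g/kg
    "clay": (30.0, 6.0, 1.0),       # clay content, %
}

SOURCES = ("field", "herbarium", "database", "literature")
SOURCE_PROBS = (0.05, 0.05, 0.85, 0.05)


@dataclass(frozen=True)
class HotspotCenter:
    """A planted diversity hotspot: narrow endemics concentrate here."""

    lon: float
    lat: float
    radius: float = 0.15       # degrees
    intensity: float = 10.0    # occurrence oversampling multiplier


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults give a desk-scale analogue of an archipelago-wide
    compilation: an 4 x 4 degree domain, 80 species with 3-60 raw
    points each, a karst layer over ~30% of the domain and protected
    areas over half of the planted hotspot cells.
    """

    n_species: int = 80
    n_points_min: int = 3
    n_points_max: int = 60
    domain_bbox: tuple[float, float, float, float] = (120.0, 10.0, 124.0, 14.0)
    range_shape: float = 1.5     # Pareto tail index of range radii
    range_scale: float = 0.05    # degrees; minimum range radius
    endemic_radius: float = 0.04  # degrees; range radius of hotspot endemics
    hotspot_centers: tuple[HotspotCenter, ...] = ()
    karst_fraction: float = 0.3
    pa_coverage: float = 0.5
    env_separation: float = 0.0  # karst/non-karst mean shift, noise-SD units
    dirty_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        west, south, east, north = self.domain_bbox
        if east <= west or north <= south:
            raise ValueError("empty domain_bbox")
        if self.n_species < 0:
            raise ValueError("n_species must be non-negative")
        if not 0 < self.n_points_min <= self.n_points_max:
            raise ValueError("invalid n_points range")
        for name in ("karst_fraction", "pa_coverage", "dirty_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def domain_polygon(self) -> BaseGeometry:
        return box(*self.domain_bbox)

    @property
    def domain_area(self) -> float:
        west, south, east, north = self.domain_bbox
        return (east - west) * (north - south)

    def planted_cells(self, grid: GridSpec) -> set[Cell]:
        """Grid cells containing the planted hotspot centers."""
        return {grid.cell_of(h.lon, h.lat) for h in self.hotspot_centers}

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, stream]))


def _sample_in_disk(rng, lon, lat, radius, n):
    theta = rng.uniform(0, 2 * math.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    return lon + r * np.cos(theta), lat + r * np.sin(theta)


def _uniform_disk_points(rng, center, radius, n, bbox):
    """Uniform draws from the disk around ``center`` rejected into
    ``bbox``; the bounded support keeps species ranges contiguous and
    their occupied-cell counts finite regardless of sample size."""
    west, south, east, north = bbox
    lons = np.empty(n)
    lats = np.empty(n)
    filled = 0
    for _ in range(200):
        k = n - filled
        if k == 0:
            break
        x, y = _sample_in_disk(rng, center[0], center[1], radius, k)
        ok = (x >= west) & (x <= east) & (y >= south) & (y <= north)
        m = int(ok.sum())
        lons[filled : filled + m] = x[ok]
        lats[filled : filled + m] = y[ok]
        filled += m
    if filled < n:  # pathological center far outside; clip remainder
        x, y = _sample_in_disk(rng, center[0], center[1], radius, n - filled)
        lons[filled:] = np.clip(x, west, east)
        lats[filled:] = np.clip(y, south, north)
    return lons, lats


def generate_occurrences(scenario: SyntheticScenario) -> pd.DataFrame:
    """Raw occurrence table with planted spatial structure.

    Each species occupies a contiguous range (points around a
    species-specific center with species-specific spread); range radii
    follow a Pareto(shape) tail so most species are narrow-ranged.
    Species are preferentially centred inside hotspot circles in
    proportion to hotspot intensity and area, where their ranges are
    also capped to stay narrow — this is what plants richness *and*
    endemism peaks. Points falling inside a hotspot are additionally
    oversampled by the intensity multiplier. A ``dirty_fraction`` of
    extra rows (out-of-bounds points, exact duplicates, blank species
    names) is appended for the cleaning stage to remove.

    Columns: ``species, decimalLongitude, decimalLatitude, source``.
    """
    if scenario.n_species == 0:
        return pd.DataFrame(
            columns=["species", "decimalLongitude", "decimalLatitude", "source"]
        )
    rng = _rng(scenario, 1)
    west, south, east, north = scenario.domain_bbox
    span = min(east - west, north - south)

    # Species centers are drawn from a mixture of hotspots and a uniform
    # background. Each hotspot's attraction is its intensity against a
    # fixed background weight, so an intensity-10 hotspot concentrates a
    # substantial minority of (narrow-ranged) species regardless of its
    # footprint — the mechanism that plants richness *and* endemism.
    background_weight = 30.0
    w = np.array([h.intensity for h in scenario.hotspot_centers] + [background_weight])
    weights = w / w.sum()
    choices = list(range(len(scenario.hotspot_centers))) + [-1]

    rows = []
    for i in range(scenario.n_species):
        name = f"Species_{i:04d}"
        which = int(rng.choice(choices, p=weights))
        radius = scenario.range_scale * (1.0 + rng.pareto(scenario.range_shape))
        radius = min(radius, span / 2)
        if which >= 0:
            h = scenario.hotspot_centers[which]
            clon, clat = _sample_in_disk(rng, h.lon, h.lat, h.radius / 3, 1)
            center = (float(clon[0]), float(clat[0]))
            # hotspot endemics get ranges about one analysis cell wide
            radius = min(radius, scenario.endemic_radius)
        else:
            center = (rng.uniform(west, east), rng.uniform(south, north))
        n_pts = int(rng.integers(scenario.n_points_min, scenario.n_points_max + 1))
        lons, lats = _uniform_disk_points(rng, center, radius, n_pts, scenario.domain_bbox)
        src = rng.choice(SOURCES, size=n_pts, p=SOURCE_PROBS)
        for lon, lat, s in zip(lons, lats, src):
            rows.append((name, float(lon), float(lat), str(s)))
        # oversample points inside hotspot circles by the multiplier
        for h in scenario.hotspot_centers:
            d2 = (lons - h.lon) ** 2 + (lats - h.lat) ** 2
            inside = d2 <= h.radius**2
            extra_per_point = max(0, int(round(h.intensity)) - 1)
            n_in = int(inside.sum())
            if extra_per_point == 0 or n_in == 0:
                continue
            n_extra = n_in * extra_per_point
            jx, jy = _sample_in_disk(rng, 0.0, 0.0, h.radius / 8, n_extra)
            xs = np.clip(np.repeat(lons[inside], extra_per_point) + jx, west, east)
            ys = np.clip(np.repeat(lats[inside], extra_per_point) + jy, south, north)
            xsrc = rng.choice(SOURCES, size=n_extra, p=SOURCE_PROBS)
            for lon, lat, s in zip(xs, ys, xsrc):
                rows.append((name, float(lon), float(lat), str(s)))

    df = pd.DataFrame(
        rows, columns=["species", "decimalLongitude", "decimalLatitude", "source"]
    )

    # dirty rows: one third each out-of-bounds, duplicates, blank names
    n_dirty = int(round(scenario.dirty_fraction * len(df)))
    if n_dirty:
        n_oob = n_dirty // 3
        n_dup = n_dirty // 3
        n_blank = n_dirty - n_oob - n_dup
        dirty = []
        for _ in range(n_oob):
            j = int(rng.integers(len(df)))
            r = df.iloc[j]
            dirty.append(
                (r["species"], r["decimalLongitude"] + (east - west) + 1.0,
                 r["decimalLatitude"], r["source"])
            )
        for _ in range(n_dup):
            j = int(rng.integers(len(df)))
            r = df.iloc[j]
            dirty.append(tuple(r[c] for c in df.columns))
        for _ in range(n_blank):
            lon = rng.uniform(west, east)
            lat = rng.uniform(south, north)
            dirty.append(("", float(lon), float(lat), "database"))
        df = pd.concat([df, pd.DataFrame(dirty, columns=df.columns)], ignore_index=True)
    return df


def generate_landscape_polygons(scenario: SyntheticScenario) -> BaseGeometry:
    """Patchy karst layer as a union of random disks clipped to the
    domain, covering approximately ``karst_fraction`` of its area
    (within about +-20% relative for fractions away from the ends)."""
    frac = scenario.karst_fraction
    domain = scenario.domain_polygon
    if frac == 0:
        return shapely.geometry.MultiPolygon()
    if frac == 1:
        return domain
    rng = _rng(scenario, 2)
    west, south, east, north = scenario.domain_bbox
    span = min(east - west, north - south)
    target = frac * scenario.domain_area
    # disk radii small relative to the remaining deficit, so the union
    # area lands close to the target without overshooting
    r_hi = min(0.08 * span, math.sqrt(0.15 * target / math.pi))
    r_lo = r_hi / 2
    union: BaseGeometry = shapely.geometry.MultiPolygon()
    for _ in range(5000):
        if union.area >= target:
            break
        r = rng.uniform(r_lo, r_hi)
        cx = rng.uniform(west, east)
        cy = rng.uniform(south, north)
        disk = Point(cx, cy).buffer(r, quad_segs=16).intersection(domain)
        union = union.union(disk)
    return shapely.make_valid(union)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_protected_areas(
    scenario: SyntheticScenario,
    planted_hotspot_cells: set[Cell] | frozenset[Cell],
    grid: GridSpec,
) -> list[BaseGeometry]:
    """Protected-area polygons covering a controlled share of the
    planted hotspot cells.

    Exactly ``round_half_up(pa_coverage * n_planted)`` planted cells are
    fully covered (each PA polygon is the cell rectangle itself, so
    neighbouring planted cells receive zero area overlap); the rest are
    left untouched and become known gap areas downstream.
    """
    if not 0 <= scenario.pa_coverage <= 1:
        raise ValueError("pa_coverage must lie in [0, 1]")
    cells = sorted(planted_hotspot_cells)
    if scenario.pa_coverage > 0 and not cells:
        raise ValueError("planted_hotspot_cells is empty but pa_coverage > 0")
    n_cover = _round_half_up(scenario.pa_coverage * len(cells))
    if n_cover == 0:
        return []
    rng = _rng(scenario, 3)
    chosen_idx = rng.choice(len(cells), size=n_cover, replace=False)
    return [box(*grid.cell_bounds(cells[i])) for i in sorted(chosen_idx)]


def generate_env_rasters(
    scenario: SyntheticScenario,
    karst_polygons: BaseGeometry,
    resolution: float = 1 / 60.0,
    layers: list[str] | None = None,
) -> dict[str, Raster]:
    """Environmental layers: smooth gradient + noise, with a karst
    mean shift of ``env_separation`` noise-SDs when requested.

    Each layer is a linear trend plus a low-frequency sinusoid (the
    "smooth spatial gradient") plus i.i.d. Gaussian noise, all on the
    layer's own scale from :data:`DEFAULT_LAYERS`. Pixels whose center
    lies in the karst union get ``env_separation * noise_SD`` added, so
    the planted standardized karst/non-karst mean difference equals
    ``env_separation``.
    """
    names = list(DEFAULT_LAYERS) if layers is None else list(layers)
    unknown = [n for n in names if n not in DEFAULT_LAYERS]
    if unknown:
        raise ValueError(f"unknown layer name(s): {unknown}")
    west, south, east, north = scenario.domain_bbox
    n_cols = int(round((east - west) / resolution))
    n_rows = int(round((north - south) / resolution))
    lon = west + (np.arange(n_cols) + 0.5) * resolution
    lat = north - (np.arange(n_rows) + 0.5) * resolution
    X, Y = np.meshgrid(lon, lat)
    xn = (X - west) / (east - west)
    yn = (Y - south) / (north - south)

    if karst_polygons is None or karst_polygons.is_empty:
        mask = np.zeros_like(X, dtype=bool)
    else:
        shapely.prepare(karst_polygons)
        mask = shapely.covers(
            karst_polygons, shapely.points(X.ravel(), Y.ravel())
        ).reshape(X.shape)

    out: dict[str, Raster] = {}
    for k, name in enumerate(names):
        mean, sd, grad_amp = DEFAULT_LAYERS[name]
        rng = _rng(scenario, 100 + k)
        a, b = rng.uniform(-1, 1, 2)
        fx, fy = rng.uniform(0.5, 1.5, 2)
        phase = rng.uniform(0, 2 * math.pi)
        trend = a * xn + b * yn + 0.5 * np.sin(2 * math.pi * (fx * xn + fy * yn) + phase)
        data = mean + grad_amp * sd * trend + rng.normal(0.0, sd, X.shape)
        if scenario.env_separation != 0:
            # shift karst pixels by the effect size in units of the
            # realized field SD, so the planted standardized mean
            # difference equals env_separation as measured on pixels
            data = data + scenario.env_separation * data.std() * mask
        out[name] = Raster(data=data, west=west, south=south, cell_size=resolution)
    return out
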