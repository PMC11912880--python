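"""Hotspot selection, three-metric congruence and conservation gaps.

Hotspots are the top X% of occupied grid cells ranked by a diversity
index (X in {10, 20, 30, 50} by convention). Congruent hotspots are
cells in the top set of all three indices (SR, WE, CWE) at one
threshold. The gap analysis partitions congruent cells into
"protected" (the cell polygon overlaps the protected-area union) and
"gap" (it does not), and reports areas on a spherical Earth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .grid import Cell, GridSpec

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

METRICS = ("SR", "WE", "CWE")
DEFAULT_THRESHOLDS = (10, 20, 30, 50)


@dataclass(frozen=True)
class HotspotSet:
    """Top-percentile cells for one metric at one threshold."""

    metric: str
    threshold: float  # percent of occupied cells
    cells: frozenset[Cell]


def select_hotspots(
    table: pd.DataFrame, metric: str, threshold_percent: float
) -> HotspotSet:
    """Cells in the top ``threshold_percent``% of ``table`` by ``metric``.

    Cells are ranked descending; the top ceil(threshold/100 * n) are
    selected, and any cell tied with the cut-off value is also included
    (so the set can exceed the nominal size but never depends on sort
    order).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not 0 < threshold_percent <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if table.empty:
        raise ValueError("empty diversity table")
    values = table[metric].to_numpy(dtype=float)
    n_top = math.ceil(threshold_percent / 100.0 * len(table))
    cutoff = sorted(values, reverse=True)[n_top - 1]
    sel = table[table[metric] >= cutoff]
    cells = frozenset(zip(sel["col"].astype(int), sel["row"].astype(int)))
    return HotspotSet(metric=metric, threshold=threshold_percent, cells=cells)


def congruent_hotspots(*sets: HotspotSet) -> frozenset[Cell]:
    """Intersection of per-metric hotspot sets at one threshold."""
    if not sets:
        raise ValueError("need at least one hotspot set")
    thresholds = {s.threshold for s in sets}
    if len(thresholds) != 1:
        raise ValueError(f"mismatched thresholds: {sorted(thresholds)}")
    out = set(sets[0].cells)
    for s in sets[1:]:
        out &= s.cells
    return frozenset(out)


def cell_area_km2(cell: Cell, grid: GridSpec) -> float:
    """Spherical-Earth area of a grid cell in square kilometres.

    A = R^2 * d_lambda * (sin(phi_top) - sin(phi_bottom)), angles in
    radians.
    """
    west, south, east, north = grid.cell_bounds(cell)
    dlam = math.radians(east - west)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (math.sin(math.radians(north)) - math.sin(math.radians(south)))
    )


@dataclass
class GapReport:
    """Protected / gap partition of the congruent hotspot cells."""

    congruent: frozenset[Cell]
    protected: frozenset[Cell]
    gap: frozenset[Cell]
    cell_areas_km2: dict[Cell, float]
    tau: float

    @property
    def total_area_km2(self) -> float:
        return sum(self.cell_areas_km2.values())

    @property
    def protected_area_km2(self) -> float:
        return sum(self.cell_areas_km2[c] for c in self.protected)

    @property
    def gap_area_km2(self) -> float:
        return sum(self.cell_areas_km2[c] for c in self.gap)

    def as_frame(self, grid: GridSpec) -> pd.DataFrame:
        cells = sorted(self.congruent)
        centers = [grid.cell_center(c) for c in cells]
        return pd.DataFrame(
            {
                "col": [c[0] for c in cells],
                "row": [c[1] for c in cells],
                "center_lon": [c[0] for c in centers],
                "center_lat": [c[1] for c in centers],
                "status": [
                    "protected" if c in self.protected else "gap" for c in cells
                ],
                "area_km2": [self.cell_areas_km2[c] for c in cells],
            }
        )


def gap_partition(
    congruent: frozenset[Cell] | set[Cell],
    pa_polygons: BaseGeometry | list[BaseGeometry] | None,
    grid: GridSpec,
    tau: float = 0.0,
) -> GapReport:
    """Split congruent hotspot cells into protected vs gap.

    A cell is protected when the fraction of its polygon's area covered
    by the protected-area union is ``> tau`` (default ``tau = 0``: any
    positive overlap protects). Cells failing the criterion are gap
    areas. Areas are reported with :func:`cell_area_km2`.
    """
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    if pa_polygons is None:
        pa_union: BaseGeometry = shapely.geometry.GeometryCollection()
    elif isinstance(pa_polygons, BaseGeometry):
        pa_union = pa_polygons
    else:
        for i, p in enumerate(pa_polygons):
            if not p.is_valid:
                raise ValueError(f"invalid protected-area polygon at index {i}")
        pa_union = shapely.union_all(list(pa_polygons))
    if not pa_union.is_valid:
        raise ValueError("invalid protected-area geometry")

    protected, gap = set(), set()
    for cell in congruent:
        if not grid.contains_cell(cell):
            raise ValueError(f"cell {cell} outside grid")
        poly = box(*grid.cell_bounds(cell))
        frac = 0.0
        if not pa_union.is_empty:
            frac = poly.intersection(pa_union).area / poly.area
        (protected if frac > tau else gap).add(cell)
    areas = {c: cell_area_km2(c, grid) for c in congruent}
    return GapReport(
        congruent=frozenset(congruent),
        protected=frozenset(protected),
        gap=frozenset(gap),
        cell_areas_km2=areas,
        tau=tau,
    )
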