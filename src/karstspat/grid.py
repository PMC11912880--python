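"""Gridded diversity indices: species richness, weighted endemism, CWE.

Occurrences are binned onto a regular lon/lat lattice (default 0.083333
degrees, i.e. 5 arc-minutes) and three per-cell indices are computed:

* SR  — species richness, the number of distinct species in the cell;
* WE  — weighted endemism (range-size rarity), the sum over species
  present of 1 / C_s where C_s is the number of cells the species
  occupies;
* CWE — corrected weighted endemism, WE / SR, which removes the
  richness trend and isolates range restriction.

Pairwise Pearson correlations between the three indices are classified
on the conventional |r| bands (negligible < 0.1 <= weak < 0.4 <=
moderate < 0.7 <= strong < 0.9 <= very strong).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

Cell = tuple[int, int]

DEFAULT_CELL_SIZE = 0.083333  # degrees; 5 arcmin

CORRELATION_CLASSES = (
    (0.1, "negligible"),
    (0.4, "weak"),
    (0.7, "moderate"),
    (0.9, "strong"),
)


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat analysis lattice.

    Cells are indexed ``(col, row)`` from the origin (south-west corner)
    with half-open edges: a point on an interior edge belongs to the
    higher-index cell.
    """

    origin_lon: float
    origin_lat: float
    n_cols: int
    n_rows: int
    cell_size: float = DEFAULT_CELL_SIZE

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid must have positive dimensions")

    @classmethod
    def from_bbox(cls, bbox, cell_size: float = DEFAULT_CELL_SIZE) -> "GridSpec":
        """Smallest grid covering ``bbox`` whose origin lies on whole
        cell multiples from (0, 0) — reproducible without an arbitrary
        anchor."""
        west, south, east, north = bbox
        if east <= west or north <= south:
            raise ValueError("empty bbox")
        origin_lon = math.floor(west / cell_size) * cell_size
        origin_lat = math.floor(south / cell_size) * cell_size
        n_cols = int(math.ceil((east - origin_lon) / cell_size))
        n_rows = int(math.ceil((north - origin_lat) / cell_size))
        return cls(origin_lon, origin_lat, n_cols, n_rows, cell_size)

    def cell_of(self, lon: float, lat: float) -> Cell:
        col = int(math.floor((lon - self.origin_lon) / self.cell_size))
        row = int(math.floor((lat - self.origin_lat) / self.cell_size))
        return (col, row)

    def cells_of(self, lons, lats) -> np.ndarray:
        """Vectorised ``cell_of``; returns an (n, 2) int array."""
        cols = np.floor((np.asarray(lons) - self.origin_lon) / self.cell_size)
        rows = np.floor((np.asarray(lats) - self.origin_lat) / self.cell_size)
        return np.stack([cols, rows], axis=1).astype(int)

    def contains_cell(self, cell: Cell) -> bool:
        col, row = cell
        return 0 <= col < self.n_cols and 0 <= row < self.n_rows

    def cell_bounds(self, cell: Cell) -> tuple[float, float, float, float]:
        col, row = cell
        west = self.origin_lon + col * self.cell_size
        south = self.origin_lat + row * self.cell_size
        return (west, south, west + self.cell_size, south + self.cell_size)

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        west, south, east, north = self.cell_bounds(cell)
        return ((west + east) / 2.0, (south + north) / 2.0)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_lon,
            self.origin_lat,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat + self.n_rows * self.cell_size,
        )


@dataclass
class CellAssignment:
    """Presence/absence views of a gridded occurrence set.

    ``species_cells`` and ``cell_species`` are transposes of each other.
    """

    species_cells: dict[str, set[Cell]]
    cell_species: dict[Cell, set[str]]

    @property
    def n_species(self) -> int:
        return len(self.species_cells)

    @property
    def occupied_cells(self) -> set[Cell]:
        return set(self.cell_species)

    def range_sizes(self) -> dict[str, int]:
        """Cells occupied per species (C_s)."""
        return {sp: len(cells) for sp, cells in self.species_cells.items()}


def assign_to_grid(records: pd.DataFrame, grid: GridSpec) -> CellAssignment:
    """Map tagged occurrence records onto grid cells.

    Every record must fall inside the grid extent; offenders are listed
    in the raised error. Repeated records of a species in one cell
    collapse to a single presence.
    """
    if records.empty:
        return CellAssignment({}, {})
    cells = grid.cells_of(
        records["decimalLongitude"].to_numpy(), records["decimalLatitude"].to_numpy()
    )
    bad = (
        (cells[:, 0] < 0)
        | (cells[:, 0] >= grid.n_cols)
        | (cells[:, 1] < 0)
        | (cells[:, 1] >= grid.n_rows)
    )
    if bad.any():
        offenders = records.loc[bad, ["species", "decimalLongitude", "decimalLatitude"]]
        raise ValueError(
            f"{bad.sum()} record(s) outside grid extent:\n{offenders.head(10)}"
        )
    species_cells: dict[str, set[Cell]] = {}
    cell_species: dict[Cell, set[str]] = {}
    for sp, col, row in zip(records["species"], cells[:, 0], cells[:, 1]):
        cell = (int(col), int(row))
        species_cells.setdefault(sp, set()).add(cell)
        cell_species.setdefault(cell, set()).add(sp)
    return CellAssignment(species_cells, cell_species)


def compute_richness(assignment: CellAssignment) -> dict[Cell, int]:
    """SR(cell) = number of distinct species present."""
    return {cell: len(sps) for cell, sps in assignment.cell_species.items()}


def compute_weighted_endemism(
    assignment: CellAssignment,
    range_sizes: Mapping[str, int] | None = None,
) -> dict[Cell, float]:
    """WE(cell) = sum over present species of 1 / C_s.

    ``range_sizes`` overrides the per-species cell counts; pass counts
    from a whole-dataset assignment to weight by global range size
    instead of range within the analysed subset.
    """
    if range_sizes is None:
        range_sizes = assignment.range_sizes()
    we: dict[Cell, float] = {}
    for cell, sps in assignment.cell_species.items():
        we[cell] = sum(1.0 / range_sizes[sp] for sp in sps)
    return we


def compute_cwe(
    sr: Mapping[Cell, int], we: Mapping[Cell, float]
) -> dict[Cell, float]:
    """CWE(cell) = WE(cell) / SR(cell); requires identical cell sets."""
    if set(sr) != set(we):
        raise ValueError("SR and WE are defined on different cell sets")
    return {cell: we[cell] / sr[cell] for cell in sr}


def diversity_table(
    records: pd.DataFrame,
    grid: GridSpec,
    landscape: str | None = None,
    range_scope: str = "subset",
) -> pd.DataFrame:
    """Per-cell SR/WE/CWE table for one landscape subset.

    Parameters
    ----------
    records : tagged occurrences (needs a ``landscape`` column when a
        subset is requested).
    landscape : ``"KL"``, ``"NKL"`` or None for all records.
    range_scope : ``"subset"`` computes each species' range size within
        the selected subset; ``"global"`` computes it over all records.

    Returns a DataFrame with columns ``col, row, center_lon, center_lat,
    SR, WE, CWE`` (one row per occupied cell) and the landscape label in
    ``.attrs["landscape"]``.
    """
    if range_scope not in ("subset", "global"):
        raise ValueError(f"unknown range_scope: {range_scope!r}")
    subset = records if landscape is None else records[records["landscape"] == landscape]
    assignment = assign_to_grid(subset, grid)
    range_sizes = None
    if range_scope == "global":
        range_sizes = assign_to_grid(records, grid).range_sizes()
    sr = compute_richness(assignment)
    we = compute_weighted_endemism(assignment, range_sizes)
    cwe = compute_cwe(sr, we)
    cells = sorted(sr)
    centers = [grid.cell_center(c) for c in cells]
    table = pd.DataFrame(
        {
            "col": [c[0] for c in cells],
            "row": [c[1] for c in cells],
            "center_lon": [c[0] for c in centers],
            "center_lat": [c[1] for c in centers],
            "SR": [sr[c] for c in cells],
            "WE": [we[c] for c in cells],
            "CWE": [cwe[c] for c in cells],
        }
    )
    table.attrs["landscape"] = landscape or "all"
    table.attrs["range_scope"] = range_scope
    return table


def classify_correlation(r: float) -> str:
    """Label |r| on the conventional five-band scale.

    Bands: negligible [0, 0.1), weak [0.1, 0.4), moderate [0.4, 0.7),
    strong [0.7, 0.9), very strong [0.9, 1.0]. |r| = 1 is classed very
    strong.
    """
    a = abs(r)
    if a > 1 or math.isnan(a):
        raise ValueError(f"|r| must be <= 1, got {r}")
    for bound, label in CORRELATION_CLASSES:
        if a < bound:
            return label
    return "very strong"


def index_correlations(table: pd.DataFrame) -> dict[str, tuple[float, str]]:
    """Pairwise Pearson r between SR, WE and CWE over cells.

    Returns ``{"SR~WE": (r, class), ...}``. A zero-variance index makes
    r undefined; the pair is reported as ``(nan, "undefined")``.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 cells to correlate indices")
    out: dict[str, tuple[float, str]] = {}
    for a, b in (("SR", "WE"), ("SR", "CWE"), ("WE", "CWE")):
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[f"{a}~{b}"] = (float("nan"), "undefined")
            continue
        r = float(stats.pearsonr(x, y).statistic)
        r = max(-1.0, min(1.0, r))  # guard rounding past +-1
        out[f"{a}~{b}"] = (r, classify_correlation(r))
    return out
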