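"""Occurrence-record cleaning, spatial thinning and landscape tagging.

Raw occurrence tables use Darwin-Core-aligned columns: ``species``,
``decimalLongitude``, ``decimalLatitude``, ``source`` (field /
herbarium / database / literature). Cleaning applies, in order:
coordinate parsing, optional per-row coordinate corrections, a study
bounding box, species-name resolution through a synonym map, and exact
duplicate removal. Each rule logs how many rows it removed.

Thinning keeps at most one record per species per pixel (default 30
arc-seconds, about 1 km at the equator), with pixels anchored at
(0, 0) so the rule has no free origin parameter. Tagging assigns each
point to the karst landscape (KL) when it lies inside or on the
boundary of the karst polygon union, otherwise non-karst (NKL).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

REQUIRED_COLUMNS = ("species", "decimalLongitude", "decimalLatitude")

#: tie-break priority when thinning: GPS field points are the most
#: precise, then physical vouchers, then database and literature rows.
SOURCE_PRIORITY = {"field": 0, "herbarium": 1, "database": 2, "literature": 3}

DEFAULT_PIXEL_SIZE = 0.0083333  # degrees; 30 arcsec, ~1 km at the equator

KL = "KL"
NKL = "NKL"


@dataclass
class SynonymMap:
    """Name-variant resolution: variant -> accepted name, plus a set of
    names flagged for exclusion (unplaced, no formal record)."""

    mapping: dict[str, str] = dc_field(default_factory=dict)
    excluded: set[str] = dc_field(default_factory=set)

    def __post_init__(self) -> None:
        clash = set(self.mapping) & self.excluded
        if clash:
            raise ValueError(f"names both mapped and excluded: {sorted(clash)[:5]}")

    def resolve(self, name: str) -> str | None:
        """Accepted name for ``name``, or None when excluded."""
        if name in self.excluded:
            return None
        return self.mapping.get(name, name)

    @classmethod
    def from_csv(cls, path) -> "SynonymMap":
        """Two-column delimited file ``variant,accepted``; an empty
        accepted field flags the variant as excluded."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        variant_col, accepted_col = df.columns[:2]
        mapping, excluded = {}, set()
        for variant, accepted in zip(df[variant_col], df[accepted_col]):
            if accepted.strip() == "":
                excluded.add(variant)
            else:
                mapping[variant] = accepted
        return cls(mapping, excluded)


@dataclass
class CleaningLog:
    """Per-rule removal counts from one cleaning pass."""

    n_input: int = 0
    malformed_coordinates: int = 0
    corrected_coordinates: int = 0
    out_of_bounds: int = 0
    blank_species: int = 0
    excluded_species: int = 0
    duplicates: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.malformed_coordinates
            + self.out_of_bounds
            + self.blank_species
            + self.excluded_species
            + self.duplicates
        )

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "malformed_coordinates": self.malformed_coordinates,
            "corrected_coordinates": self.corrected_coordinates,
            "out_of_bounds": self.out_of_bounds,
            "blank_species": self.blank_species,
            "excluded_species": self.excluded_species,
            "duplicates": self.duplicates,
            "n_output": self.n_output,
        }


def clean_records(
    raw: pd.DataFrame,
    bbox: tuple[float, float, float, float],
    synonyms: SynonymMap | None = None,
    corrections: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CleaningLog]:
    """Multi-step occurrence cleaning.

    Parameters
    ----------
    raw : table with at least the Darwin-Core columns ``species``,
        ``decimalLongitude``, ``decimalLatitude``.
    bbox : (west, south, east, north) study bounds; records outside are
        removed (bounds inclusive).
    synonyms : optional name resolution; excluded names are removed.
    corrections : optional per-row coordinate reassignments with
        columns ``row_id, new_lon, new_lat`` (``row_id`` indexes
        ``raw``); stands in for manual voucher-label georeferencing.

    Returns the cleaned table (original row order, fresh index) and a
    :class:`CleaningLog`. Non-numeric coordinates are routed to the log
    rather than raising.
    """
    west, south, east, north = bbox
    if east <= west or north <= south:
        raise ValueError("empty bbox")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    log = CleaningLog(n_input=len(raw))
    df = raw.copy()
    df["decimalLongitude"] = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    df["decimalLatitude"] = pd.to_numeric(df["decimalLatitude"], errors="coerce")

    if corrections is not None and len(corrections):
        ids = corrections["row_id"].to_numpy()
        valid = df.index.intersection(pd.Index(ids))
        cor = corrections.set_index("row_id").loc[valid]
        df.loc[valid, "decimalLongitude"] = cor["new_lon"].to_numpy(dtype=float)
        df.loc[valid, "decimalLatitude"] = cor["new_lat"].to_numpy(dtype=float)
        log.corrected_coordinates = int(len(valid))

    malformed = df["decimalLongitude"].isna() | df["decimalLatitude"].isna()
    log.malformed_coordinates = int(malformed.sum())
    df = df[~malformed]

    inside = (
        df["decimalLongitude"].between(west, east)
        & df["decimalLatitude"].between(south, north)
    )
    log.out_of_bounds = int((~inside).sum())
    df = df[inside]

    species = df["species"].astype(str).str.strip()
    blank = (species == "") | species.isin(("nan", "None"))
    log.blank_species = int(blank.sum())
    df = df[~blank]
    species = species[~blank]

    if synonyms is not None:
        resolved = species.map(synonyms.resolve)
        dropped = resolved.isna()
        log.excluded_species = int(dropped.sum())
        df = df[~dropped].assign(species=resolved[~dropped])
    else:
        df = df.assign(species=species)

    before = len(df)
    df = df.drop_duplicates(
        subset=["species", "decimalLongitude", "decimalLatitude"], keep="first"
    )
    log.duplicates = before - len(df)

    return df.reset_index(drop=True), log


def thin_records(
    records: pd.DataFrame, pixel_size: float = DEFAULT_PIXEL_SIZE
) -> pd.DataFrame:
    """Keep one record per species per pixel.

    Pixels are fixed lon/lat cells of edge ``pixel_size`` anchored at
    (0, 0). Within a (species, pixel) group the surviving record is
    deterministic: rows are ordered by source precision (field >
    herbarium > database > literature) then original position, and the
    first is kept. Output size equals the number of distinct
    (species, pixel) pairs; thinning is idempotent.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if records.empty:
        return records.copy()
    df = records.reset_index(drop=True).copy()
    px = np.floor(df["decimalLongitude"].to_numpy() / pixel_size).astype(int)
    py = np.floor(df["decimalLatitude"].to_numpy() / pixel_size).astype(int)
    df["_px"], df["_py"] = px, py
    if "source" in df.columns:
        prio = df["source"].map(SOURCE_PRIORITY).fillna(len(SOURCE_PRIORITY))
    else:
        prio = pd.Series(0, index=df.index)
    df["_prio"] = prio
    df["_pos"] = np.arange(len(df))
    df = df.sort_values(["species", "_prio", "_pos"], kind="stable")
    df = df.drop_duplicates(subset=["species", "_px", "_py"], keep="first")
    df = df.sort_values("_pos")
    return df.drop(columns=["_px", "_py", "_prio", "_pos"]).reset_index(drop=True)


def tag_landscape(
    records: pd.DataFrame, karst_polygons: BaseGeometry
) -> pd.DataFrame:
    """Tag each record KL or NKL by point-in-polygon against the karst
    layer; boundary points count as KL (inclusive convention)."""
    if karst_polygons is not None and not karst_polygons.is_valid:
        raise ValueError(f"invalid karst geometry: {shapely.is_valid_reason(karst_polygons)}")
    df = records.copy()
    if karst_polygons is None or karst_polygons.is_empty:
        df["landscape"] = NKL
        return df
    pts = shapely.points(
        df["decimalLongitude"].to_numpy(), df["decimalLatitude"].to_numpy()
    )
    shapely.prepare(karst_polygons)
    inside = shapely.covers(karst_polygons, pts)
    df["landscape"] = np.where(inside, KL, NKL)
    return df


@dataclass
class PartitionSummary:
    """Distinct-species counts per landscape class.

    A species seen in both landscapes counts in both ``n_kl`` and
    ``n_nkl``; percentages are of ``n_total_species``, rounded half-up
    to two decimals.
    """

    n_total_species: int
    n_kl: int
    n_nkl: int
    n_kl_only: int
    n_nkl_only: int

    @property
    def n_both(self) -> int:
        return self.n_kl + self.n_nkl - self.n_total_species

    def _pct(self, count: int) -> float:
        if self.n_total_species == 0:
            return 0.0
        raw = Decimal(count) / Decimal(self.n_total_species) * 100
        return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def pct_kl(self) -> float:
        return self._pct(self.n_kl)

    @property
    def pct_nkl(self) -> float:
        return self._pct(self.n_nkl)

    @property
    def pct_kl_only(self) -> float:
        return self._pct(self.n_kl_only)

    @property
    def pct_nkl_only(self) -> float:
        return self._pct(self.n_nkl_only)

    def as_dict(self) -> dict[str, float]:
        return {
            "n_total_species": self.n_total_species,
            "n_kl": self.n_kl,
            "n_nkl": self.n_nkl,
            "n_kl_only": self.n_kl_only,
            "n_nkl_only": self.n_nkl_only,
            "pct_kl": self.pct_kl,
            "pct_nkl": self.pct_nkl,
            "pct_kl_only": self.pct_kl_only,
            "pct_nkl_only": self.pct_nkl_only,
        }


def summarize_partition(records: pd.DataFrame) -> PartitionSummary:
    """Species-level KL/NKL partition of a tagged occurrence table."""
    if records.empty:
        return PartitionSummary(0, 0, 0, 0, 0)
    if "landscape" not in records.columns:
        raise ValueError("records must be landscape-tagged first")
    kl_species = set(records.loc[records["landscape"] == KL, "species"])
    nkl_species = set(records.loc[records["landscape"] == NKL, "species"])
    total = kl_species | nkl_species
    return PartitionSummary(
        n_total_species=len(total),
        n_kl=len(kl_species),
        n_nkl=len(nkl_species),
        n_kl_only=len(kl_species - nkl_species),
        n_nkl_only=len(nkl_species - kl_species),
    )
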