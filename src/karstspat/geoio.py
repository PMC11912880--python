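"""File I/O: Darwin-Core-style occurrence tables, GeoJSON vectors,
ESRI ASCII rasters (via :mod:`karstspat.rasters`)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .rasters import Raster


def read_occurrences(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited occurrence table; coordinates stay as-parsed
    (cleaning handles malformed values)."""
    return pd.read_csv(path, sep=sep, dtype={"species": str}, keep_default_na=False)


def write_occurrences(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_polygons(path) -> BaseGeometry:
    """Union of all (multi)polygon features in a GeoJSON file."""
    with Path(path).open() as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    return shapely.union_all(geoms)


def write_polygons(geoms, path, properties: list[dict] | None = None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    if isinstance(geoms, BaseGeometry):
        geoms = [geoms]
    feats = []
    for i, g in enumerate(geoms):
        props = properties[i] if properties else {}
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(g)}
        )
    with Path(path).open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_raster_dir(path, pattern: str = "*.asc") -> dict[str, Raster]:
    """Load every ASCII-grid raster in a directory, keyed by stem."""
    out = {}
    for p in sorted(Path(path).glob(pattern)):
        out[p.stem] = Raster.from_ascii(p)
    if not out:
        raise FileNotFoundError(f"no {pattern} rasters under {path}")
    return out
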