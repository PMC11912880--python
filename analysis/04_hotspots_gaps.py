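"""Identify top-percentile hotspot cells per index, intersect the three
indices into congruent hotspots at the 50% threshold, and partition
them into protected vs gap cells against the protected-area layer.

Writes gaps_KL.csv / gaps_NKL.csv and prints the hotspot accounting.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd
import shapely

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from karstspat import geoio
from karstspat.grid import GridSpec
from karstspat.hotspots import METRICS, congruent_hotspots, gap_partition, select_hotspots
from karstspat.pipeline import default_scenario

cfg = cfg_mod.CONFIG
grid = GridSpec.from_bbox(default_scenario(cfg).domain_bbox, cfg.cell_size)
pas = geoio.read_polygons(cfg_mod.OUTDIR / "data" / "protected_areas.geojson")

for landscape in ("KL", "NKL"):
    table = pd.read_csv(cfg_mod.OUTDIR / f"diversity_{landscape}.csv")
    for t in cfg.thresholds:
        sizes = {m: len(select_hotspots(table, m, t).cells) for m in METRICS}
        print(f"{landscape} top {t}%: " +
              ", ".join(f"{m} {n} cells" for m, n in sizes.items()))
    sets = [select_hotspots(table, m, cfg.congruence_threshold) for m in METRICS]
    congruent = congruent_hotspots(*sets)
    report = gap_partition(congruent, pas, grid, cfg.tau)
    report.as_frame(grid).to_csv(cfg_mod.OUTDIR / f"gaps_{landscape}.csv", index=False)
    print(f"{landscape} congruent hotspots at {cfg.congruence_threshold}%: "
          f"{len(report.congruent)} cells covering "
          f"{report.total_area_km2:,.1f} km2 -> {len(report.protected)} protected, "
          f"{len(report.gap)} gap ({report.gap_area_km2:,.1f} km2 unprotected)")
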