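"""Generate the synthetic study system: occurrences with planted
hotspots, a patchy karst layer, protected areas over half the planted
cells, and environmental rasters.

Writes occurrences_raw.csv, karst.geojson, protected_areas.geojson and
rasters/*.asc under results/analysis/data.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from karstspat import geoio
from karstspat.grid import GridSpec
from karstspat.pipeline import default_scenario
from karstspat.synthetic import (
    generate_env_rasters,
    generate_landscape_polygons,
    generate_occurrences,
    generate_protected_areas,
)

scenario = default_scenario(cfg_mod.CONFIG)
datadir = cfg_mod.OUTDIR / "data"
datadir.mkdir(parents=True, exist_ok=True)

occ = generate_occurrences(scenario)
geoio.write_occurrences(occ, datadir / "occurrences_raw.csv")

karst = generate_landscape_polygons(scenario)
geoio.write_polygons(karst, datadir / "karst.geojson")

grid = GridSpec.from_bbox(scenario.domain_bbox, cfg_mod.CONFIG.cell_size)
planted = scenario.planted_cells(grid)
pas = generate_protected_areas(scenario, planted, grid)
geoio.write_polygons(pas, datadir / "protected_areas.geojson")

rasterdir = datadir / "rasters"
rasterdir.mkdir(exist_ok=True)
for name, raster in generate_env_rasters(scenario, karst).items():
    raster.to_ascii(rasterdir / f"{name}.asc")

print(f"scenario seed {scenario.seed}: {len(occ)} raw occurrence rows, "
      f"{scenario.n_species} species")
print(f"karst covers {karst.area / scenario.domain_area:.1%} of the domain "
      f"(target {scenario.karst_fraction:.0%})")
print(f"{len(planted)} planted hotspot cells, {len(pas)} under protection")
print(f"data written to {datadir}")
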