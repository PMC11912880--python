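"""Clean, spatially thin and landscape-tag the raw occurrence records,
then summarise the species partition between karst (KL) and non-karst
(NKL) landscapes.

Reads results/analysis/data; writes occurrences_clean.csv,
cleaning_log.json and partition.json under results/analysis.
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from karstspat import geoio
from karstspat.occurrences import clean_records, summarize_partition, tag_landscape, thin_records

cfg = cfg_mod.CONFIG
datadir = cfg_mod.OUTDIR / "data"
raw = geoio.read_occurrences(datadir / "occurrences_raw.csv")
karst = geoio.read_polygons(datadir / "karst.geojson")

from karstspat.pipeline import default_scenario

bbox = default_scenario(cfg).domain_bbox
cleaned, log = clean_records(raw, bbox)
print(f"cleaning: {log.n_input} rows in, {log.n_output} out "
      f"({log.out_of_bounds} out-of-bounds, {log.blank_species} blank names, "
      f"{log.duplicates} duplicates, {log.malformed_coordinates} malformed)")

thinned = thin_records(cleaned, cfg.pixel_size)
print(f"thinning at {cfg.pixel_size:.7f} deg: {len(cleaned)} -> {len(thinned)} records")

tagged = tag_landscape(thinned, karst)
geoio.write_occurrences(tagged, cfg_mod.OUTDIR / "occurrences_clean.csv")

s = summarize_partition(tagged)
print(f"{s.n_total_species} species total: {s.n_kl} in KL ({s.pct_kl}%), "
      f"{s.n_nkl} in NKL ({s.pct_nkl}%), {s.n_kl_only} KL-exclusive "
      f"({s.pct_kl_only}%)")

(cfg_mod.OUTDIR / "cleaning_log.json").write_text(json.dumps(log.as_dict(), indent=2))
(cfg_mod.OUTDIR / "partition.json").write_text(json.dumps(s.as_dict(), indent=2))
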