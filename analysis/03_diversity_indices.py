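"""Grid the tagged occurrences at 5 arc-minutes and compute species
richness (SR), weighted endemism (WE) and corrected weighted endemism
(CWE) per cell, separately for the KL and NKL subsets, with pairwise
Pearson correlations between the indices.

Writes diversity_KL.csv, diversity_NKL.csv and correlations.json.
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from karstspat import geoio
from karstspat.grid import GridSpec, diversity_table, index_correlations
from karstspat.pipeline import default_scenario

cfg = cfg_mod.CONFIG
tagged = geoio.read_occurrences(cfg_mod.OUTDIR / "occurrences_clean.csv")
grid = GridSpec.from_bbox(default_scenario(cfg).domain_bbox, cfg.cell_size)

all_corr = {}
for landscape in ("KL", "NKL"):
    table = diversity_table(tagged, grid, landscape, cfg.range_scope)
    table.to_csv(cfg_mod.OUTDIR / f"diversity_{landscape}.csv", index=False)
    corr = index_correlations(table)
    all_corr[landscape] = {k: {"r": v[0], "class": v[1]} for k, v in corr.items()}
    print(f"{landscape}: {len(table)} occupied cells, "
          f"SR {table.SR.min()}-{table.SR.max()}, "
          f"WE max {table.WE.max():.2f}, CWE max {table.CWE.max():.2f}")
    for pair, (r, label) in corr.items():
        print(f"  {pair}: r = {r:.2f} ({label})")

(cfg_mod.OUTDIR / "correlations.json").write_text(json.dumps(all_corr, indent=2))
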