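"""Environmental drivers of the KL/NKL split: balance the two classes,
extract raster values at each point, filter weak and collinear
predictors, and ordinate with PCA in the three variable modes.

Writes pca_scores_<mode>.csv and pca_<mode>.png, and prints variance
explained plus the class-separation diagnostic.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from karstspat import geoio
from karstspat.drivers import (
    balance_sample,
    extract_env,
    filter_predictors,
    plot_scores,
    run_pca,
    separation_diagnostic,
)

cfg = cfg_mod.CONFIG
tagged = geoio.read_occurrences(cfg_mod.OUTDIR / "occurrences_clean.csv")
rasters = geoio.read_raster_dir(cfg_mod.OUTDIR / "data" / "rasters")

balanced = balance_sample(tagged, cfg.seed)
kl = (balanced["landscape"] == "KL").sum()
print(f"balanced sample: {kl} KL + {len(balanced) - kl} NKL points")

env, n_dropped = extract_env(balanced, rasters)
reduced, flog = filter_predictors(env)
print(f"extracted {len(env.columns) - 1} variables ({n_dropped} no-data points "
      f"dropped); filter removed {flog.n_dropped} "
      f"({len(flog.weak_response)} weak, {len(flog.collinear)} collinear)")
if len(reduced.columns) - 1 < 2:
    print("every predictor is a weak correlate of the landscape split; "
          "ordinating the full matrix descriptively")
    reduced = env.drop(columns=flog.zero_variance)

for mode in ("all", "bioclim_only", "soil_only"):
    try:
        res = run_pca(reduced, mode)
    except ValueError as e:
        print(f"{mode}: skipped ({e})")
        continue
    sep = separation_diagnostic(res)
    res.scores.to_csv(cfg_mod.OUTDIR / f"pca_scores_{mode}.csv", index=False)
    plot_scores(res, cfg_mod.OUTDIR / f"pca_{mode}.png")
    print(f"{mode}: PC1 {res.explained_pct[0]:.1f}%, "
          f"PC1+PC2 {res.cumulative_pct[1]:.1f}%; centroid separation "
          f"{sep.centroid_distance:.2f} pooled SD "
          f"({'nested' if sep.nested else 'separated'})")
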