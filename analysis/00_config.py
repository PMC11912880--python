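"""Shared configuration for the numbered analysis scripts.

Edit here (or point the scripts at your own occurrence/karst/PA files
via PipelineConfig paths) and re-run 01..05 in order. Outputs land
under results/analysis/.
"""

from pathlib import Path

from karstspat.pipeline import PipelineConfig

OUTDIR = Path("results/analysis")

CONFIG = PipelineConfig(
    outdir=str(OUTDIR),
    seed=1,
    n_species=80,
    n_hotspots=2,       # planted diversity hotspots
    karst_fraction=0.3,
    pa_coverage=0.5,    # half the planted hotspot cells get protection
    env_separation=0.0,  # no planted environmental split (null)
)
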