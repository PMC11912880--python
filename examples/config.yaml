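# Full-pipeline configuration. All paths optional: when the occurrence
# file is unset, the synthetic scenario below is generated instead.
outdir: results/pipeline
seed: 1

# synthetic scenario
n_species: 80
karst_fraction: 0.3
pa_coverage: 0.5
env_separation: 0.0
n_hotspots: 2

# analysis parameters
cell_size: 0.083333      # 5 arcmin diversity grid
pixel_size: 0.0083333    # 30 arcsec thinning pixel (~1 km)
thresholds: [10, 20, 30, 50]
congruence_threshold: 50
tau: 0.0                 # any positive PA overlap protects a cell
range_scope: subset      # or: global
pca_mode: all            # or: bioclim_only / soil_only

# real inputs (leave null to simulate)
occurrences_path: null
karst_path: null
pa_path: null
raster_dir: null
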