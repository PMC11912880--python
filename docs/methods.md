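# Methods

`karstspat` implements a spatial-diversity and conservation-gap
workflow for species occurrence records split between two landscape
classes — karst (KL) and non-karst (NKL) — together with a synthetic
data generator that plants known structure for every stage to recover.
This note documents the models, the parameters that matter, and the
design choices made where more than one defensible option existed.

## Occurrence cleaning, thinning and tagging

Raw tables use Darwin-Core-aligned columns (`species`,
`decimalLongitude`, `decimalLatitude`, `source`). Cleaning applies, in
order: coordinate parsing (non-numeric values are logged, never fatal),
optional per-row coordinate corrections (a stand-in for manual
georeferencing from voucher labels, which cannot be automated), an
inclusive study bounding box, synonym resolution through a user-supplied
two-column map (variants with an empty accepted name are excluded
outright), and exact-duplicate removal on (species, lon, lat). Each
rule's removal count is logged so the final accounting is auditable.

Spatial thinning retains one record per species per pixel. Pixels are
fixed 30-arc-second lon/lat cells (≈1 km at the equator) anchored at
(0°, 0°), so the rule has no free origin parameter and reruns are
reproducible without any projection choice; the true ground area of a
pixel shrinks with |latitude|, which we accept as documented. Within a
(species, pixel) group the survivor is chosen deterministically by
source precision — field GPS > herbarium voucher > database > literature
— then original row order. Thinning is idempotent and can only shrink a
species' pixel footprint.

Landscape tagging is point-in-polygon against the karst layer union;
points on the boundary count as KL (a single inclusive convention,
stated once and tested). The species partition summary counts distinct
species per class (a species in both landscapes counts in both), with
percentages of the total rounded half-up to two decimals — matching how
such compilations conventionally print their percentages.

## Diversity indices

Occurrences are binned onto a regular lon/lat lattice of 0.083333°
(5 arc-minute) square cells, indexed (col, row) from an origin snapped
to whole cell multiples of the cell size from (0°, 0°) — reproducible
without an arbitrary anchor. Cell intervals are half-open, so an
interior-edge point belongs to the higher-index cell.

Per occupied cell:

* **SR** = number of distinct species present;
* **WE** (range-size rarity) = Σ_s 1/C_s over species s present, with
  C_s the number of cells s occupies — so each species contributes
  exactly 1 summed over its whole range (asserted to 1e-9);
* **CWE** = WE / SR ∈ (0, 1], removing the richness trend.

C_s is computed **within the landscape subset under analysis** by
default, mirroring separate per-landscape runs; a `global` range scope
computes C_s over all records instead, since either convention is
plausible for this analysis type. Global ranges are never smaller, so
subset-scope WE bounds global-scope WE from above (tested).

Pairwise Pearson correlations between the indices over cells are
labelled on the conventional five-band |r| scale (negligible < 0.1 ≤
weak < 0.4 ≤ moderate < 0.7 ≤ strong < 0.9 ≤ very strong). |r| = 1.0 is
classed "very strong" (a closed upper boundary). Zero-variance indices
yield an explicit "undefined" label rather than NaN propagation.

## Hotspots and conservation gaps

Hotspots at threshold X are the top ceil(X/100 × n) occupied cells
ranked descending by an index, **with all cells tied at the cut-off
value included** — order-independent at the cost of occasional
inflation (visible on small or heavily tied tables). "Top X%" is a
percentage of occupied cells, not of the value range. Sets are nested
across thresholds by construction. Congruent hotspots are the
intersection of the SR, WE and CWE sets at one threshold (default 50%,
the threshold at which index overlap is usually assessed; others remain
reportable).

The gap partition marks a congruent cell "protected" when the fraction
of its cell polygon's area covered by the protected-area union exceeds
τ (default τ = 0: any positive area overlap protects — boundary-only
contact does not count, since it has zero area). Remaining cells are
"gap" areas. Cell areas use the spherical-Earth band formula
A = R²·Δλ·(sin φ_top − sin φ_bottom) with R = 6371.0088 km, checked
against numerical quadrature.

## Environmental drivers

The driver analysis balances the two classes by subsampling NKL points
without replacement down to the KL count (seeded), extracts one value
per point per raster with the nearest-cell rule (no-data points are
dropped and counted), and screens predictors in two steps: (1) drop
predictors whose point-biserial correlation with the binary KL/NKL
response has |r| < 0.1 — the response variable for this filter is
interpreted as the landscape indicator itself, the one binary quantity
the analysis is about; (2) among remaining pairs with pairwise
|r| > 0.70, greedily resolve the strongest pair first by dropping the
member with the weaker |response correlation|. Zero-variance columns
are dropped up front (their correlation is undefined). Every drop is
logged with both correlations.

Survivors are z-scored (the natural normalisation for mixed-unit
variables), so the PCA — `sklearn.decomposition.PCA` with the full SVD
solver — decomposes the correlation matrix; variance explained per
component is eigenvalue/Σeigenvalues × 100 and sums to 100% (±1e-9;
cross-checked in tests against an independent eigendecomposition).
Three variable modes are provided: all variables, bioclimatic only
(BIO*), and soil/terrain only (depth to bedrock, elevation, organic
carbon, clay). Per-component and cumulative percentages are both
reported so "variance explained" is unambiguous however many leading
components a reader sums.

Because the question is whether the classes segregate at all, a
descriptive diagnostic reports the distance between KL and NKL score
centroids in the PC1–PC2 plane in units of the pooled within-class SD;
clouds closer than one pooled SD are flagged **nested** (no discernible
clustering). No inferential test is attached — the diagnostic is
deliberately descriptive.

When every predictor fails the |r| ≥ 0.1 screen (the expected outcome
when no environmental split exists), the pipeline still ordinates the
full matrix descriptively and records that the filter was bypassed:
that all predictors are weak is itself the finding.

## Synthetic data generator

The generator emulates the statistical structure of a multi-source
occurrence compilation, at desk scale:

* **Domain**: a 4° × 4° box; 80 species with 3–60 raw points each
  (defaults; all exposed on `SyntheticScenario`).
* **Ranges**: each species occupies a contiguous disk-shaped range —
  points uniform in a disk around a species-specific center — whose
  radius is `range_scale × (1 + Pareto(range_shape))`, a heavy tail
  (defaults 0.05°, shape 1.5) making most species narrow-ranged. The
  bounded support keeps a species' occupied-cell count finite no matter
  how many points are drawn, which is what lets endemism peak sharply.
* **Hotspots**: species centers are drawn from a mixture of hotspot
  disks and a uniform background, each hotspot weighted by its
  intensity against a fixed background weight of 30 — so an
  intensity-10 hotspot attracts roughly a quarter of the species pool.
  Hotspot species ranges are capped at `endemic_radius` (0.04°, about
  one analysis cell), planting coincident SR, WE **and** CWE peaks;
  points inside a hotspot disk are additionally oversampled by the
  intensity multiplier. This is a construction: the planted cell is
  guaranteed rich in narrow endemics, so its recovery by the full
  pipeline is a meaningful end-to-end check.
* **Dirty records**: 5% extra rows — equal thirds out-of-bounds
  coordinates, exact duplicates, blank species names — exercise every
  cleaning rule; the cleaning log must account for each.
* **Karst layer**: a union of random disks accreted until the target
  area fraction is reached, with disk radii scaled to the remaining
  deficit so the realized fraction lands within about ±20% relative.
* **Protected areas**: exact cell rectangles over
  round-half-up(pa_coverage × n_planted) planted hotspot cells. Using
  the exact rectangle means neighbouring planted cells receive zero
  area overlap, so the downstream gap partition recovers the
  constructed protected/gap split exactly.
* **Environmental layers**: the eleven variables of the driver set
  (BIO1, BIO4, BIO7, BIO12, BIO15, BIO17, BIO19, depth to bedrock,
  elevation, organic carbon, clay), each a linear + low-frequency
  sinusoid trend plus i.i.d. Gaussian noise on a realistic scale.
  `env_separation` shifts karst pixels by that many SDs of the realized
  field, so the planted standardized mean difference, measured on the
  pixels, equals the parameter (tested at ±0.3).

Determinism: every stage draws from `numpy` generators seeded by
`SeedSequence([seed, stage])`, so identical scenarios reproduce
byte-identical occurrences, polygons and rasters.

**What the generator does not emulate**: real coastline or karst
geometry; spatially autocorrelated sampling effort (collection-road
bias); taxonomic uncertainty beyond a synonym map; raster no-data
structure; non-Gaussian environmental noise. Passing tests therefore
demonstrate that the *methods* recover planted structure under clean
assumptions, not that any real compilation is free of the biases the
cleaning stage cannot see.

## Problem sizes

Default test and analysis runs use 40–80 species (up to ~16k raw rows),
a 49×49-cell diversity grid, rasters at 1–2 arc-minutes, and 100-seed
replicate sweeps for the null-separation rate; these sizes give stable
statistics for every check while keeping a full run in seconds, and all
scale up linearly through `SyntheticScenario` and `PipelineConfig`.

## Known limitations

* Pixel-based thinning (one record per species per fixed cell) is the
  implemented rule; nearest-neighbour-distance thinning is out of scope.
* Degree-based polygon areas are used for the karst-fraction control
  (synthetic domain only); physical areas always use the spherical
  formula.
* The tie rule can inflate hotspot sets well past the nominal
  percentage on tables dominated by a single value (e.g. SR = 1
  nearly everywhere), which is visible in sparse landscapes.
* The separation diagnostic uses only PC1–PC2 and assumes roughly
  elliptical score clouds; it is a summary, not a test.
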