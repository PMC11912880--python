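"""End-to-end orchestration: simulate -> clean -> thin -> tag ->
indices -> hotspots/gaps -> drivers, under one config, with a run
manifest recording row counts, parameters and output checksums."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import geoio
from .drivers import balance_sample, extract_env, filter_predictors, plot_scores, run_pca, separation_diagnostic
from .grid import DEFAULT_CELL_SIZE, GridSpec, diversity_table, index_correlations
from .hotspots import DEFAULT_THRESHOLDS, METRICS, congruent_hotspots, gap_partition, select_hotspots
from .occurrences import DEFAULT_PIXEL_SIZE, clean_records, summarize_partition, tag_landscape, thin_records
from .synthetic import HotspotCenter, SyntheticScenario, generate_env_rasters, generate_landscape_polygons, generate_occurrences, generate_protected_areas


@dataclass
class PipelineConfig:
    """Flat parameter set for one pipeline run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # synthetic scenario (used when no occurrence file is supplied)
    n_species: int = 80
    karst_fraction: float = 0.3
    pa_coverage: float = 0.5
    env_separation: float = 0.0
    n_hotspots: int = 2
    # analysis parameters
    cell_size: float = DEFAULT_CELL_SIZE
    pixel_size: float = DEFAULT_PIXEL_SIZE
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    congruence_threshold: int = 50
    tau: float = 0.0
    range_scope: str = "subset"
    pca_mode: str = "all"
    # optional real inputs; when unset the synthetic generator runs
    occurrences_path: str | None = None
    karst_path: str | None = None
    pa_path: str | None = None
    raster_dir: str | None = None

    def validate(self) -> None:
        for t in tuple(self.thresholds) + (self.congruence_threshold,):
            if not 0 < t <= 100:
                raise ValueError(f"threshold {t} outside (0, 100]")
        if self.range_scope not in ("subset", "global"):
            raise ValueError(f"bad range_scope {self.range_scope!r}")
        if not 0 <= self.tau < 1:
            raise ValueError("tau must be in [0, 1)")
        for name in ("occurrences_path", "karst_path", "pa_path", "raster_dir"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        with Path(path).open("w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            d = yaml.safe_load(fh) or {}
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_scenario(config: PipelineConfig) -> SyntheticScenario:
    """Scenario with ``n_hotspots`` planted centers spread across the
    default domain."""
    centers = []
    anchors = [(121.0, 11.0), (123.0, 13.0), (122.0, 12.5), (121.5, 13.5)]
    for i in range(config.n_hotspots):
        lon, lat = anchors[i % len(anchors)]
        centers.append(HotspotCenter(lon=lon, lat=lat))
    return SyntheticScenario(
        n_species=config.n_species,
        hotspot_centers=tuple(centers),
        karst_fraction=config.karst_fraction,
        pa_coverage=config.pa_coverage,
        env_separation=config.env_separation,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Stage order matches the analysis protocol: data assembly, record
    cleaning, spatial thinning, landscape tagging, per-landscape
    diversity indices, hotspot congruence + gap partition, and the
    balanced-sample driver PCA. No stage mutates its inputs; all
    outputs land under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def log_stage(name: str, **info) -> None:
        manifest["stages"][name] = info

    # -- stage 1: assemble inputs ------------------------------------
    scenario = default_scenario(config)
    grid: GridSpec
    if config.occurrences_path:
        raw = geoio.read_occurrences(config.occurrences_path)
        karst = geoio.read_polygons(config.karst_path) if config.karst_path else None
        pa_polys = geoio.read_polygons(config.pa_path) if config.pa_path else None
        bbox = (
            float(pd.to_numeric(raw["decimalLongitude"], errors="coerce").min()),
            float(pd.to_numeric(raw["decimalLatitude"], errors="coerce").min()),
            float(pd.to_numeric(raw["decimalLongitude"], errors="coerce").max()),
            float(pd.to_numeric(raw["decimalLatitude"], errors="coerce").max()),
        )
        rasters = geoio.read_raster_dir(config.raster_dir) if config.raster_dir else None
    else:
        raw = generate_occurrences(scenario)
        karst = generate_landscape_polygons(scenario)
        bbox = scenario.domain_bbox
        grid_tmp = GridSpec.from_bbox(bbox, config.cell_size)
        pa_list = generate_protected_areas(
            scenario, scenario.planted_cells(grid_tmp), grid_tmp
        )
        import shapely

        pa_polys = shapely.union_all(pa_list) if pa_list else None
        rasters = generate_env_rasters(scenario, karst)
        geoio.write_occurrences(raw, outdir / "occurrences_raw.csv")
        if karst is not None:
            geoio.write_polygons(karst, outdir / "karst.geojson")
        if pa_polys is not None:
            geoio.write_polygons(pa_polys, outdir / "protected_areas.geojson")
    log_stage("simulate", n_raw_records=len(raw))

    grid = GridSpec.from_bbox(bbox, config.cell_size)

    # -- stage 2-4: clean, thin, tag ----------------------------------
    cleaned, clog = clean_records(raw, bbox)
    log_stage("clean", **clog.as_dict())
    thinned = thin_records(cleaned, config.pixel_size)
    log_stage("thin", n_in=len(cleaned), n_out=len(thinned))
    tagged = tag_landscape(thinned, karst)
    partition = summarize_partition(tagged)
    log_stage("tag", n_records=len(tagged), **partition.as_dict())
    geoio.write_occurrences(tagged, outdir / "occurrences_clean.csv")

    # -- stage 5: diversity indices per landscape subset --------------
    tables = {}
    for landscape in ("KL", "NKL"):
        sub = tagged[tagged["landscape"] == landscape]
        if sub.empty:
            continue
        table = diversity_table(tagged, grid, landscape, config.range_scope)
        table.to_csv(outdir / f"diversity_{landscape}.csv", index=False)
        tables[landscape] = table
    corr = {
        ls: {k: {"r": v[0], "class": v[1]} for k, v in index_correlations(t).items()}
        for ls, t in tables.items()
        if len(t) >= 3
    }
    log_stage(
        "indices",
        **{f"n_cells_{ls}": len(t) for ls, t in tables.items()},
        correlations=corr,
    )

    # -- stage 6: hotspots and gaps -----------------------------------
    gap_reports = {}
    for landscape, table in tables.items():
        sets = {
            m: select_hotspots(table, m, config.congruence_threshold) for m in METRICS
        }
        congruent = congruent_hotspots(*sets.values())
        report = gap_partition(congruent, pa_polys, grid, config.tau)
        report.as_frame(grid).to_csv(outdir / f"gaps_{landscape}.csv", index=False)
        gap_reports[landscape] = report
        log_stage(
            f"gaps_{landscape}",
            n_congruent=len(report.congruent),
            n_protected=len(report.protected),
            n_gap=len(report.gap),
            total_area_km2=report.total_area_km2,
        )

    # -- stage 7: drivers ---------------------------------------------
    drivers_out = {}
    if rasters is not None and {"KL", "NKL"} <= set(tagged["landscape"]):
        balanced = balance_sample(tagged, config.seed)
        env, n_dropped = extract_env(balanced, rasters)
        reduced, flog = filter_predictors(env)
        n_predictors = len(reduced.columns) - 1
        filter_bypassed = False
        if n_predictors < 2:
            # every predictor is a weak correlate of the landscape split
            # (itself a finding); ordinate the full matrix descriptively
            reduced = env.drop(columns=flog.zero_variance)
            filter_bypassed = True
            n_predictors = len(reduced.columns) - 1
        pca = run_pca(reduced, config.pca_mode)
        sep = separation_diagnostic(pca)
        pca.scores.to_csv(outdir / "pca_scores.csv", index=False)
        plot_scores(pca, outdir / "pca_scores.png")
        drivers_out = {
            "n_balanced": len(balanced),
            "n_nodata_dropped": n_dropped,
            "n_predictors_kept": n_predictors,
            "n_predictors_dropped": flog.n_dropped,
            "filter_bypassed": filter_bypassed,
            "explained_pct_pc1": float(pca.explained_pct[0]),
            "explained_pct_pc1_pc2": float(pca.cumulative_pct[1]),
            "separation_distance": sep.centroid_distance,
            "nested": sep.nested,
        }
    log_stage("drivers", **drivers_out)

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.suffix in {".csv", ".geojson", ".asc"}:
            manifest["files"][p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
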