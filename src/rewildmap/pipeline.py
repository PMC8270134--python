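"""End-to-end pipeline: ranges -> selection -> occupancy -> scores -> report.

Runs the whole monitoring workflow for every species in a configuration:
filter tracking data, estimate ranges, generate pseudo-absences, fit the
habitat-selection forest, predict the probability surface, classify
occupancy, then cross-species faunal complexity and ecological integrity
(before vs after rewilding), with CSV/GeoTIFF/GeoJSON artifacts and a
structured run report. Every run writes its resolved configuration next to
its outputs so results are reproducible from one provenance artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import geodata_io as gio
from . import habitat_mapping as hm
from . import habitat_selection as hs
from . import range_estimation as re_
from . import rewilding_scores as rs

logger = logging.getLogger("rewildmap")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the framework's stated constants."""

    habitat_raster: str = ""
    tracking_csv: str = ""
    boundary_geojson: str = ""
    output_dir: str = "rewildmap_out"
    species: list[str] = field(default_factory=list)
    min_obs: int = 10
    threshold: float = 0.5
    aggregation_cell_m: float = 30.0
    bandwidth: str | float = "auto"
    isopleth: float = 0.95
    n_trees: int = 500
    seed: int = 0
    denominator_mode: str = "site"

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")
        if not 0 < self.isopleth < 1:
            raise ValueError(f"isopleth {self.isopleth} outside (0, 1)")
        if self.min_obs < 1:
            raise ValueError("min_obs must be >= 1")
        if self.aggregation_cell_m <= 0:
            raise ValueError("aggregation cell size must be > 0")
        if self.denominator_mode not in ("site", "predicted"):
            raise ValueError("denominator_mode must be 'site' or 'predicted'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    """Everything a run computed, re-derivable from the emitted rasters."""

    ranges: dict = field(default_factory=dict)       # species -> summary dict
    models: dict = field(default_factory=dict)       # species -> metadata dict
    occupancy_tables: dict = field(default_factory=dict)   # species -> AreaTable
    occupancy_summary: pd.DataFrame | None = None
    complexity_tables: dict = field(default_factory=dict)  # realized/potential
    integrity: dict = field(default_factory=dict)    # before/after AreaTables + pcts
    dropped: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, species: str | None, cause: Exception):
        self.stage = stage
        self.species = species
        where = f"stage {stage!r}" + (f", species {species!r}" if species else "")
        super().__init__(f"{where}: {cause}")


def _aggregation_factor(cell_size: float, target_m: float) -> int:
    return max(int(np.ceil(target_m / cell_size)), 1)


def run_pipeline(
    config: PipelineConfig,
    habitat: gio.HabitatMap | None = None,
    tracking: gio.TrackingTable | None = None,
    boundary: gio.BoundaryPolygon | None = None,
    write_artifacts: bool = True,
) -> RunReport:
    """Execute the full monitoring workflow.

    In-memory inputs may be passed directly (tests, library use); otherwise
    they are loaded from the configured paths. Deterministic given identical
    config and seed.
    """
    config.validate()
    outdir = Path(config.output_dir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "resolved_config.yaml")

    try:
        if habitat is None:
            habitat = gio.read_raster(config.habitat_raster, "habitat")
        if tracking is None:
            tracking = gio.read_tracking_csv(config.tracking_csv)
        if boundary is None:
            if config.boundary_geojson:
                boundary = gio.read_boundary_geojson(config.boundary_geojson)
            else:
                boundary = gio.BoundaryPolygon(habitat.grid.envelope())
    except Exception as exc:  # noqa: BLE001
        raise StageError("load-inputs", None, exc) from exc

    species = config.species or tracking.species_list()
    if not species:
        raise StageError("load-inputs", None, ValueError("no species to process"))
    report = RunReport()

    factor = _aggregation_factor(habitat.grid.cell_size, config.aggregation_cell_m)
    try:
        proportions = hm.aggregate_proportions(habitat, factor)
    except Exception as exc:  # noqa: BLE001
        raise StageError("aggregate", None, exc) from exc
    if write_artifacts:
        gio.write_raster(proportions, outdir / "habitat_proportions_30m.tif")

    occ_maps: list[rs.OccupancyMap] = []
    occ_rows = []
    for sp in species:
        # -- ranges -----------------------------------------------------
        try:
            kept = re_.filter_individuals(tracking, sp, boundary, config.min_obs)
            rng_est = re_.species_range(kept, sp, proportions.grid,
                                        bandwidth=config.bandwidth,
                                        level=config.isopleth)
        except Exception as exc:  # noqa: BLE001
            raise StageError("range", sp, exc) from exc
        report.ranges[sp] = {
            "n_points": len(kept),
            "n_individuals": kept.frame["individual_id"].nunique(),
            "range_area_km2": rng_est.area_km2,
            "median_individual_area_km2": rng_est.median_individual_area_km2,
            "bandwidth_m": rng_est.bandwidth_m,
            "isopleth": rng_est.isopleth,
        }

        # -- pseudo-absences and training set ---------------------------
        try:
            pa = re_.generate_pseudo_absences(
                kept.points(), rng_est.median_individual_area_km2, boundary,
                seed=config.seed, species=sp,
            )
            rows = hs.build_training_set(
                kept.points(), pa.points, proportions,
                rng_est.median_individual_area_km2,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("pseudoabs", sp, exc) from exc

        # -- selection model and surface --------------------------------
        try:
            model = hs.fit_selection_model(rows, n_trees=config.n_trees,
                                           seed=config.seed)
            surface = hs.predict_surface(model, proportions, species=sp)
        except Exception as exc:  # noqa: BLE001
            raise StageError("select", sp, exc) from exc
        meta = model.metadata()
        meta["buffer_radius_m"] = pa.exclusion_radius_m
        report.models[sp] = meta

        # -- occupancy ---------------------------------------------------
        try:
            occ = rs.classify_occupancy(surface, rng_est.polygons, config.threshold)
        except Exception as exc:  # noqa: BLE001
            raise StageError("score", sp, exc) from exc
        occ_maps.append(occ)
        table = gio.area_summary(occ, boundary, denominator_mode="site")
        report.occupancy_tables[sp] = table

        def _area(lbl: str) -> float:
            try:
                return float(table.row(lbl)["area_km2"])
            except KeyError:
                return 0.0

        r_km2, p_km2 = _area("REALIZED"), _area("POTENTIAL")
        occ_rows.append({
            "species": sp,
            "realized_km2": r_km2,
            "realized_pct": rs.realized_fraction(r_km2, p_km2) if r_km2 + p_km2 > 0 else float("nan"),
            "potential_km2": p_km2,
            "potential_pct": rs.realized_fraction(p_km2, r_km2) if r_km2 + p_km2 > 0 else float("nan"),
        })

        if write_artifacts:
            safe = sp.replace(" ", "_")
            gio.write_raster(surface, outdir / f"selection_{safe}.tif")
            gio.write_geojson({"range": rng_est.polygons}, outdir / f"range_{safe}.geojson",
                              epsg=habitat.grid.epsg)
            gio.write_geojson(rs.occupancy_polygons(occ), outdir / f"occupancy_{safe}.geojson",
                              epsg=habitat.grid.epsg)
            pd.DataFrame({
                "individual_id": list(rng_est.per_individual_areas_km2),
                "area_km2": list(rng_est.per_individual_areas_km2.values()),
            }).to_csv(outdir / f"individual_ranges_{safe}.csv", index=False)
            pts = np.vstack([kept.points(), pa.points])
            pd.DataFrame({
                "x": pts[:, 0], "y": pts[:, 1],
                "label": [1] * len(kept) + [0] * len(pa.points),
            }).to_csv(outdir / f"presence_absence_{safe}.csv", index=False)

    report.occupancy_summary = pd.DataFrame(occ_rows)

    # -- cross-species scores -------------------------------------------
    try:
        cmx = rs.faunal_complexity(occ_maps)
        before = rs.ecological_integrity(occ_maps, "before")
        after = rs.ecological_integrity(occ_maps, "after")
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", None, exc) from exc

    report.complexity_tables = {
        "realized": gio.area_summary(cmx, boundary, config.denominator_mode,
                                     field="realized", background=(0,)),
        "potential": gio.area_summary(cmx, boundary, config.denominator_mode,
                                      field="potential", background=(0,)),
    }
    report.integrity = rs.integrity_delta(before, after, boundary)

    if write_artifacts:
        gio.write_raster(after, outdir / "integrity_after.tif")
        gio.write_raster(before, outdir / "integrity_before.tif")
        render_report(report, outdir)
    return report


def _render_figures(report: RunReport, outdir: Path) -> list[Path]:
    """Bar charts of the report's area tables (map rasters are emitted by
    run_pipeline as GeoTIFFs; figures here summarise the tables)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots(figsize=(6, 3.5))
    df = report.occupancy_summary
    x = np.arange(len(df))
    ax.bar(x - 0.2, df["realized_km2"], width=0.4, label="realized")
    ax.bar(x + 0.2, df["potential_km2"], width=0.4, label="potential")
    ax.set_xticks(x, df["species"], rotation=20, ha="right")
    ax.set_ylabel("area (km²)")
    ax.legend()
    fig.tight_layout()
    p = outdir / "occupancy_areas.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if "before" in report.integrity and "after" in report.integrity:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for scen, off in (("before", -0.2), ("after", 0.2)):
            t = report.integrity[scen].table
            t = t[t["label"].astype(str) != "total"]
            ax.bar(np.arange(len(t)) + off, t["percent"], width=0.4, label=scen)
            ax.set_xticks(np.arange(len(t)), [str(l) for l in t["label"]])
        ax.set_xlabel("ecological integrity score")
        ax.set_ylabel("% of site")
        ax.legend()
        fig.tight_layout()
        p = outdir / "integrity_distribution.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def render_report(report: RunReport, outdir: str | Path, format: str = "csv") -> list[Path]:
    """Emit report tables as CSV (and optional PNG maps via format='csv+png')."""
    if format not in ("csv", "csv+png"):
        raise ValueError(f"unknown report format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if report.occupancy_summary is None or report.occupancy_summary.empty:
        raise ValueError("report has no species: nothing to render")
    p = outdir / "occupancy_summary.csv"
    report.occupancy_summary.to_csv(p, index=False)
    written.append(p)

    for kind, table in report.complexity_tables.items():
        p = outdir / f"complexity_{kind}.csv"
        table.to_csv(p)
        written.append(p)
    for scen in ("before", "after"):
        if scen in report.integrity:
            p = outdir / f"integrity_{scen}.csv"
            report.integrity[scen].to_csv(p)
            written.append(p)

    if format == "csv+png":
        written += _render_figures(report, outdir)

    meta = {
        "ranges": report.ranges,
        "models": report.models,
        "high_integrity_before_pct": report.integrity.get("high_integrity_before_pct"),
        "high_integrity_after_pct": report.integrity.get("high_integrity_after_pct"),
        "dropped": report.dropped,
    }
    p = outdir / "run_report.json"
    with open(p, "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    written.append(p)
    return written
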