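"""Pipeline configuration and orchestration.

`run_pipeline` executes the full analysis in dependency order:

    simulate (optional) -> friction -> travel time / allocation
    -> fit decay from survey -> probability surface
    -> catchments -> burden summaries

Each stage emits a machine-readable JSON line on stderr (stage name,
inputs, key parameters) and writes its artifacts into the output
directory.  Runs are idempotent: the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import vectorio
from .burden import RegionTable, delineate_catchments, summarize
from .decay import DistanceDecayModel, probability_surface
from .friction import SpeedTable, build_friction_surface
from .grids import GridSpec, Raster, read_raster, write_raster
from .synthetic import (
    SyntheticScenario,
    generate_dem,
    generate_facilities,
    generate_landcover,
    generate_population,
    generate_regions,
    generate_rivers,
    generate_roads,
    simulate_survey,
)
from .traveltime import AllocationSurface, TravelTimeSurface, accumulate_cost

logger = logging.getLogger(__name__)

DEFAULT_LANDCOVER_PROPORTIONS = {
    1: 0.05,  # tree cover, broadleaved
    3: 0.05,  # tree cover, other
    4: 0.30,  # shrub
    5: 0.20,  # herbaceous
    6: 0.15,  # sparse herbaceous
    7: 0.10,  # cultivated
    8: 0.13,  # bare / desert
    9: 0.02,  # water (barrier)
}


def _log_stage(stage: str, **info) -> None:
    payload = {"stage": stage, **info}
    print(json.dumps(payload, default=str), file=sys.stderr)


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through JSON unchanged."""

    out_dir: str
    seed: int = 0
    scenario: dict | None = None  # synthetic inputs; else paths below are used
    landcover_path: str | None = None
    dem_path: str | None = None
    roads_path: str | None = None
    rivers_path: str | None = None
    population_path: str | None = None
    regions_path: str | None = None
    facilities_path: str | None = None
    survey_path: str | None = None
    region_table_path: str | None = None
    speed_table_path: str | None = None
    transform: str = "log10"
    n_bins: int = 15
    t_floor: float = 1.0
    threshold_minutes: float = 180.0
    time_band_edges: tuple[float, ...] = (30.0, 60.0, 120.0, 180.0)
    probability_band_edges: tuple[float, ...] = (0.5, 0.6, 0.7, 0.75)
    total_population: int = 100_000
    relief_amplitude: float = 300.0
    n_roads: int = 5
    n_rivers: int = 2
    n_population_centres: int = 5

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["time_band_edges"] = list(self.time_band_edges)
        d["probability_band_edges"] = list(self.probability_band_edges)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for k in ("time_band_edges", "probability_band_edges"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PipelineArtifacts:
    """In-memory handles to everything a run produced."""

    friction: object
    travel_time: TravelTimeSurface
    allocation: AllocationSurface
    decay: object
    probability: Raster
    catchments: object
    summaries: dict[str, pd.DataFrame]
    survey: pd.DataFrame
    region_table: RegionTable


def _simulate_inputs(cfg: PipelineConfig, out: Path):
    """Generate and write all synthetic inputs for a scenario run."""
    scen = SyntheticScenario.from_dict(cfg.scenario)
    g = scen.grid
    seed = scen.seed
    dem = generate_dem(g, seed, cfg.relief_amplitude)
    landcover = generate_landcover(g, seed + 1, DEFAULT_LANDCOVER_PROPORTIONS)
    roads = generate_roads(g, seed + 2, cfg.n_roads)
    rivers = generate_rivers(g, seed + 3, cfg.n_rivers)
    population = generate_population(
        g, seed + 4, cfg.n_population_centres, cfg.total_population
    )
    regions = generate_regions(g, scen.n_regions)

    write_raster(out / "dem.asc", dem)
    write_raster(out / "landcover.asc", landcover)
    write_raster(out / "population.asc", population)
    write_raster(out / "regions.asc", regions)
    vectorio.write_roads(out / "roads.geojson", roads)
    vectorio.write_rivers(out / "rivers.geojson", rivers)
    _log_stage("simulate-inputs", grid=f"{g.n_rows}x{g.n_cols}", seed=seed)
    return scen, dem, landcover, roads, rivers, population, regions


def run_pipeline(cfg: PipelineConfig) -> PipelineArtifacts:
    """Execute all stages; returns in-memory artifacts and writes files."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = (
        SpeedTable.from_json(cfg.speed_table_path)
        if cfg.speed_table_path
        else SpeedTable.default()
    )

    scen = None
    if cfg.scenario is not None:
        scen, dem, landcover, roads, rivers, population, regions = _simulate_inputs(
            cfg, out
        )
    else:
        landcover = read_raster(cfg.landcover_path, dtype=int)
        g = landcover.grid
        dem = (
            read_raster(cfg.dem_path, expect_grid=g) if cfg.dem_path else None
        )
        roads = vectorio.read_roads(cfg.roads_path) if cfg.roads_path else None
        rivers = vectorio.read_rivers(cfg.rivers_path) if cfg.rivers_path else None
        population = read_raster(cfg.population_path, expect_grid=g)
        regions = read_raster(cfg.regions_path, dtype=int, expect_grid=g)

    friction = build_friction_surface(landcover, roads, rivers, dem, table)
    write_raster(out / "friction.asc", friction.base_speed)
    _log_stage(
        "friction",
        barrier_cells=int(friction.barrier.values.sum()),
        grid=f"{friction.grid.n_rows}x{friction.grid.n_cols}",
    )

    if cfg.scenario is not None:
        facilities = generate_facilities(
            population, scen.n_facilities, scen.seed + 5, barrier=friction.barrier
        )
        vectorio.write_facilities(out / "facilities.geojson", facilities)
    else:
        facilities = vectorio.read_facilities(cfg.facilities_path)

    tt, alloc = accumulate_cost(friction, dem, facilities)
    write_raster(out / "travel_time.asc", tt.minutes)
    write_raster(out / "allocation.asc", alloc.facility_id, inf_as_nodata=False)
    _log_stage(
        "travel-time",
        facilities=len(facilities),
        reached_cells=int(np.isfinite(tt.minutes.values).sum()),
    )

    if cfg.scenario is not None:
        survey = simulate_survey(scen, tt, regions=regions, barrier=friction.barrier)
        vectorio.write_survey(out / "survey.csv", survey)
        region_table = RegionTable.from_mapping(
            prevalence={
                r: scen.fever_prevalence_by_region[r] for r in range(scen.n_regions)
            },
            under5_fraction={
                r: scen.under5_fraction_by_region[r] for r in range(scen.n_regions)
            },
        )
        region_table.to_csv(out / "region_table.csv")
    else:
        survey = vectorio.read_survey(cfg.survey_path)
        region_table = RegionTable.from_csv(cfg.region_table_path)
    _log_stage("survey", children=len(survey), fevers=int((survey["fever"] == 1).sum()))

    model = DistanceDecayModel.from_dataframe(
        survey, transform=cfg.transform, n_bins=cfg.n_bins, t_floor=cfg.t_floor
    )
    res = model.fit()
    res.to_json(out / "decay_model.json")
    _log_stage("fit-decay", C=res.C, A=res.A, B=res.B, ssr=res.ssr)

    prob = probability_surface(res, tt)
    write_raster(out / "probability.asc", prob)

    catchments = delineate_catchments(tt, alloc, cfg.threshold_minutes)
    write_raster(out / "catchments.asc", catchments.catchment, inf_as_nodata=False)
    _log_stage(
        "catchments",
        threshold_minutes=cfg.threshold_minutes,
        inside_cells=int(catchments.mask().sum()),
    )

    children = burden_mod.children_surface(population, regions, region_table)
    fever = burden_mod.fever_surface(children, regions, region_table)
    attendees, _ = burden_mod.expected_attendance(fever, prob)

    summaries = {}
    summaries["regions"] = summarize(
        children, fever, attendees, strata="regions",
        regions=regions, table=region_table, catchments=catchments,
    )
    summaries["time_bands"] = summarize(
        children, fever, attendees, strata="time-bands",
        band_edges=cfg.time_band_edges, cumulative=True, tt=tt,
        catchments=catchments,
    )
    summaries["probability_bands"] = summarize(
        children, fever, attendees, strata="probability-bands",
        band_edges=cfg.probability_band_edges, probability=prob,
        catchments=catchments,
    )
    summaries["catchments"] = summarize(
        children, fever, attendees, strata="catchments", catchments=catchments,
    )
    for name, df in summaries.items():
        df.to_csv(out / f"summary_{name}.csv", index=False)
    _log_stage(
        "burden",
        total_children=float(children.values.sum()),
        total_fevers=float(fever.values.sum()),
        expected_attendees=float(attendees.values.sum()),
    )

    return PipelineArtifacts(
        friction=friction,
        travel_time=tt,
        allocation=alloc,
        decay=res,
        probability=prob,
        catchments=catchments,
        summaries=summaries,
        survey=survey,
        region_table=region_table,
    )
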