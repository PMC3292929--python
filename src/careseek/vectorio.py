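"""GeoJSON and CSV interchange for vector layers and survey tables.

Vectors (facilities, roads, rivers) travel as GeoJSON FeatureCollections;
the survey and region tables as CSV.  Coordinates are planar metres
throughout — no CRS handling, by design.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape

from .synthetic import Road
from .traveltime import Facility

__all__ = [
    "write_facilities",
    "read_facilities",
    "write_roads",
    "read_roads",
    "write_rivers",
    "read_rivers",
    "write_survey",
    "read_survey",
]

SURVEY_COLUMNS = [
    "cluster_id", "region_id", "x", "y", "child_id",
    "fever", "attended_public", "travel_time_min",
]


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_facilities(path: str | Path, facilities) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(Point(f.x, f.y)),
            "properties": {"facility_id": int(f.facility_id)},
        }
        for f in facilities
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats), indent=1) + "\n")


def read_facilities(path: str | Path) -> list[Facility]:
    fc = json.loads(Path(path).read_text())
    facs = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        facs.append(
            Facility(
                facility_id=int(feat["properties"]["facility_id"]),
                x=float(geom.x),
                y=float(geom.y),
            )
        )
    return facs


def write_roads(path: str | Path, roads) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {"road_class": r.road_class},
        }
        for r in roads
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats), indent=1) + "\n")


def read_roads(path: str | Path) -> list[Road]:
    fc = json.loads(Path(path).read_text())
    return [
        Road(
            geometry=shape(feat["geometry"]),
            road_class=feat["properties"]["road_class"],
        )
        for feat in fc["features"]
    ]


def write_rivers(path: str | Path, rivers) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(r), "properties": {"barrier": True}}
        for r in rivers
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats), indent=1) + "\n")


def read_rivers(path: str | Path) -> list[LineString]:
    fc = json.loads(Path(path).read_text())
    return [shape(feat["geometry"]) for feat in fc["features"]]


def write_survey(path: str | Path, survey: pd.DataFrame) -> None:
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise ValueError(f"survey table is missing columns {missing}")
    survey.to_csv(path, index=False, columns=SURVEY_COLUMNS)


def read_survey(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} is missing columns {missing}")
    return df
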