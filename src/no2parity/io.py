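"""Reading and writing the pipeline's file formats.

Pixels travel as flat CSV tables (four footprint corners, center, column,
QA, ISO date); tracts and roads as GeoJSON FeatureCollections; gridded
fields as long-form CSV (lon, lat, value, weight, count); configs as JSON
key/value files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .regrid import GriddedField, GridSpec
from .synthetic import ScenarioConfig

TRACT_PROPERTIES = [
    "tract_id",
    "urban",
    "msa_key",
    "frac_white",
    "frac_black",
    "frac_other",
    "frac_hispanic",
    "median_income",
    "frac_highschool",
    "frac_college",
    "frac_graduate",
    "frac_no_vehicle",
]


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and np.isnan(v):
        return None
    if isinstance(v, (np.bool_, bool)):
        return bool(v)
    return v


def write_tracts_geojson(tracts: pd.DataFrame, path) -> None:
    feats = []
    cols = [c for c in TRACT_PROPERTIES if c in tracts.columns]
    for rec in tracts.to_dict("records"):
        props = {c: _jsonable(rec[c]) for c in cols}
        feats.append(
            {"type": "Feature", "geometry": mapping(rec["geometry"]), "properties": props}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_tracts_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        row = dict(feat["properties"])
        geom = shape(feat["geometry"])
        row["geometry"] = geom
        c = geom.centroid
        row["centroid_lon"] = c.x
        row["centroid_lat"] = c.y
        rows.append(row)
    df = pd.DataFrame(rows)
    if "median_income" in df.columns:
        df["median_income"] = df["median_income"].astype(float)
    return df


def write_roads_geojson(roads: pd.DataFrame, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(rec["geometry"]),
            "properties": {"segment_id": rec["segment_id"]},
        }
        for rec in roads.to_dict("records")
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_roads_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    return pd.DataFrame(
        {
            "segment_id": [f["properties"].get("segment_id", str(i))
                           for i, f in enumerate(data["features"])],
            "geometry": [shape(f["geometry"]) for f in data["features"]],
        }
    )


def write_pixels_csv(pixels: pd.DataFrame, path) -> None:
    pixels.to_csv(path, index=False)


def read_pixels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_grid_csv(field: GriddedField, path) -> None:
    spec = field.spec
    lon, lat = spec.center_mesh()
    df = pd.DataFrame(
        {
            "lon": lon.ravel(),
            "lat": lat.ravel(),
            "value": field.values.ravel(),
            "weight": field.weights.ravel(),
            "count": field.counts.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# grid lon0={spec.lon0} lat0={spec.lat0} n_lon={spec.n_lon} "
            f"n_lat={spec.n_lat} dlon={spec.dlon} dlat={spec.dlat} period={field.period}\n"
        )
        df.to_csv(fh, index=False)


def read_grid_csv(path) -> GriddedField:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv)
    spec = GridSpec(
        lon0=float(meta["lon0"]),
        lat0=float(meta["lat0"]),
        n_lon=int(meta["n_lon"]),
        n_lat=int(meta["n_lat"]),
        dlon=float(meta["dlon"]),
        dlat=float(meta["dlat"]),
    )
    shp = (spec.n_lat, spec.n_lon)
    return GriddedField(
        spec,
        df["value"].to_numpy().reshape(shp),
        df["weight"].to_numpy().reshape(shp),
        df["count"].to_numpy().reshape(shp).astype(int),
        period=meta.get("period", ""),
    )


def write_config_json(config: ScenarioConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2))


def read_config_json(path) -> ScenarioConfig:
    data = json.loads(Path(path).read_text())
    for key in ("domain_bbox", "plume_amplitudes", "pixel_size_km"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return ScenarioConfig(**data)
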