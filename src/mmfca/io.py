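"""File formats: GeoJSON roads/facilities/points, speed table CSV, OD CSV.

All coordinates are planar metres; GeoJSON here is used as a geometry
container, not as a geographic CRS claim.  Infinity is serialised as the
literal ``inf`` in CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .network import DEFAULT_MODES, ODMatrix, RoadSegment, TravelMode


def write_roads_geojson(path, segments: list[RoadSegment]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(seg.geometry),
            "properties": {
                "segment_id": seg.segment_id,
                "road_class": seg.road_class,
                "zone": seg.zone,
            },
        }
        for seg in segments
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n"
    )


def read_roads_geojson(path) -> list[RoadSegment]:
    fc = json.loads(Path(path).read_text())
    segments = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        if "road_class" not in props:
            raise ValueError("road feature missing required property 'road_class'")
        segments.append(
            RoadSegment(
                segment_id=str(props.get("segment_id", f"seg{len(segments):05d}")),
                geometry=shape(feat["geometry"]),
                road_class=props["road_class"],
                zone=props.get("zone", "default"),
            )
        )
    return segments


def write_facilities_geojson(path, facilities: pd.DataFrame) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {"facility_id": row.facility_id, "staff": int(row.staff)},
        }
        for row in facilities.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n"
    )


def read_facilities(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".geojson") or path.endswith(".json"):
        fc = json.loads(Path(path).read_text())
        rows = [
            (
                f["properties"]["facility_id"],
                float(f["geometry"]["coordinates"][0]),
                float(f["geometry"]["coordinates"][1]),
                int(f["properties"]["staff"]),
            )
            for f in fc["features"]
        ]
        return pd.DataFrame(rows, columns=["facility_id", "x", "y", "staff"])
    df = pd.read_csv(path)
    required = {"facility_id", "x", "y", "staff"}
    if not required.issubset(df.columns):
        raise ValueError(f"facility CSV must have columns {sorted(required)}")
    return df[["facility_id", "x", "y", "staff"]]


def read_speed_table(path) -> dict[str, dict[str, float]]:
    """Read a zone-by-class speed CSV (columns: zone, highway, major, residential)."""
    df = pd.read_csv(path)
    required = {"zone", "highway", "major", "residential"}
    if not required.issubset(df.columns):
        raise ValueError(f"speed table must have columns {sorted(required)}")
    return {
        str(r.zone): {
            "highway": float(r.highway),
            "major": float(r.major),
            "residential": float(r.residential),
        }
        for r in df.itertuples()
    }


def write_speed_table(path, table: dict[str, dict[str, float]]) -> None:
    rows = [
        {"zone": z, "highway": r["highway"], "major": r["major"], "residential": r["residential"]}
        for z, r in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_od_matrix(path, od: ODMatrix) -> None:
    df = od.to_long_frame()
    df.to_csv(path, index=False)  # pandas writes +inf as 'inf'


def read_od_matrix(path, modes: tuple[TravelMode, ...] = DEFAULT_MODES) -> ODMatrix:
    df = pd.read_csv(path)
    return ODMatrix.from_long_frame(df, modes)


def write_access_geojson(path, surface: pd.DataFrame) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {
                "cell_id": row.cell_id,
                "pop": float(row.pop),
                "access": float(row.access),
                "zone": "outside" if row.zone == 0 else int(row.zone),
            },
        }
        for row in surface.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n"
    )
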