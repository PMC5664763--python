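"""Plain-text file interfaces: GeoJSON layers, CSV tables, ASCII grids.

All vector layers are exchanged as GeoJSON in projected metric coordinates
(road class in property ``road_class``, land use in ``use_class``, point
category in ``category``); the vegetation raster as an ESRI ASCII grid;
sites and measurement series as CSV; models and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .gis import (
    FeatureMatrix,
    HouseholdLayer,
    LandUseLayer,
    PointFeatureSet,
    RasterGrid,
    RoadNetwork,
    Site,
    StudyLayers,
)
from .variables import CandidateVariable, LANDUSE_CLASSES, POINT_CATEGORIES

__all__ = [
    "read_sites_csv",
    "write_sites_csv",
    "read_layers",
    "write_layers",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_model_json",
]


def read_sites_csv(path: str | Path) -> list[Site]:
    df = pd.read_csv(path, dtype={"site_id": str})
    return [
        Site(r.site_id, float(r.x), float(r.y), str(getattr(r, "area", "")))
        for r in df.itertuples()
    ]


def write_sites_csv(sites: Sequence[Site], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "area": [s.area_label for s in sites],
        }
    ).to_csv(path, index=False)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_layers(layers: StudyLayers, outdir: str | Path) -> None:
    """Write roads/points/landuse as GeoJSON and the NDVI ASCII grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    feats = []
    for cls, lines in layers.roads.lines.items():
        for line in lines:
            feats.append(
                {"type": "Feature", "properties": {"road_class": cls}, "geometry": mapping(line)}
            )
    (outdir / "roads.geojson").write_text(json.dumps(_feature_collection(feats)))

    feats = []
    for cat, fs in layers.point_features.items():
        for x, y in fs.points:
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"category": cat},
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                }
            )
    (outdir / "points.geojson").write_text(json.dumps(_feature_collection(feats)))

    feats = [
        {
            "type": "Feature",
            "properties": {"category": "household"},
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        }
        for x, y in layers.households.points
    ]
    (outdir / "households.geojson").write_text(json.dumps(_feature_collection(feats)))

    feats = []
    for cls, polys in layers.landuse.polygons.items():
        for poly in polys:
            feats.append(
                {"type": "Feature", "properties": {"use_class": cls}, "geometry": mapping(poly)}
            )
    (outdir / "landuse.geojson").write_text(json.dumps(_feature_collection(feats)))

    if layers.ndvi is not None:
        write_ascii_grid(layers.ndvi, outdir / "ndvi.asc")


def read_layers(indir: str | Path) -> StudyLayers:
    indir = Path(indir)

    segs: dict[str, list] = {}
    for feat in json.loads((indir / "roads.geojson").read_text())["features"]:
        segs.setdefault(feat["properties"]["road_class"], []).append(shape(feat["geometry"]))
    roads = RoadNetwork(segs)

    pts: dict[str, list] = {c: [] for c in POINT_CATEGORIES}
    for feat in json.loads((indir / "points.geojson").read_text())["features"]:
        pts.setdefault(feat["properties"]["category"], []).append(
            feat["geometry"]["coordinates"]
        )
    point_features = {
        c: PointFeatureSet(c, np.asarray(v, dtype=float).reshape(-1, 2))
        for c, v in pts.items()
    }

    hh = [
        feat["geometry"]["coordinates"]
        for feat in json.loads((indir / "households.geojson").read_text())["features"]
    ]
    households = HouseholdLayer(np.asarray(hh, dtype=float).reshape(-1, 2))

    polys: dict[str, list] = {c: [] for c in LANDUSE_CLASSES}
    for feat in json.loads((indir / "landuse.geojson").read_text())["features"]:
        polys.setdefault(feat["properties"]["use_class"], []).append(shape(feat["geometry"]))
    landuse = LandUseLayer(polys)

    ndvi_path = indir / "ndvi.asc"
    ndvi = read_ascii_grid(ndvi_path) if ndvi_path.exists() else None

    return StudyLayers(roads, point_features, households, landuse, ndvi)


def write_ascii_grid(raster: RasterGrid, path: str | Path) -> None:
    """ESRI ASCII grid; rows are written north-to-south as the format requires."""
    nrow, ncol = raster.values.shape
    header = (
        f"ncols {ncol}\nnrows {nrow}\nxllcorner {raster.x0}\nyllcorner {raster.y0}\n"
        f"cellsize {raster.cell_size}\nNODATA_value -9999\n"
    )
    vals = np.where(np.isfinite(raster.values), raster.values, -9999.0)
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in vals[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    vals = np.loadtxt(lines[i:], dtype=float)
    vals = np.atleast_2d(vals)[::-1]  # back to south-first row order
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return RasterGrid(
        x0=header["xllcorner"], y0=header["yllcorner"],
        cell_size=header["cellsize"], values=vals,
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV of values plus a sidecar ``<path>.meta.json`` of column metadata."""
    path = Path(path)
    fm.df.to_csv(path)
    meta = {
        name: {
            "var_type": v.var_type,
            "category": v.category,
            "buffer_m": v.buffer_m,
            "expected_sign": v.expected_sign,
            "unit": v.unit,
        }
        for name, v in fm.variables.items()
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="site_id")
    df.index = df.index.astype(str)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    variables = {
        name: CandidateVariable(
            name=name,
            var_type=m["var_type"],
            category=m["category"],
            buffer_m=m["buffer_m"],
            expected_sign=m["expected_sign"],
            unit=m["unit"],
        )
        for name, m in meta.items()
    }
    return FeatureMatrix(df, variables)


def write_model_json(model_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_dict, indent=1, sort_keys=True))
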