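"""Buffer-based GIS predictors for noise land-use regression.

Every operation works in a projected metric coordinate system; inputs whose
bounds look like geographic lon/lat degrees are refused rather than silently
mis-measured. The circular buffer around a site is a closed disc.

Road lengths inside a buffer are clipped against the true circle
analytically (per-segment quadratic solve), which is exact for straight
segments: a diametral chord measures exactly ``2r``. Land-use areas use
shapely polygon intersection with a finely polygonised disc; household
densities and inverse distances use k-d trees; raster means use the
cell-centre-in-disc rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon

from .variables import (
    CandidateVariable,
    LANDUSE_CLASSES,
    ROAD_CLASSES,
    ROAD_COMPOSITES,
    table1_variables,
)

__all__ = [
    "Site",
    "RoadNetwork",
    "PointFeatureSet",
    "HouseholdLayer",
    "LandUseLayer",
    "RasterGrid",
    "StudyLayers",
    "FeatureMatrix",
    "line_length_in_buffer",
    "inverse_distance",
    "inverse_distance_to_roads",
    "household_density",
    "landuse_area_in_buffer",
    "raster_mean_in_buffer",
    "build_feature_matrix",
    "UnprojectedInputError",
]

logger = logging.getLogger(__name__)

#: Inverse distances are floored at 1 m so a site touching a feature yields
#: a bounded value instead of dominating the regression screen.
MIN_DISTANCE_M = 1.0



class UnprojectedInputError(ValueError):
    """Coordinates look like geographic degrees, not projected meters."""


def _check_projected(xy: np.ndarray, what: str) -> None:
    if xy.size == 0:
        return
    x, y = xy[:, 0], xy[:, 1]
    if (np.abs(x) <= 180).all() and (np.abs(y) <= 90).all():
        raise UnprojectedInputError(
            f"{what}: all coordinates fit in a lon/lat degree box; "
            "re-project to a metric CRS before ingestion"
        )


@dataclass(frozen=True)
class Site:
    """A measurement site in projected metric coordinates."""

    site_id: str
    x: float
    y: float
    area_label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"site {self.site_id!r}: non-finite coordinates")


class RoadNetwork:
    """Road polylines, each tagged with one of four traffic classes.

    Internally each class is decomposed into straight segments stored as
    coordinate arrays, which makes exact circle clipping and nearest-distance
    queries cheap numpy operations.
    """

    def __init__(self, segments_by_class: Mapping[str, Sequence[LineString]]):
        unknown = set(segments_by_class) - set(ROAD_CLASSES)
        if unknown:
            raise ValueError(f"unknown road classes: {sorted(unknown)}")
        self.lines: dict[str, list[LineString]] = {c: [] for c in ROAD_CLASSES}
        self._p0: dict[str, np.ndarray] = {c: np.empty((0, 2)) for c in ROAD_CLASSES}
        self._p1: dict[str, np.ndarray] = {c: np.empty((0, 2)) for c in ROAD_CLASSES}
        for cls, lines in segments_by_class.items():
            p0s, p1s = [], []
            for line in lines:
                coords = np.asarray(line.coords, dtype=float)
                if len(coords) < 2 or LineString(coords).length == 0:
                    raise ValueError(f"degenerate {cls} road geometry")
                p0s.append(coords[:-1])
                p1s.append(coords[1:])
                self.lines[cls].append(LineString(coords))
            if p0s:
                self._p0[cls] = np.vstack(p0s)
                self._p1[cls] = np.vstack(p1s)
            else:
                self._p0[cls] = np.empty((0, 2))
                self._p1[cls] = np.empty((0, 2))
        all_pts = np.vstack([self._p0[c] for c in ROAD_CLASSES] + [self._p1[c] for c in ROAD_CLASSES])
        _check_projected(all_pts, "road network")

    @property
    def is_empty(self) -> bool:
        return all(len(self._p0[c]) == 0 for c in ROAD_CLASSES)

    def segments(self, classes: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        classes = tuple(classes)
        return (
            np.vstack([self._p0[c] for c in classes]),
            np.vstack([self._p1[c] for c in classes]),
        )


def _clipped_segment_lengths(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Length of each segment's intersection with the closed disc (exact)."""
    d = p1 - p0
    f = p0 - center
    a = np.einsum("ij,ij->i", d, d)
    b = np.einsum("ij,ij->i", f, d)
    c = np.einsum("ij,ij->i", f, f) - radius * radius
    disc = b * b - a * c
    out = np.zeros(len(p0))
    hit = (disc > 0) & (a > 0)
    if hit.any():
        sq = np.sqrt(disc[hit])
        t1 = np.clip((-b[hit] - sq) / a[hit], 0.0, 1.0)
        t2 = np.clip((-b[hit] + sq) / a[hit], 0.0, 1.0)
        out[hit] = (t2 - t1) * np.sqrt(a[hit])
    return out


def line_length_in_buffer(
    network: RoadNetwork,
    classes: Iterable[str],
    site: Site,
    radius_m: float,
) -> float:
    """Total clipped length of the given road classes inside the disc."""
    classes = tuple(classes)
    if not classes:
        raise ValueError("empty road-class subset")
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    p0, p1 = network.segments(classes)
    if len(p0) == 0:
        return 0.0
    center = np.array([site.x, site.y])
    return float(_clipped_segment_lengths(p0, p1, center, radius_m).sum())


def _ring_disc_contributions(
    a: np.ndarray, b: np.ndarray, radius: float
) -> np.ndarray:
    """Signed area contribution of directed edges against the disc at origin.

    Green's-theorem decomposition of ``area(polygon ∩ disc)``: the part of
    each edge inside the circle contributes a chord (cross-product) term, the
    parts outside contribute circular-arc terms of ``r²θ/2`` with the signed
    central angle. Summed over a CCW ring this is the exact intersection
    area; a ring not touching the disc sums to 0 (or the full disc when it
    encloses the centre).
    """
    r2 = radius * radius

    def arc(p: np.ndarray, q: np.ndarray) -> np.ndarray:
        cross = p[:, 0] * q[:, 1] - p[:, 1] * q[:, 0]
        dot = np.einsum("ij,ij->i", p, q)
        return 0.5 * r2 * np.arctan2(cross, dot)

    d = b - a
    A = np.einsum("ij,ij->i", d, d)
    B = np.einsum("ij,ij->i", a, d)
    C = np.einsum("ij,ij->i", a, a) - r2
    disc = B * B - A * C
    out = arc(a, b)
    hit = (disc > 0) & (A > 0)
    if hit.any():
        sq = np.sqrt(disc[hit])
        t1 = np.clip((-B[hit] - sq) / A[hit], 0.0, 1.0)
        t2 = np.clip((-B[hit] + sq) / A[hit], 0.0, 1.0)
        inside = t2 > t1
        if inside.any():
            ah, dh = a[hit][inside], d[hit][inside]
            q1 = ah + t1[inside, None] * dh
            q2 = ah + t2[inside, None] * dh
            chord = 0.5 * (q1[:, 0] * q2[:, 1] - q1[:, 1] * q2[:, 0])
            vals = arc(ah, q1) + chord + arc(q2, a[hit][inside] + dh)
            tmp = out[hit]
            tmp[inside] = vals
            out[hit] = tmp
    return out


def _polygon_rings_ccw(poly: Polygon) -> list[np.ndarray]:
    """Coordinate rings of a polygon, shell CCW and holes CW."""
    from shapely.geometry.polygon import orient

    rings = []
    poly = orient(poly, sign=1.0)
    rings.append(np.asarray(poly.exterior.coords, dtype=float))
    for hole in poly.interiors:
        rings.append(np.asarray(hole.coords, dtype=float))
    return rings


def _disc_polygon_area(
    center: np.ndarray, radius: float, edge_a: np.ndarray, edge_b: np.ndarray
) -> float:
    """Exact area of (disc ∩ polygons) given concatenated oriented edges."""
    return float(
        _ring_disc_contributions(edge_a - center, edge_b - center, radius).sum()
    )


def _point_segment_distances(
    pt: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    d = p1 - p0
    a = np.einsum("ij,ij->i", d, d)
    t = np.zeros(len(p0))
    nz = a > 0
    t[nz] = np.clip(np.einsum("ij,ij->i", pt - p0[nz], d[nz]) / a[nz], 0.0, 1.0)
    nearest = p0 + t[:, None] * d
    return np.hypot(*(pt - nearest).T)


@dataclass
class PointFeatureSet:
    """Point features of one category (airport, railway, church, ...)."""

    category: str
    points: np.ndarray  # (n, 2) projected coordinates

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) and not np.isfinite(self.points).all():
            raise ValueError("non-finite feature coordinates")
        self._tree = cKDTree(self.points) if len(self.points) else None

    def __len__(self) -> int:
        return len(self.points)


def inverse_distance(site: Site, features: PointFeatureSet) -> float:
    """1 / distance to the nearest feature, distance floored at 1 m."""
    if len(features) == 0:
        raise ValueError(f"empty feature set {features.category!r}")
    d, _ = features._tree.query([site.x, site.y])
    return 1.0 / max(float(d), MIN_DISTANCE_M)


def inverse_distance_to_roads(site: Site, network: RoadNetwork) -> float:
    """1 / distance to the nearest road segment of any class (floored at 1 m)."""
    if network.is_empty:
        raise ValueError("empty road network")
    p0, p1 = network.segments(ROAD_CLASSES)
    d = _point_segment_distances(np.array([site.x, site.y]), p0, p1).min()
    return 1.0 / max(float(d), MIN_DISTANCE_M)


@dataclass
class HouseholdLayer:
    """One point per household."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) and not np.isfinite(self.points).all():
            raise ValueError("non-finite household coordinates")
        self._tree = cKDTree(self.points) if len(self.points) else None

    def __len__(self) -> int:
        return len(self.points)


def household_density(
    households: HouseholdLayer, site: Site, radius_m: float
) -> float:
    """Households within the closed disc divided by the disc area (per m²)."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if len(households) == 0:
        return 0.0
    n = len(households._tree.query_ball_point([site.x, site.y], radius_m))
    return n / (np.pi * radius_m**2)


class LandUseLayer:
    """Land-use polygons in five classes; invalid geometries are repaired."""

    def __init__(self, polygons_by_class: Mapping[str, Sequence[Polygon]]):
        unknown = set(polygons_by_class) - set(LANDUSE_CLASSES)
        if unknown:
            raise ValueError(f"unknown land-use classes: {sorted(unknown)}")
        self.polygons: dict[str, list[Polygon]] = {c: [] for c in LANDUSE_CLASSES}
        self._trees: dict[str, shapely.STRtree] = {}
        for cls, polys in polygons_by_class.items():
            fixed = []
            for i, poly in enumerate(polys):
                if not poly.is_valid:
                    poly = shapely.make_valid(poly)
                    if not poly.is_valid or poly.is_empty:
                        raise ValueError(f"unrepairable {cls} polygon #{i}")
                fixed.append(poly)
            self.polygons[cls] = fixed

    def _edges(self, use_class: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Oriented edges with a per-polygon bounding-box index.

        Returns ``(a, b, edge_poly_id, poly_bboxes)``. Overlapping polygons
        are unioned first so areas are never counted twice; a mosaic (no
        internal overlap) is used as-is. Whole polygons are always kept
        together so the winding of rings enclosing a buffer stays intact.
        """
        if not hasattr(self, "_edge_cache"):
            self._edge_cache: dict[str, tuple] = {}
        if use_class not in self._edge_cache:
            polys = self.polygons[use_class]
            total = sum(p.area for p in polys)
            merged = shapely.union_all(polys) if polys else None
            if merged is not None and not np.isclose(total, merged.area, rtol=1e-9):
                polys = (
                    list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
                )
            a_parts, b_parts, ids, bboxes = [], [], [], []
            for pid, poly in enumerate(polys):
                for ring in _polygon_rings_ccw(poly):
                    a_parts.append(ring[:-1])
                    b_parts.append(ring[1:])
                    ids.append(np.full(len(ring) - 1, pid))
                bboxes.append(poly.bounds)
            if a_parts:
                cache = (
                    np.vstack(a_parts),
                    np.vstack(b_parts),
                    np.concatenate(ids),
                    np.asarray(bboxes, dtype=float),
                )
            else:
                cache = (np.empty((0, 2)), np.empty((0, 2)), np.empty(0, dtype=int), np.empty((0, 4)))
            self._edge_cache[use_class] = cache
        return self._edge_cache[use_class]

    def is_empty_class(self, use_class: str) -> bool:
        return len(self.polygons[use_class]) == 0

    @property
    def is_empty(self) -> bool:
        return all(self.is_empty_class(c) for c in LANDUSE_CLASSES)


def landuse_area_in_buffer(
    layer: LandUseLayer, use_class: str, site: Site, radius_m: float
) -> float:
    """Area of the class polygons intersected with the closed disc, in m².

    Computed analytically against the true circle (chord + arc terms per
    polygon edge), so a disc wholly inside a polygon measures exactly
    ``π r²`` and a half-plane polygon through the centre exactly half that.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if layer.is_empty_class(use_class):
        return 0.0
    a, b, edge_pid, bboxes = layer._edges(use_class)
    if len(a) == 0:
        return 0.0
    near = ~(
        (bboxes[:, 0] > site.x + radius_m)
        | (bboxes[:, 2] < site.x - radius_m)
        | (bboxes[:, 1] > site.y + radius_m)
        | (bboxes[:, 3] < site.y - radius_m)
    )
    if not near.any():
        return 0.0
    mask = near[edge_pid]
    center = np.array([site.x, site.y])
    return max(0.0, _disc_polygon_area(center, radius_m, a[mask], b[mask]))


@dataclass
class RasterGrid:
    """A regular vegetation-index grid; row 0 is the southernmost row.

    ``x0, y0`` locate the lower-left corner of the grid; cell centres are at
    ``(x0 + (col+0.5)*cell, y0 + (row+0.5)*cell)``. Missing cells are NaN;
    values must lie in [-1, 1].
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1).any():
            raise ValueError("vegetation index must lie in [-1, 1]")


def raster_mean_in_buffer(raster: RasterGrid, site: Site, radius_m: float) -> float:
    """Mean of non-missing cells whose centres fall in the closed disc."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    cs = raster.cell_size
    nrow, ncol = raster.values.shape
    r0 = max(0, int(np.floor((site.y - radius_m - raster.y0) / cs - 0.5)))
    r1 = min(nrow, int(np.ceil((site.y + radius_m - raster.y0) / cs + 0.5)))
    c0 = max(0, int(np.floor((site.x - radius_m - raster.x0) / cs - 0.5)))
    c1 = min(ncol, int(np.ceil((site.x + radius_m - raster.x0) / cs + 0.5)))
    if r0 >= r1 or c0 >= c1:
        raise ValueError("buffer does not overlap the raster extent")
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    cy = raster.y0 + (rows + 0.5) * cs
    cx = raster.x0 + (cols + 0.5) * cs
    dx = cx[None, :] - site.x
    dy = cy[:, None] - site.y
    inside = dx * dx + dy * dy <= radius_m * radius_m
    vals = raster.values[r0:r1, c0:c1][inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no non-missing raster cells in buffer")
    return float(vals.mean())


@dataclass
class StudyLayers:
    """All predictor layers of one study region, in a shared metric CRS."""

    roads: RoadNetwork
    point_features: dict[str, PointFeatureSet]
    households: HouseholdLayer
    landuse: LandUseLayer
    ndvi: RasterGrid | None


@dataclass
class FeatureMatrix:
    """Sites x candidate-predictor value grid with per-column metadata."""

    df: pd.DataFrame
    variables: dict[str, CandidateVariable]

    def __post_init__(self) -> None:
        missing_meta = set(self.df.columns) - set(self.variables)
        if missing_meta:
            raise ValueError(f"columns without metadata: {sorted(missing_meta)}")
        if self.df.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def site_ids(self) -> list[str]:
        return list(self.df.index)

    def columns_for(self, names: Sequence[str]) -> pd.DataFrame:
        return self.df[list(names)]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.df[list(names)].copy(), {n: self.variables[n] for n in names}
        )


def _road_length_columns(
    sites: Sequence[Site], network: RoadNetwork, radii: Sequence[float]
) -> dict[tuple[str, float], np.ndarray]:
    """Per-class clipped lengths; composites are sums of class columns."""
    centers = np.array([[s.x, s.y] for s in sites])
    per_class: dict[tuple[str, float], np.ndarray] = {}
    for cls in ROAD_CLASSES:
        p0, p1 = network.segments((cls,))
        for r in radii:
            if len(p0) == 0:
                per_class[(cls, r)] = np.zeros(len(sites))
            else:
                per_class[(cls, r)] = np.array(
                    [
                        _clipped_segment_lengths(p0, p1, c, r).sum()
                        for c in centers
                    ]
                )
    return per_class


def build_feature_matrix(
    sites: Sequence[Site],
    layers: StudyLayers,
    variables: Sequence[CandidateVariable] | None = None,
) -> FeatureMatrix:
    """Compute every candidate predictor for every site.

    Variables whose source layer is empty are dropped with a warning so the
    matrix is always dense. Site order is preserved in the row order.
    """
    if variables is None:
        variables = table1_variables()
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate site ids")
    _check_projected(np.array([[s.x, s.y] for s in sites]), "sites")

    radii = sorted({v.buffer_m for v in variables if v.category == "roads"})
    road_cols = (
        _road_length_columns(sites, layers.roads, radii)
        if not layers.roads.is_empty
        else {}
    )

    data: dict[str, np.ndarray] = {}
    kept: dict[str, CandidateVariable] = {}
    for var in variables:
        col: np.ndarray | None = None
        if var.category == "roads":
            if layers.roads.is_empty:
                logger.warning("dropping %s: empty road network", var.name)
                continue
            classes = ROAD_COMPOSITES[var.var_type]
            col = sum(road_cols[(c, var.buffer_m)] for c in classes)
        elif var.category == "inverse_distance":
            target = var.var_type.removeprefix("inv_dist_")
            if target == "road":
                if layers.roads.is_empty:
                    logger.warning("dropping %s: empty road network", var.name)
                    continue
                col = np.array(
                    [inverse_distance_to_roads(s, layers.roads) for s in sites]
                )
            else:
                fs = layers.point_features.get(target)
                if fs is None or len(fs) == 0:
                    logger.warning("dropping %s: no %s features", var.name, target)
                    continue
                col = np.array([inverse_distance(s, fs) for s in sites])
        elif var.category == "household_density":
            if len(layers.households) == 0:
                col = np.zeros(len(sites))
            else:
                col = np.array(
                    [household_density(layers.households, s, var.buffer_m) for s in sites]
                )
        elif var.category == "landuse":
            use = var.var_type.removeprefix("landuse_")
            if layers.landuse.is_empty_class(use):
                logger.warning("dropping %s: no %s polygons", var.name, use)
                continue
            col = np.array(
                [landuse_area_in_buffer(layers.landuse, use, s, var.buffer_m) for s in sites]
            )
        elif var.category == "ndvi":
            if layers.ndvi is None:
                logger.warning("dropping %s: no vegetation raster", var.name)
                continue
            col = np.array(
                [raster_mean_in_buffer(layers.ndvi, s, var.buffer_m) for s in sites]
            )
        else:
            raise ValueError(f"unknown variable category {var.category!r}")
        data[var.name] = np.asarray(col, dtype=float)
        kept[var.name] = var

    df = pd.DataFrame(data, index=pd.Index(ids, name="site_id"))
    return FeatureMatrix(df, kept)
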