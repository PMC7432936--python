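"""Spatial containers for a study region.

A :class:`CityScene` bundles every layer the GIS predictor extraction needs:
roads with traffic counts, land-use polygons, the coastline, industrial point
sources, elevation and population rasters, and hourly meteorology per region.
Coordinates are planar projected meters throughout — buffer geometry is exact
and there is no geodesy anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .fields import RasterField

ROAD_CLASSES = ("major", "minor")
LANDUSE_CLASSES = ("industrial", "urban", "open_space", "harbor")
POLLUTANTS = ("NO2", "SO2", "PM10", "PM25")
SEASONS = ("summer", "autumn", "winter", "spring")


@dataclass(frozen=True)
class Road:
    """One road feature: a polyline with a class and daily vehicle counts."""

    road_id: str
    geometry: LineString
    road_class: str  # 'major' | 'minor'
    ldmv: float  # light-duty motor vehicles / day
    hdmv: float  # heavy-duty motor vehicles / day

    @property
    def intensity(self) -> float:
        return self.ldmv + self.hdmv


@dataclass(frozen=True)
class LandUseZone:
    zone_id: str
    geometry: Polygon
    zone_class: str  # one of LANDUSE_CLASSES


@dataclass(frozen=True)
class IndustrySource:
    name: str
    x: float
    y: float

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class WindSeries:
    """Hourly wind for one region.

    Directions use the meteorological convention: the direction the wind blows
    FROM, in degrees clockwise from north.
    """

    direction_deg: np.ndarray
    speed_ms: np.ndarray

    def __post_init__(self):
        if len(self.direction_deg) != len(self.speed_ms):
            raise ValueError("direction and speed series must be equal length")


@dataclass
class CityScene:
    """All spatial layers of a (synthetic or real) study region."""

    bounds: tuple[float, float, float, float]
    roads: list[Road]
    landuse: list[LandUseZone]
    coastline: LineString
    industries: list[IndustrySource]
    elevation: RasterField
    population: RasterField  # persons per cell
    wind: dict[str, WindSeries]  # region -> hourly series
    region_split_y: float
    crs: str = "local-projected-meters"
    construction: list | None = None  # optional construction-activity layer
    meteorology: dict = field(default_factory=dict)  # region -> DataFrame-like extras

    def region_of(self, x, y) -> str:
        return "south" if y < self.region_split_y else "north"

    def roads_of_class(self, road_class: str) -> list[Road]:
        if road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {road_class!r}")
        return [r for r in self.roads if r.road_class == road_class]

    def landuse_of_class(self, zone_class: str) -> list[LandUseZone]:
        if zone_class not in LANDUSE_CLASSES:
            raise ValueError(f"unknown land-use class {zone_class!r}")
        return [z for z in self.landuse if z.zone_class == zone_class]

    # ---- cached geometry derived from the layers -------------------------

    @cached_property
    def _segments(self) -> dict[str, dict]:
        """Per-class arrays of road segments and per-segment owning road.

        Polylines are exploded into straight segments; each segment remembers
        which road feature it belongs to so traffic counts are attributed once
        per feature.
        """
        out = {}
        for cls in ROAD_CLASSES + ("all",):
            roads = self.roads if cls == "all" else self.roads_of_class(cls)
            p0, p1, owner, ldmv, hdmv = [], [], [], [], []
            for k, road in enumerate(roads):
                xy = np.asarray(road.geometry.coords, dtype=float)
                for a, b in zip(xy[:-1], xy[1:]):
                    p0.append(a)
                    p1.append(b)
                    owner.append(k)
            out[cls] = {
                "p0": np.asarray(p0, dtype=float).reshape(-1, 2),
                "p1": np.asarray(p1, dtype=float).reshape(-1, 2),
                "owner": np.asarray(owner, dtype=int),
                "roads": roads,
            }
        return out

    def road_segments(self, road_class: str = "all") -> dict:
        return self._segments[road_class]

    @cached_property
    def road_union(self) -> MultiLineString:
        return unary_union([r.geometry for r in self.roads])

    def road_class_union(self, road_class: str):
        return unary_union([r.geometry for r in self.roads_of_class(road_class)])

    @cached_property
    def landuse_union(self) -> dict[str, object]:
        return {
            cls: unary_union([z.geometry for z in self.landuse_of_class(cls)])
            for cls in LANDUSE_CLASSES
        }

    @cached_property
    def road_intersections(self) -> np.ndarray:
        """(n, 2) array of points where distinct road features cross."""
        geoms = [r.geometry for r in self.roads]
        pts: list[tuple[float, float]] = []
        if len(geoms) > 1:
            tree = STRtree(geoms)
            for i, g in enumerate(geoms):
                for j in tree.query(g):
                    if j <= i:
                        continue
                    inter = g.intersection(geoms[j])
                    if inter.is_empty:
                        continue
                    for part in getattr(inter, "geoms", [inter]):
                        if isinstance(part, Point):
                            pts.append((part.x, part.y))
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    @cached_property
    def _road_tree(self) -> STRtree:
        return STRtree([r.geometry for r in self.roads])

    def nearest_road(self, x: float, y: float) -> tuple[Road | None, float]:
        """The road feature nearest to (x, y) and its distance in meters."""
        if not self.roads:
            return None, float("inf")
        p = Point(x, y)
        idx = self._road_tree.nearest(p)
        road = self.roads[idx]
        # STRtree.nearest is exact for distance queries in shapely 2
        return road, p.distance(road.geometry)

    def roads_within(self, x: float, y: float, radius: float) -> list[Road]:
        p = Point(x, y)
        idxs = self._road_tree.query(p.buffer(radius))
        return [self.roads[i] for i in idxs if p.distance(self.roads[i].geometry) <= radius]
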