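"""Synthetic two-region coastal city and monitoring-campaign simulator.

The generator emulates the study design the package is built around: a
coastal metropolitan area with an industrial southern region containing a
harbor and large point sources (refineries, a paper mill), and a primarily
residential northern region; between them lies a sparsely used band of open
space. A known ground-truth pollution surface (:class:`TruthModel`) drives a
simulated monitoring campaign — three seasons of 2-week passive/impactor
measurements at ~40 sites plus a continuously measured reference site — so
that every downstream stage (QA, temporal adjustment, predictor extraction,
model selection, validation) can be tested end to end with no external data.

All randomness flows through a single integer seed; identical
``(config, seed)`` pairs give byte-identical scenes, sites and records.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box

from . import geo_predictors as gp
from .errors import ConfigurationError, DataError, PlacementError, ScheduleError
from .fields import GaussianRandomField, RasterField
from .scene import (
    CityScene,
    IndustrySource,
    LandUseZone,
    POLLUTANTS,
    Road,
    SEASONS,
    WindSeries,
)

SITE_TYPES = ("regional_background", "urban", "street")


# ---------------------------------------------------------------------------
# scene configuration and generation


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic study region (planar meters)."""

    bounds: tuple[float, float, float, float] = (0.0, 0.0, 20_000.0, 30_000.0)
    region_split_y: float = 15_000.0
    n_industrial: int = 6
    n_urban_north: int = 8
    n_urban_south: int = 4
    n_open_space: int = 8
    n_major_south: int = 2
    n_major_north: int = 2
    n_minor_extra: int = 30
    raster_cell: float = 250.0
    raster_margin: float = 2_000.0  # so 2 km buffers never leave coverage
    elevation_slope: float = 0.0075  # m of altitude per m inland
    base_density: float = 80.0  # persons / km^2 outside classed zones
    urban_density: float = 2_500.0
    wind_hours: int = 8760

    def validate(self):
        x0, y0, x1, y1 = self.bounds
        if not (x1 > x0 and y1 > y0):
            raise ConfigurationError("bounds must have positive extent")
        for name in (
            "n_industrial",
            "n_urban_north",
            "n_urban_south",
            "n_open_space",
            "n_major_south",
            "n_major_north",
            "n_minor_extra",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.raster_cell <= 0:
            raise ConfigurationError("raster_cell must be positive")
        if not (y0 < self.region_split_y < y1):
            raise ConfigurationError("region_split_y must lie inside bounds")


def _rect(rng, cx, cy, w, h, bounds):
    x0, y0, x1, y1 = bounds
    g = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
    return g.intersection(box(x0, y0, x1, y1))


def generate_city(config: SceneConfig | None = None, seed: int = 1) -> CityScene:
    """Generate a reproducible synthetic study region.

    Deterministic given ``(config, seed)``. The southern sub-region contains
    the harbor polygon and the industrial zones; the north is residential;
    elevation rises with distance from the coastline (east edge).
    """
    cfg = config or SceneConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = cfg.bounds
    split = cfg.region_split_y

    coastline = LineString([(x1, y0), (x1, y1)])

    landuse: list[LandUseZone] = []
    # harbor: against the coast at the north end of the southern region
    hw = rng.uniform(1400, 1900)
    hh = rng.uniform(1800, 2400)
    harbor_cy = split - 2600 + rng.uniform(-300, 300)
    harbor = _rect(rng, x1 - hw / 2, harbor_cy, hw, hh, cfg.bounds)
    landuse.append(LandUseZone("harbor_0", harbor, "harbor"))

    for k in range(cfg.n_industrial):
        cx = rng.uniform(x1 - 6500, x1 - 1200)
        cy = rng.uniform(y0 + 1500, split - 4000)
        g = _rect(rng, cx, cy, rng.uniform(700, 1600), rng.uniform(700, 1600), cfg.bounds)
        landuse.append(LandUseZone(f"industrial_{k}", g, "industrial"))

    n_urb = 0
    for k in range(cfg.n_urban_north):
        cx = rng.uniform(x0 + 3000, x1 - 2500)
        cy = rng.uniform(split + 3500, y1 - 1200)
        g = _rect(rng, cx, cy, rng.uniform(1200, 2600), rng.uniform(1200, 2600), cfg.bounds)
        landuse.append(LandUseZone(f"urban_{n_urb}", g, "urban"))
        n_urb += 1
    for k in range(cfg.n_urban_south):
        cx = rng.uniform(x0 + 4000, x1 - 7500)
        cy = rng.uniform(y0 + 1500, split - 3000)
        g = _rect(rng, cx, cy, rng.uniform(1200, 2400), rng.uniform(1200, 2400), cfg.bounds)
        landuse.append(LandUseZone(f"urban_{n_urb}", g, "urban"))
        n_urb += 1

    # the band between the regions is open space, plus scattered parks
    landuse.append(
        LandUseZone(
            "open_space_band",
            box(x0 + 1000, split - 1500, x1 - 500, split + 2500),
            "open_space",
        )
    )
    for k in range(cfg.n_open_space):
        cx = rng.uniform(x0 + 1000, x1 - 1000)
        cy = rng.uniform(y0 + 1000, y1 - 1000)
        g = _rect(rng, cx, cy, rng.uniform(500, 1500), rng.uniform(500, 1500), cfg.bounds)
        landuse.append(LandUseZone(f"open_space_{k}", g, "open_space"))

    roads: list[Road] = []

    def add_road(name, pts, cls, ldmv, hdmv_share):
        roads.append(Road(name, LineString(pts), cls, float(ldmv), float(ldmv * hdmv_share)))

    hwy_x = x1 - rng.uniform(2200, 3200)
    add_road("hwy_coastal", [(hwy_x, y0), (hwy_x, y1)], "major", rng.uniform(35000, 60000), 0.12)
    for k in range(cfg.n_major_south):
        yy = rng.uniform(y0 + 2500, split - 3500)
        add_road(f"maj_s{k}", [(x0 + 800, yy), (hwy_x, yy)], "major", rng.uniform(18000, 45000), 0.15)
    for k in range(cfg.n_major_north):
        yy = rng.uniform(split + 3500, y1 - 2000)
        add_road(f"maj_n{k}", [(x0 + 800, yy), (hwy_x, yy)], "major", rng.uniform(18000, 45000), 0.10)
    # harbor access road: heavy-duty corridor
    add_road(
        "maj_harbor",
        [(hwy_x, harbor_cy), (x1 - 300, harbor_cy)],
        "major",
        rng.uniform(15000, 30000),
        0.30,
    )

    n_min = 0
    for z in landuse:
        if z.zone_class != "urban" or z.geometry.is_empty:
            continue
        bx0, by0, bx1, by1 = z.geometry.bounds
        for fx in (0.33, 0.67):
            xx = bx0 + fx * (bx1 - bx0)
            add_road(f"min_{n_min}", [(xx, by0), (xx, by1)], "minor", rng.uniform(400, 6000), 0.06)
            n_min += 1
        for fy in (0.33, 0.67):
            yy = by0 + fy * (by1 - by0)
            add_road(f"min_{n_min}", [(bx0, yy), (bx1, yy)], "minor", rng.uniform(400, 6000), 0.06)
            n_min += 1
    for k in range(cfg.n_minor_extra):
        south = k % 2 == 0
        cx = rng.uniform(x0 + 1000, x1 - 1000)
        cy = rng.uniform(y0 + 1000, split - 1000) if south else rng.uniform(split + 1000, y1 - 1000)
        length = rng.uniform(800, 2500)
        if rng.random() < 0.5:
            pts = [(cx - length / 2, cy), (cx + length / 2, cy)]
        else:
            pts = [(cx, cy - length / 2), (cx, cy + length / 2)]
        add_road(f"min_{n_min}", pts, "minor", rng.uniform(300, 6000), 0.06)
        n_min += 1

    industries = []
    ind_zones = [z for z in landuse if z.zone_class == "industrial" and not z.geometry.is_empty]
    for name, z in zip(("refinery_a", "refinery_b", "paper_mill"), ind_zones):
        c = z.geometry.centroid
        industries.append(IndustrySource(name, c.x, c.y))

    # rasters extend `raster_margin` past the bounds so 2 km buffers at
    # coastal receptors stay covered
    m = cfg.raster_margin
    cell = cfg.raster_cell
    rx0, ry0 = x0 - m, y0 - m
    ncols = int(np.ceil((x1 - x0 + 2 * m) / cell))
    nrows = int(np.ceil((y1 - y0 + 2 * m) / cell))
    cxs = rx0 + (np.arange(ncols) + 0.5) * cell
    cys = ry0 + (np.arange(nrows) + 0.5) * cell
    gx, gy = np.meshgrid(cxs, cys)

    elev = cfg.elevation_slope * np.maximum(x1 - gx, 0.0)
    for _ in range(4):
        bx = rng.uniform(x0, x1 - 4000)
        by = rng.uniform(y0, y1)
        amp = rng.uniform(10, 40)
        rad = rng.uniform(1500, 4000)
        elev = elev + amp * np.exp(-((gx - bx) ** 2 + (gy - by) ** 2) / (2 * rad**2))
    elevation = RasterField(rx0, ry0, cell, np.maximum(elev, 0.0))

    import shapely

    dens = np.full(gx.shape, cfg.base_density)
    for cls, d in (
        ("open_space", 15.0),
        ("industrial", 30.0),
        ("harbor", 5.0),
        ("urban", cfg.urban_density),
    ):
        geoms = [z.geometry for z in landuse if z.zone_class == cls and not z.geometry.is_empty]
        if geoms:
            from shapely.ops import unary_union

            u = unary_union(geoms)
            mask = shapely.contains_xy(u, gx.ravel(), gy.ravel()).reshape(gx.shape)
            dens[mask] = d
    inside = (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
    dens = dens * np.exp(rng.normal(0.0, 0.25, size=dens.shape))
    dens[~inside] = 0.0
    population = RasterField(rx0, ry0, cell, dens * (cell / 1000.0) ** 2)

    wind = {}
    met = {}
    for region, weights in (("south", (0.5, 0.5)), ("north", (0.55, 0.45))):
        comp = rng.random(cfg.wind_hours) < weights[0]
        d_ne = np.degrees(rng.vonmises(np.radians(45.0), 4.0, cfg.wind_hours)) % 360
        d_sw = np.degrees(rng.vonmises(np.radians(225.0), 4.0, cfg.wind_hours)) % 360
        direction = np.where(comp, d_ne, d_sw)
        speed = rng.gamma(2.0, 1.8, cfg.wind_hours) + 0.5
        wind[region] = WindSeries(direction, speed)
        hours = np.arange(cfg.wind_hours)
        met[region] = {
            "temperature": 20.5
            + 4.0 * np.sin(2 * np.pi * hours / 8760)
            + rng.normal(0, 1.5, cfg.wind_hours),
            "humidity": np.clip(
                70 + 10 * np.sin(2 * np.pi * hours / 8760 + 1.0) + rng.normal(0, 6, cfg.wind_hours),
                5,
                100,
            ),
        }

    return CityScene(
        bounds=cfg.bounds,
        roads=roads,
        landuse=[z for z in landuse if not z.geometry.is_empty],
        coastline=coastline,
        industries=industries,
        elevation=elevation,
        population=population,
        wind=wind,
        region_split_y=split,
        meteorology=met,
    )


# ---------------------------------------------------------------------------
# monitoring sites


@dataclass(frozen=True)
class MonitoringSite:
    id: str
    x: float
    y: float
    region: str  # 'north' | 'south'
    site_type: str  # one of SITE_TYPES
    measures: frozenset = frozenset({"gas"})
    reference: bool = False


@dataclass(frozen=True)
class SiteVerdict:
    ok: bool
    violations: tuple[str, ...]


def validate_site(
    location,
    site_type: str,
    scene: CityScene,
    *,
    intersection_dist: float = 25.0,
    roadside_dist: float = 2.0,
    construction_dist: float = 100.0,
    urban_max_traffic: float = 3000.0,
    urban_traffic_dist: float = 50.0,
    urban_source_dist: float = 100.0,
    street_min_intensity: float = 10_000.0,
) -> SiteVerdict:
    """Check a candidate monitoring location against the siting criteria.

    Universal rules: at least 25 m from any traffic intersection, at least
    2 m from the roadside, and at least 100 m from construction activity (if
    a construction layer is present). Urban sites additionally require no
    road carrying more than 3000 vehicles/day within 50 m and no key source
    (industry point, industrial or harbor zone) within 100 m. Street sites
    require the nearest road to carry more than 10,000 vehicles/day.
    """
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site type {site_type!r}")
    x, y = location
    violations: list[str] = []

    ints = scene.road_intersections
    if len(ints):
        d = np.hypot(ints[:, 0] - x, ints[:, 1] - y).min()
        if d < intersection_dist:
            violations.append("intersection-25m")
    _, d_road = scene.nearest_road(x, y)
    if d_road < roadside_dist:
        violations.append("roadside-2m")
    if scene.construction:
        p = Point(x, y)
        if any(p.distance(g) < construction_dist for g in scene.construction):
            violations.append("construction-100m")

    if site_type == "urban":
        busy = [
            r
            for r in scene.roads_within(x, y, urban_traffic_dist)
            if r.intensity > urban_max_traffic
        ]
        if busy:
            violations.append("urban-traffic-3000-50m")
        p = Point(x, y)
        source_hit = any(
            p.distance(ind.point) < urban_source_dist for ind in scene.industries
        )
        for cls in ("industrial", "harbor"):
            u = scene.landuse_union[cls]
            if not u.is_empty and p.distance(u) < urban_source_dist:
                source_hit = True
        if source_hit:
            violations.append("urban-source-100m")
    elif site_type == "street":
        road, _ = scene.nearest_road(x, y)
        if road is None or road.intensity <= street_min_intensity:
            violations.append("street-10000")

    return SiteVerdict(not violations, tuple(violations))


def _apportion(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among keys by weight."""
    total = sum(weights.values())
    raw = {k: n * w / total for k, w in weights.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    left = n - sum(base.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - base[k]), k)):
        if left <= 0:
            break
        base[k] += 1
        left -= 1
    return base


DEFAULT_TYPE_MIX = {"regional_background": 0.12, "urban": 0.53, "street": 0.35}


def place_sites(
    scene: CityScene,
    n_gas: int = 41,
    n_pm: int = 21,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    *,
    south_fraction: float = 23 / 40,
    include_reference: bool | None = None,
    min_spacing: float = 150.0,
    max_tries: int = 600,
) -> list[MonitoringSite]:
    """Place monitoring sites that all pass :func:`validate_site`.

    Defaults mirror the campaign the package emulates: 41 gas sites (23
    south, 17 north, plus one reference between the regions) of which 21 also
    measure PM (11 south, 9 north, plus the reference). PM sites are a subset
    of the gas sites.
    """
    if n_pm > n_gas:
        raise ConfigurationError("n_pm cannot exceed n_gas")
    mix = dict(mix or DEFAULT_TYPE_MIX)
    rng = np.random.default_rng(seed)
    if include_reference is None:
        include_reference = n_gas > 1
    n_field = n_gas - (1 if include_reference else 0)
    n_south = int(round(n_field * south_fraction))
    n_north = n_field - n_south

    x0, y0, x1, y1 = scene.bounds
    split = scene.region_split_y
    placed: list[MonitoringSite] = []

    def far_enough(x, y):
        return all(np.hypot(s.x - x, s.y - y) >= min_spacing for s in placed)

    def candidate(region: str, site_type: str):
        ylo, yhi = (y0 + 300, split - 300) if region == "south" else (split + 300, y1 - 300)
        if site_type == "street":
            busy = [
                r
                for r in scene.roads
                if r.intensity > 10_000
                and not r.geometry.buffer(1).intersection(box(x0, ylo, x1, yhi)).is_empty
            ]
            if not busy:
                return None
            road = busy[rng.integers(len(busy))]
            t = rng.uniform(0.05, 0.95)
            p = road.geometry.interpolate(t, normalized=True)
            # step a few meters off the carriageway, perpendicular-ish
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(3.0, 15.0)
            return p.x + off * np.cos(ang), p.y + off * np.sin(ang)
        if site_type == "urban":
            zones = [
                z
                for z in scene.landuse
                if z.zone_class == "urban"
                and ylo <= z.geometry.centroid.y <= yhi
            ]
            if not zones:
                return None
            z = zones[rng.integers(len(zones))]
            bx0, by0, bx1, by1 = z.geometry.bounds
            for _ in range(10):
                xx, yy = rng.uniform(bx0, bx1), rng.uniform(by0, by1)
                if z.geometry.contains(Point(xx, yy)):
                    return xx, yy
            return None
        # regional background: away from any road and from sources
        for _ in range(10):
            xx = rng.uniform(x0 + 500, x1 - 500)
            yy = rng.uniform(ylo, yhi)
            _, d_road = scene.nearest_road(xx, yy)
            if d_road < 300:
                continue
            p = Point(xx, yy)
            if any(p.distance(i.point) < 500 for i in scene.industries):
                continue
            return xx, yy
        return None

    def place_one(region, site_type, site_id, measures, reference=False):
        for _ in range(max_tries):
            c = candidate(region, site_type)
            if c is None:
                continue
            xx, yy = c
            if not (x0 <= xx <= x1 and y0 <= yy <= y1):
                continue
            if not far_enough(xx, yy):
                continue
            if validate_site((xx, yy), site_type, scene).ok:
                site = MonitoringSite(
                    site_id, float(xx), float(yy), region, site_type, measures, reference
                )
                placed.append(site)
                return site
        raise PlacementError(
            f"could not place a {site_type} site in {region} after {max_tries} tries"
        )

    counts = {
        "south": _apportion(n_south, mix),
        "north": _apportion(n_north, mix),
    }
    ids = {"south": iter(f"S{k:02d}" for k in range(1, 99)), "north": iter(f"N{k:02d}" for k in range(1, 99))}
    for region in ("south", "north"):
        for site_type in SITE_TYPES:
            for _ in range(counts[region].get(site_type, 0)):
                place_one(region, site_type, next(ids[region]), frozenset({"gas"}))

    if include_reference:
        # the reference site sits between the regions, urban-background-like
        for _ in range(max_tries):
            xx = rng.uniform(x0 + 2000, x1 - 3000)
            yy = rng.uniform(split - 1500, split + 1500)
            if not far_enough(xx, yy):
                continue
            if validate_site((xx, yy), "urban", scene).ok:
                placed.append(
                    MonitoringSite(
                        "REF",
                        float(xx),
                        float(yy),
                        scene.region_of(xx, yy),
                        "urban",
                        frozenset({"gas", "pm"}),
                        reference=True,
                    )
                )
                break
        else:
            raise PlacementError("could not place the reference site")

    # PM subset: spread across each region in placement order
    n_pm_field = n_pm - (1 if include_reference else 0)
    n_pm_south = int(round(n_pm_field * 11 / 20)) if n_pm_field else 0
    n_pm_north = n_pm_field - n_pm_south
    out: list[MonitoringSite] = []
    taken = {"south": 0, "north": 0}
    want = {"south": n_pm_south, "north": n_pm_north}
    for s in placed:
        if s.reference:
            out.append(s)
        elif taken[s.region] < want[s.region]:
            out.append(replace(s, measures=frozenset({"gas", "pm"})))
            taken[s.region] += 1
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class PollutantTruth:
    """Generating model for one pollutant's true concentration surface."""

    baseline: float  # ug/m3 at zero covariates, annual scale
    coefs: dict[str, float]  # predictor-name -> coefficient
    spatial_sd: float  # marginal SD of the correlated spatial noise
    spatial_range: float  # e-folding range of its exponential covariance, m
    meas_sd: float  # measurement noise SD per 2-week record
    temporal_sd: float  # SD of the shared city-wide per-period deviation
    season_mult: dict[str, float]  # season -> multiplier (annual ~ mean 1)
    blank_mean: float = 0.2
    blank_sd: float = 0.05

    def __post_init__(self):
        if self.baseline <= 0:
            raise ConfigurationError("baseline must be positive")
        if any(m <= 0 for m in self.season_mult.values()):
            raise ConfigurationError("seasonal multipliers must be positive")

    def multiplier(self, period: str) -> float:
        if period == "annual":
            return float(np.mean([self.season_mult[s] for s in SEASONS]))
        try:
            return self.season_mult[period]
        except KeyError as exc:
            raise KeyError(f"unknown period {period!r}") from exc


@dataclass(frozen=True)
class TruthModel:
    pollutants: dict[str, PollutantTruth]
    seasonal_mode: str = "multiplicative"  # or 'additive'

    def __post_init__(self):
        if self.seasonal_mode not in ("multiplicative", "additive"):
            raise ConfigurationError(f"bad seasonal_mode {self.seasonal_mode!r}")

    def noiseless(self) -> "TruthModel":
        """Copy with all noise sources (spatial, measurement, temporal) off."""
        return TruthModel(
            {
                p: replace(t, spatial_sd=0.0, meas_sd=0.0, temporal_sd=0.0, blank_sd=0.0)
                for p, t in self.pollutants.items()
            },
            self.seasonal_mode,
        )


def default_truth_model() -> TruthModel:
    """Defaults calibrated to the seasonal contrasts of the emulated campaign.

    Winter/summer multiplier ratios: NO2 ~2.5, SO2 ~1.5, PM10 ~2.5, PM2.5
    ~2.0; spring sits near the annual level; the autumn multiplier closes the
    four-season mean to ~1 so the baseline is the annual level. Coefficients
    act on named predictors of the default grid with signs that agree with
    the a-priori direction-of-effect table.
    """
    return TruthModel(
        {
            "NO2": PollutantTruth(
                baseline=13.0,
                coefs={
                    "major_length_300": 8.0e-3,
                    "harbor_2000": 8.0e-7,
                    "industrial_500": 2.0e-6,
                    "elevation": -3.0e-2,
                    "population_1000": 2.0e-4,
                },
                spatial_sd=1.6,
                spatial_range=4000.0,
                meas_sd=1.2,
                temporal_sd=1.5,
                season_mult={"summer": 0.62, "winter": 1.52, "spring": 1.20, "autumn": 0.66},
            ),
            "SO2": PollutantTruth(
                baseline=2.4,
                coefs={"industrial_500": 6.0e-6, "ldmv_100": 2.0e-5},
                spatial_sd=0.45,
                spatial_range=3500.0,
                meas_sd=0.35,
                temporal_sd=0.4,
                season_mult={"summer": 0.82, "winter": 1.24, "spring": 0.97, "autumn": 0.97},
                blank_mean=0.1,
                blank_sd=0.03,
            ),
            "PM10": PollutantTruth(
                baseline=30.0,
                coefs={
                    "major_length_1000": 3.0e-3,
                    "elevation": -6.0e-2,
                    "population_2000": 2.0e-4,
                },
                spatial_sd=4.0,
                spatial_range=4500.0,
                meas_sd=3.0,
                temporal_sd=4.0,
                season_mult={"summer": 0.56, "winter": 1.37, "spring": 1.05, "autumn": 1.02},
                blank_mean=0.5,
                blank_sd=0.15,
            ),
            "PM25": PollutantTruth(
                baseline=9.0,
                coefs={
                    "open_space_100": -8.0e-5,
                    "ldmv_100": 3.0e-5,
                    "population_2000": 8.0e-5,
                    "major_length_500": 1.2e-3,
                },
                spatial_sd=1.6,
                spatial_range=4000.0,
                meas_sd=1.1,
                temporal_sd=1.2,
                season_mult={"summer": 0.69, "winter": 1.38, "spring": 0.93, "autumn": 1.00},
                blank_mean=0.3,
                blank_sd=0.08,
            ),
        }
    )


class TruthRealization:
    """One realized truth: the deterministic surface plus a frozen spatial
    noise field per pollutant. Field evaluations at a fixed set of coordinates
    are cached, so repeated campaign draws are cheap."""

    def __init__(self, scene: CityScene, truth: TruthModel, seed: int = 0, quad_segs: int = 256):
        self.scene = scene
        self.truth = truth
        self.quad_segs = quad_segs
        self._spatial_cache: dict = {}
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self.grf: dict[str, GaussianRandomField] = {}
        for p, child in zip(POLLUTANTS, ss.spawn(len(POLLUTANTS))):
            t = truth.pollutants.get(p)
            if t is None:
                continue
            self.grf[p] = GaussianRandomField.realize(
                scene.bounds, t.spatial_sd, t.spatial_range, np.random.default_rng(child)
            )

    def _fields_at(self, names: tuple[str, ...], xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        key = (names, xs.tobytes(), ys.tobytes())
        got = self._spatial_cache.get(key)
        if got is None:
            grid = {s.name: s for s in gp.default_predictor_grid()}
            cols = []
            for name in names:
                spec = grid[name]
                cols.append(
                    [
                        gp.evaluate_spec(spec, (x, y), self.scene, self.quad_segs)
                        for x, y in zip(xs, ys)
                    ]
                )
            got = np.asarray(cols, dtype=float)
            self._spatial_cache[key] = got
        return got

    def deterministic(self, pollutant: str, xs, ys) -> np.ndarray:
        """baseline + sum(coef * field) at the given coordinates (annual scale)."""
        t = self.truth.pollutants[pollutant]
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        names = tuple(t.coefs)
        vals = np.full(len(xs), t.baseline)
        if names:
            F = self._fields_at(names, xs, ys)
            vals = vals + np.asarray(list(t.coefs.values())) @ F
        return vals

    def spatial(self, pollutant: str, xs, ys, period: str = "annual", noise: bool = True):
        """Seasonal true concentration (no temporal/measurement noise)."""
        t = self.truth.pollutants[pollutant]
        m = t.multiplier(period)
        det = self.deterministic(pollutant, xs, ys)
        if self.truth.seasonal_mode == "multiplicative":
            out = m * det
        else:  # additive: season scales the baseline only
            out = det + (m - 1.0) * t.baseline
        if noise:
            xs = np.atleast_1d(np.asarray(xs, dtype=float))
            ys = np.atleast_1d(np.asarray(ys, dtype=float))
            out = out + self.grf[pollutant].sample(xs, ys)
        return out


def true_concentration(
    scene: CityScene,
    truth: TruthModel,
    pollutant: str,
    period: str,
    location,
    realization: TruthRealization | None = None,
    noise: bool = True,
) -> float:
    """True concentration (ug/m3) at one location for one period.

    ``period`` is a season name or ``'annual'``. With ``noise=True`` a
    :class:`TruthRealization` supplies the frozen spatially correlated noise
    field; without one, a zero-noise realization is built on the fly.
    """
    if pollutant not in truth.pollutants:
        raise KeyError(f"unknown pollutant {pollutant!r}")
    x0, y0, x1, y1 = scene.bounds
    x, y = location
    if not (x0 <= x <= x1 and y0 <= y <= y1):
        raise ValueError("location outside scene bounds")
    if realization is None:
        realization = TruthRealization(scene, truth.noiseless() if not noise else truth, seed=0)
    vals = realization.spatial(pollutant, [x], [y], period, noise=noise)
    return float(vals[0])


# ---------------------------------------------------------------------------
# campaign schedule and simulation


@dataclass(frozen=True)
class Period:
    period_id: int
    start: dt.date
    end: dt.date  # inclusive of start, exclusive of end
    season: str


def _season_of(date: dt.date) -> str:
    # southern hemisphere
    return {
        12: "summer", 1: "summer", 2: "summer",
        3: "autumn", 4: "autumn", 5: "autumn",
        6: "winter", 7: "winter", 8: "winter",
        9: "spring", 10: "spring", 11: "spring",
    }[date.month]


@dataclass(frozen=True)
class CampaignSchedule:
    """The calendar of the campaign: a year of contiguous 2-week periods at
    the reference site; field sites measure one period per scheduled season,
    staggered across the season's periods (samplers rotate between sites with
    breaks in between)."""

    year_start: dt.date = dt.date(2015, 7, 1)
    period_days: int = 14
    n_periods: int = 26
    measured_seasons: tuple[str, ...] = ("winter", "spring", "summer")

    def periods(self) -> list[Period]:
        out = []
        for k in range(self.n_periods):
            start = self.year_start + dt.timedelta(days=k * self.period_days)
            end = start + dt.timedelta(days=self.period_days)
            out.append(Period(k, start, end, _season_of(start)))
        return out

    def assign(self, sites) -> dict[str, dict[str, int]]:
        """site id -> {season -> period_id}; round-robin within each season."""
        periods = self.periods()
        by_season: dict[str, list[int]] = {}
        for p in periods:
            by_season.setdefault(p.season, []).append(p.period_id)
        out: dict[str, dict[str, int]] = {}
        for k, s in enumerate(sites):
            if s.reference:
                continue
            out[s.id] = {}
            for season in self.measured_seasons:
                pool = by_season.get(season)
                if not pool:
                    raise ScheduleError(f"schedule has no periods in {season}")
                out[s.id][season] = pool[k % len(pool)]
        return out


@dataclass
class ReferenceSeries:
    """Contiguous period means spanning one year at the reference site."""

    pollutant: str
    period_ids: np.ndarray
    starts: list
    ends: list
    seasons: list
    values: np.ndarray

    @property
    def annual_mean(self) -> float:
        return float(np.mean(self.values))

    def season_mean(self, season: str) -> float:
        mask = np.asarray([s == season for s in self.seasons])
        if not mask.any():
            raise KeyError(f"reference series has no {season!r} periods")
        return float(np.mean(self.values[mask]))

    def scope_mean(self, scope: str) -> float:
        return self.annual_mean if scope == "annual" else self.season_mean(scope)

    def value_for(self, period_id: int) -> float:
        idx = np.nonzero(self.period_ids == period_id)[0]
        if len(idx) == 0:
            raise KeyError(f"no reference period {period_id}")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_id": self.period_ids,
                "start": self.starts,
                "end": self.ends,
                "season": self.seasons,
                "value_ugm3": self.values,
            }
        )


@dataclass
class CampaignResult:
    records: pd.DataFrame
    references: dict[str, ReferenceSeries]
    schedule: CampaignSchedule
    realization: TruthRealization
    true_means: pd.DataFrame  # site x pollutant x scope ground truth

    def reference_site(self, sites):
        for s in sites:
            if s.reference:
                return s
        return None


RECORD_COLUMNS = [
    "site_id", "region", "site_type", "pollutant", "period_id", "season",
    "start", "end", "value_ugm3", "true_ugm3", "flag",
]


def simulate_campaign(
    scene: CityScene,
    truth: TruthModel,
    sites,
    schedule: CampaignSchedule | None = None,
    seed: int = 0,
    dropout_rate: float = 0.025,
    realization: TruthRealization | None = None,
) -> CampaignResult:
    """Simulate the monitoring campaign over the scheduled year.

    Every non-reference site receives one 2-week mean per measured season
    (true seasonal concentration + shared per-period deviation + measurement
    noise); the reference site is measured in every period and additionally
    yields one field blank and one duplicate per pollutant per period. A
    small dropout fraction of field records is flagged stolen/outlier
    (default 2.5%).
    """
    schedule = schedule or CampaignSchedule()
    periods = schedule.periods()
    if schedule.n_periods * schedule.period_days < 364:
        raise ScheduleError("reference coverage must span one year")
    assignment = schedule.assign(sites)
    for sid, season_map in assignment.items():
        if len(set(season_map.values())) != len(season_map):
            raise ScheduleError(f"site {sid} has overlapping period assignments")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_real, s_tau, s_meas, s_drop, s_qa = ss.spawn(5)
    if realization is None:
        realization = TruthRealization(scene, truth, seed=s_real)
    rng_tau = np.random.default_rng(s_tau)
    rng_meas = np.random.default_rng(s_meas)
    rng_drop = np.random.default_rng(s_drop)
    rng_qa = np.random.default_rng(s_qa)

    ref_site = next((s for s in sites if s.reference), None)
    pollutants = [p for p in POLLUTANTS if p in truth.pollutants]
    tau = {
        p: rng_tau.normal(0.0, truth.pollutants[p].temporal_sd, len(periods))
        for p in pollutants
    }
    period_by_id = {p.period_id: p for p in periods}

    xs = np.asarray([s.x for s in sites])
    ys = np.asarray([s.y for s in sites])
    site_index = {s.id: k for k, s in enumerate(sites)}
    # per-pollutant per-season true surfaces at the sites, computed once
    season_true = {
        p: {
            season: realization.spatial(p, xs, ys, season)
            for season in SEASONS
        }
        for p in pollutants
    }

    rows = []
    references: dict[str, ReferenceSeries] = {}
    for p in pollutants:
        t = truth.pollutants[p]
        gas_or_pm = "pm" if p.startswith("PM") else "gas"
        for s in sites:
            if s.reference or gas_or_pm not in s.measures:
                continue
            k = site_index[s.id]
            for season, pid in assignment[s.id].items():
                per = period_by_id[pid]
                true_val = season_true[p][season][k] + tau[p][pid]
                val = true_val + rng_meas.normal(0.0, t.meas_sd)
                flag = ""
                if dropout_rate and rng_drop.random() < dropout_rate:
                    if rng_drop.random() < 0.5:
                        flag, val = "stolen", np.nan
                    else:
                        flag, val = "outlier", val * rng_drop.uniform(3.0, 6.0)
                if flag == "" and val < 0:
                    val = 0.0  # samplers cannot report negative mass
                rows.append(
                    (s.id, s.region, s.site_type, p, pid, season, per.start, per.end,
                     val, true_val, flag)
                )
        if ref_site is not None:
            kref = site_index[ref_site.id]
            ref_vals = []
            for per in periods:
                true_val = season_true[p][per.season][kref] + tau[p][per.period_id]
                val = max(true_val + rng_meas.normal(0.0, t.meas_sd), 0.0)
                ref_vals.append(val)
                rows.append(
                    (ref_site.id, ref_site.region, ref_site.site_type, p,
                     per.period_id, per.season, per.start, per.end, val, true_val, "")
                )
                dup = max(val + rng_qa.normal(0.0, t.meas_sd), 0.0)
                rows.append(
                    (ref_site.id, ref_site.region, ref_site.site_type, p,
                     per.period_id, per.season, per.start, per.end, dup, true_val,
                     "duplicate")
                )
                blank = abs(rng_qa.normal(t.blank_mean, t.blank_sd))
                rows.append(
                    (ref_site.id, ref_site.region, ref_site.site_type, p,
                     per.period_id, per.season, per.start, per.end, blank, 0.0,
                     "blank")
                )
            references[p] = ReferenceSeries(
                p,
                np.asarray([per.period_id for per in periods]),
                [per.start for per in periods],
                [per.end for per in periods],
                [per.season for per in periods],
                np.asarray(ref_vals),
            )

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)

    # ground-truth scope means per site (for validation of the adjustment)
    mult_bar = {
        p: {per.period_id: truth.pollutants[p].multiplier(per.season) for per in periods}
        for p in pollutants
    }
    tm_rows = []
    for p in pollutants:
        t = truth.pollutants[p]
        det = realization.deterministic(p, xs, ys)
        grf = realization.grf[p].sample(xs, ys)
        for scope in ("annual",) + tuple(SEASONS):
            pids = [per.period_id for per in periods if scope == "annual" or per.season == scope]
            ms = np.asarray([mult_bar[p][pid] for pid in pids])
            taus = np.asarray([tau[p][pid] for pid in pids])
            if truth.seasonal_mode == "multiplicative":
                base = np.mean(ms) * det
            else:
                base = det + (np.mean(ms) - 1.0) * t.baseline
            vals = base + grf + taus.mean()
            for s in sites:
                tm_rows.append((s.id, p, scope, float(vals[site_index[s.id]])))
    true_means = pd.DataFrame(tm_rows, columns=["site_id", "pollutant", "scope", "true_ugm3"])

    return CampaignResult(records, references, schedule, realization, true_means)
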