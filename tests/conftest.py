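import numpy as np
import pytest
from shapely.geometry import LineString, box

from airlur import (
    CityScene,
    IndustrySource,
    LandUseZone,
    RasterField,
    Road,
    SceneConfig,
    WindSeries,
    build_predictor_matrix,
    default_truth_model,
    generate_city,
    place_sites,
    run_study,
    simulate_campaign,
)


def make_toy_scene(
    *,
    roads=(),
    landuse=(),
    industries=(),
    bounds=(0.0, 0.0, 10_000.0, 10_000.0),
    margin=3_000.0,
    cell=100.0,
    pop_per_m2=0.0,
    pop_cells=None,
    elev=0.0,
    wind_dirs=None,
    wind_speeds=None,
    coastline=None,
    split=None,
):
    """Minimal hand-built scene for geometric oracle tests.

    ``elev`` may be a constant or a callable of (x, y) cell-center arrays;
    ``pop_cells`` overrides individual raster cells with explicit counts.
    """
    x0, y0, x1, y1 = bounds
    split = split if split is not None else (y0 + y1) / 2
    ncols = int(np.ceil((x1 - x0 + 2 * margin) / cell))
    nrows = int(np.ceil((y1 - y0 + 2 * margin) / cell))
    rx0, ry0 = x0 - margin, y0 - margin
    cxs = rx0 + (np.arange(ncols) + 0.5) * cell
    cys = ry0 + (np.arange(nrows) + 0.5) * cell
    gx, gy = np.meshgrid(cxs, cys)
    if callable(elev):
        ev = np.asarray(elev(gx, gy), dtype=float)
    else:
        ev = np.full(gx.shape, float(elev))
    pv = np.full(gx.shape, float(pop_per_m2) * cell * cell)
    if pop_cells:
        pv[:] = 0.0
        for (i, j), count in pop_cells.items():
            pv[i, j] = count
    dirs = np.asarray(wind_dirs if wind_dirs is not None else [0.0], dtype=float)
    speeds = np.asarray(
        wind_speeds if wind_speeds is not None else np.full(len(dirs), 3.0), dtype=float
    )
    wind = WindSeries(dirs, speeds)
    return CityScene(
        bounds=bounds,
        roads=list(roads),
        landuse=list(landuse),
        coastline=coastline or LineString([(x1, y0), (x1, y1)]),
        industries=list(industries),
        elevation=RasterField(rx0, ry0, cell, ev),
        population=RasterField(rx0, ry0, cell, pv),
        wind={"south": wind, "north": wind},
        region_split_y=split,
    )


def road(road_id, pts, cls="major", ldmv=20_000.0, hdmv=0.0):
    return Road(road_id, LineString(pts), cls, ldmv, hdmv)


def zone(zone_id, x0, y0, x1, y1, cls="industrial"):
    return LandUseZone(zone_id, box(x0, y0, x1, y1), cls)


@pytest.fixture(scope="session")
def scene():
    return generate_city(SceneConfig(), seed=1)


@pytest.fixture(scope="session")
def truth():
    return default_truth_model()


@pytest.fixture(scope="session")
def sites(scene):
    return place_sites(scene, seed=3)


@pytest.fixture(scope="session")
def campaign(scene, truth, sites):
    return simulate_campaign(scene, truth, sites, seed=7)


@pytest.fixture(scope="session")
def matrix(scene, sites):
    return build_predictor_matrix(sites, scene, quad_segs=256)


@pytest.fixture(scope="session")
def study():
    return run_study(seed=1)
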