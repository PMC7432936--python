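"""Plain-text import/export of scenes and measurements.

Vector layers travel as GeoJSON FeatureCollections, rasters as ESRI ASCII
grids, meteorology and measurements as CSV. The measurement schema is
``site_id, pollutant, period_id, start, end, value_ugm3, flag``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .fields import RasterField
from .scene import CityScene, IndustrySource, LandUseZone, Road, WindSeries


def _feature(geom, props):
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def _collection(features):
    return {"type": "FeatureCollection", "features": features}


def write_ascii_grid(raster: RasterField, path):
    """ESRI ASCII grid; rows are written north to south as the format requires."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x0}\n")
        fh.write(f"yllcorner {raster.y0}\n")
        fh.write(f"cellsize {raster.cell}\n")
        fh.write("NODATA_value -9999\n")
        for row in raster.values[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> RasterField:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))[::-1]
    return RasterField(header["xllcorner"], header["yllcorner"], header["cellsize"], values)


def export_scene(scene: CityScene, out_dir):
    """Write every scene layer to ``out_dir`` as GeoJSON / ASCII grid / CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "roads.geojson").write_text(
        json.dumps(
            _collection(
                [
                    _feature(
                        r.geometry,
                        {"road_id": r.road_id, "class": r.road_class, "ldmv": r.ldmv, "hdmv": r.hdmv},
                    )
                    for r in scene.roads
                ]
            )
        )
    )
    (out / "landuse.geojson").write_text(
        json.dumps(
            _collection(
                [
                    _feature(z.geometry, {"zone_id": z.zone_id, "class": z.zone_class})
                    for z in scene.landuse
                ]
            )
        )
    )
    (out / "coastline.geojson").write_text(
        json.dumps(_collection([_feature(scene.coastline, {})]))
    )
    (out / "industries.geojson").write_text(
        json.dumps(
            _collection([_feature(i.point, {"name": i.name}) for i in scene.industries])
        )
    )
    write_ascii_grid(scene.elevation, out / "elevation.asc")
    write_ascii_grid(scene.population, out / "population.asc")
    for region, w in scene.wind.items():
        pd.DataFrame(
            {"direction_deg": w.direction_deg, "speed_ms": w.speed_ms}
        ).to_csv(out / f"wind_{region}.csv", index=False)
    meta = {"bounds": list(scene.bounds), "region_split_y": scene.region_split_y, "crs": scene.crs}
    (out / "scene.json").write_text(json.dumps(meta, indent=1))


def import_scene(in_dir) -> CityScene:
    src = Path(in_dir)
    meta = json.loads((src / "scene.json").read_text())
    roads = [
        Road(
            f["properties"]["road_id"],
            shape(f["geometry"]),
            f["properties"]["class"],
            float(f["properties"]["ldmv"]),
            float(f["properties"]["hdmv"]),
        )
        for f in json.loads((src / "roads.geojson").read_text())["features"]
    ]
    landuse = [
        LandUseZone(f["properties"]["zone_id"], shape(f["geometry"]), f["properties"]["class"])
        for f in json.loads((src / "landuse.geojson").read_text())["features"]
    ]
    coast = shape(
        json.loads((src / "coastline.geojson").read_text())["features"][0]["geometry"]
    )
    if not isinstance(coast, LineString):
        coast = LineString(coast.coords)
    industries = [
        IndustrySource(f["properties"]["name"], *f["geometry"]["coordinates"])
        for f in json.loads((src / "industries.geojson").read_text())["features"]
    ]
    wind = {}
    for path in sorted(src.glob("wind_*.csv")):
        region = path.stem.split("_", 1)[1]
        df = pd.read_csv(path)
        wind[region] = WindSeries(df["direction_deg"].to_numpy(), df["speed_ms"].to_numpy())
    return CityScene(
        bounds=tuple(meta["bounds"]),
        roads=roads,
        landuse=landuse,
        coastline=coast,
        industries=industries,
        elevation=read_ascii_grid(src / "elevation.asc"),
        population=read_ascii_grid(src / "population.asc"),
        wind=wind,
        region_split_y=meta["region_split_y"],
        crs=meta.get("crs", "local-projected-meters"),
    )


MEASUREMENT_COLUMNS = ["site_id", "pollutant", "period_id", "start", "end", "value_ugm3", "flag"]


def write_measurements(records: pd.DataFrame, path):
    records[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    df["start"] = df["start"].dt.date
    df["end"] = df["end"].dt.date
    df["flag"] = df["flag"].fillna("")
    return df
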