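"""Geometric oracles and invariants for buffer-based predictor extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, box

import airlur as al
from airlur.errors import DataError
from airlur.fields import CoverageError
from airlur.geo_predictors import (
    AREA_RADII,
    ROAD_RADII,
    bearing_deg,
    default_predictor_grid,
    evaluate_spec,
)

from conftest import make_toy_scene, road, zone

B = (-2000.0, -2000.0, 2000.0, 2000.0)


class TestRoadLength:
    def test_chord_through_center(self):
        sc = make_toy_scene(roads=[road("r", [(-1000, 0), (1000, 0)])], bounds=B)
        assert al.road_length_in_buffer((0, 0), sc, 100, "major") == pytest.approx(200, rel=1e-9)

    def test_half_chord(self):
        sc = make_toy_scene(roads=[road("r", [(0, 0), (300, 0)])], bounds=B)
        assert al.road_length_in_buffer((0, 0), sc, 100, "major") == pytest.approx(100, rel=1e-9)

    def test_all_roads_outside(self):
        sc = make_toy_scene(roads=[road("r", [(500, 500), (1500, 500)])], bounds=B)
        assert al.road_length_in_buffer((0, 0), sc, 100, "major") == 0.0

    def test_empty_layer_is_zero(self):
        sc = make_toy_scene(bounds=B)
        assert al.road_length_in_buffer((0, 0), sc, 100, "minor") == 0.0

    def test_additive_over_disjoint_roads(self):
        r1 = road("a", [(-1000, 50), (1000, 50)])
        r2 = road("b", [(-1000, -50), (1000, -50)])
        both = make_toy_scene(roads=[r1, r2], bounds=B)
        only1 = make_toy_scene(roads=[r1], bounds=B)
        only2 = make_toy_scene(roads=[r2], bounds=B)
        assert al.road_length_in_buffer((0, 0), both, 200, "major") == pytest.approx(
            al.road_length_in_buffer((0, 0), only1, 200, "major")
            + al.road_length_in_buffer((0, 0), only2, 200, "major"),
            rel=1e-12,
        )


class TestTrafficCount:
    def test_single_crossing_segment(self):
        sc = make_toy_scene(roads=[road("r", [(-1000, 0), (1000, 0)], ldmv=5000)], bounds=B)
        assert al.traffic_count_in_buffer((0, 0), sc, 100, "LDMV") == 5000

    def test_two_disjoint_segments_total(self):
        sc = make_toy_scene(
            roads=[
                road("a", [(-1000, 50), (1000, 50)], ldmv=5000),
                road("b", [(-1000, -50), (1000, -50)], ldmv=2000),
            ],
            bounds=B,
        )
        assert al.traffic_count_in_buffer((0, 0), sc, 100, "total") == 7000

    def test_tangent_road_not_counted(self):
        # line y = 100 touches the r=100 buffer at exactly one point
        sc = make_toy_scene(roads=[road("t", [(-1000, 100), (1000, 100)], ldmv=9000)], bounds=B)
        assert al.traffic_count_in_buffer((0, 0), sc, 100, "LDMV") == 0.0

    def test_feature_counted_once(self):
        # a polyline with many segments inside the buffer still counts once
        pts = [(-80, 0), (-40, 30), (0, 0), (40, 30), (80, 0)]
        sc = make_toy_scene(roads=[road("z", pts, ldmv=1234)], bounds=B)
        assert al.traffic_count_in_buffer((0, 0), sc, 100, "LDMV") == 1234

    def test_missing_counts_error(self):
        sc = make_toy_scene(roads=[road("r", [(-100, 0), (100, 0)], ldmv=np.nan)], bounds=B)
        with pytest.raises(DataError):
            al.traffic_count_in_buffer((0, 0), sc, 100, "LDMV")


class TestLanduseArea:
    def test_full_disc(self):
        sc = make_toy_scene(landuse=[zone("z", -500, -500, 500, 500)], bounds=B)
        assert al.landuse_area_in_buffer((0, 0), sc, 100, "industrial") == pytest.approx(
            np.pi * 100**2, rel=1e-6
        )

    def test_half_plane(self):
        sc = make_toy_scene(landuse=[zone("z", 0, -1500, 1500, 1500)], bounds=B)
        assert al.landuse_area_in_buffer((0, 0), sc, 100, "industrial") == pytest.approx(
            np.pi * 100**2 / 2, rel=1e-6
        )

    def test_overlapping_polygons_unioned(self):
        sc = make_toy_scene(
            landuse=[
                zone("a", -500, -500, 500, 500),
                zone("b", -400, -400, 600, 600),
            ],
            bounds=B,
        )
        assert al.landuse_area_in_buffer((0, 0), sc, 100, "industrial") == pytest.approx(
            np.pi * 100**2, rel=1e-6
        )

    def test_empty_class_zero(self):
        sc = make_toy_scene(bounds=B)
        assert al.landuse_area_in_buffer((0, 0), sc, 100, "harbor") == 0.0


class TestPopulation:
    def test_uniform_density(self):
        d = 0.01  # persons per m^2
        sc = make_toy_scene(pop_per_m2=d, bounds=B)
        got = al.population_in_buffer((0, 0), sc.population, 300)
        assert got == pytest.approx(d * np.pi * 300**2, rel=1e-6)

    def test_zero_field(self):
        sc = make_toy_scene(bounds=B)
        assert al.population_in_buffer((0, 0), sc.population, 300) == 0.0

    def test_single_cell_inside(self):
        sc = make_toy_scene(pop_cells={(30, 30): 42.0}, bounds=B)
        pop = sc.population
        cx = pop.x0 + (30 + 0.5) * pop.cell
        cy = pop.y0 + (30 + 0.5) * pop.cell
        assert al.population_in_buffer((cx, cy), pop, 300) == pytest.approx(42.0, rel=1e-9)

    def test_uncovered_buffer_errors(self):
        sc = make_toy_scene(bounds=B, margin=100.0)
        with pytest.raises(CoverageError):
            al.population_in_buffer((1950, 0), sc.population, 300)


class TestDistances:
    def test_on_feature(self):
        sc = make_toy_scene(roads=[road("r", [(-100, 0), (100, 0)])], bounds=B)
        u = sc.road_class_union("major")
        assert al.distance_to_nearest((0, 0), u) == 0.0
        assert al.inverse_distance((0, 0), u) == 1.0  # 1/d_min with d_min = 1 m

    def test_known_distance(self):
        sc = make_toy_scene(roads=[road("r", [(-100, 250), (100, 250)])], bounds=B)
        assert al.distance_to_nearest((0, 0), sc.road_class_union("major")) == pytest.approx(250)

    def test_minimum_of_two(self):
        sc = make_toy_scene(
            roads=[
                road("a", [(-100, 300), (100, 300)]),
                road("b", [(-100, -120), (100, -120)]),
            ],
            bounds=B,
        )
        assert al.distance_to_nearest((0, 0), sc.road_class_union("major")) == pytest.approx(120)


class TestWindFraction:
    def test_uniform_directions(self):
        dirs = np.arange(360.0)
        assert al.wind_fraction_from((0, 0), (0, 1000), dirs, 22.5) == pytest.approx(45 / 360)

    def test_all_hours_on_bearing(self):
        b = bearing_deg((0, 0), (500, 500))
        assert b == pytest.approx(45.0)
        assert al.wind_fraction_from((0, 0), (500, 500), np.full(100, b)) == 1.0

    def test_no_hours_in_sector(self):
        assert al.wind_fraction_from((0, 0), (0, 1000), np.full(50, 180.0)) == 0.0

    def test_empty_series_errors(self):
        with pytest.raises(DataError):
            al.wind_fraction_from((0, 0), (0, 1000), np.array([]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 359.999), min_size=2, max_size=60), st.integers(1, 59))
    def test_reorder_invariant_and_additive_over_partition(self, dirs, cut):
        dirs = np.asarray(dirs)
        cut = min(cut, len(dirs) - 1)
        full = al.wind_fraction_from((0, 0), (700, -300), dirs)
        shuffled = al.wind_fraction_from((0, 0), (700, -300), dirs[::-1])
        assert full == pytest.approx(shuffled)
        f1 = al.wind_fraction_from((0, 0), (700, -300), dirs[:cut])
        f2 = al.wind_fraction_from((0, 0), (700, -300), dirs[cut:])
        n1, n2 = cut, len(dirs) - cut
        assert full == pytest.approx((n1 * f1 + n2 * f2) / (n1 + n2))


class TestElevationAndMet:
    def test_flat_field(self):
        sc = make_toy_scene(elev=37.5, bounds=B)
        assert al.elevation_at((123.4, -567.8), sc.elevation) == pytest.approx(37.5)

    def test_linear_ramp_bilinear(self):
        sc = make_toy_scene(elev=lambda gx, gy: 0.01 * gx, bounds=B, cell=100.0)
        # midway between two cell centers: mean of the node values
        x_mid = sc.elevation.x0 + 1.0 * sc.elevation.cell  # on a cell edge
        v1 = sc.elevation.values[5, 0]
        v2 = sc.elevation.values[5, 1]
        y_at = sc.elevation.y0 + 5.5 * sc.elevation.cell
        assert al.elevation_at((x_mid, y_at), sc.elevation) == pytest.approx((v1 + v2) / 2)

    def test_outside_raster_errors(self):
        sc = make_toy_scene(bounds=B, margin=100.0)
        with pytest.raises(CoverageError):
            al.elevation_at((5000, 5000), sc.elevation)

    def test_annual_mean_of_constant_series(self):
        sc = make_toy_scene(wind_speeds=np.full(10, 4.25), wind_dirs=np.zeros(10), bounds=B)
        assert al.met_scalar(sc, "south", "wind_speed") == pytest.approx(4.25)


class TestPredictorMatrix:
    def test_default_grid_composition(self):
        grid = default_predictor_grid()
        assert len(grid) == 53
        kinds = {}
        for s in grid:
            kinds[s.kind] = kinds.get(s.kind, 0) + 1
        assert kinds == {
            "road_length": 10, "distance": 2, "traffic_count": 10,
            "landuse_area": 20, "population_sum": 5, "elevation": 1,
            "coastline_distance": 1, "wind_fraction": 3, "met_scalar": 1,
        }

    def test_matrix_shape_and_order(self, matrix, sites):
        assert matrix.data.shape == (41, 53)
        assert list(matrix.data.index) == [s.id for s in sites]
        assert not matrix.data.isna().any().any()

    def test_buffer_columns_nonnegative(self, matrix):
        buffered = [
            s.name for s in matrix.specs
            if s.kind in ("road_length", "traffic_count", "landuse_area", "population_sum")
        ]
        assert (matrix.data[buffered] >= 0).all().all()

    def test_monotone_in_radius(self, matrix):
        ladders = {
            "road_length": [("major_length", ROAD_RADII), ("minor_length", ROAD_RADII)],
            "traffic": [("ldmv", ROAD_RADII), ("hdmv", ROAD_RADII)],
            "area": [(c, AREA_RADII) for c in ("industrial", "urban", "open_space", "harbor")]
            + [("population", AREA_RADII)],
        }
        for group in ladders.values():
            for prefix, radii in group:
                cols = [f"{prefix}_{r}" for r in radii]
                vals = matrix.data[cols].to_numpy()
                assert (np.diff(vals, axis=1) >= -1e-9).all(), prefix

    def test_empty_landscape_buffer_columns_zero(self):
        sc = make_toy_scene(bounds=B)
        grid = [
            s for s in default_predictor_grid()
            if s.kind in ("road_length", "traffic_count", "landuse_area", "population_sum")
        ]
        with np.errstate(all="ignore"):
            m = al.build_predictor_matrix([("p", 0.0, 0.0)], sc, grid)
        assert (m.data.to_numpy() == 0).all()

    def test_translation_invariance(self):
        dx, dy = 1234.5, -987.25

        def build(ox, oy):
            return make_toy_scene(
                roads=[road("r", [(ox - 400, oy + 50), (ox + 400, oy + 50)], ldmv=7000)],
                landuse=[zone("z", ox - 300, oy - 300, ox + 300, oy + 300, "urban")],
                industries=[al.IndustrySource("refinery_a", ox + 900, oy + 100)],
                bounds=(ox - 2000, oy - 2000, ox + 2000, oy + 2000),
                wind_dirs=np.arange(0, 360, 5.0),
            )

        grid = [
            s for s in default_predictor_grid()
            if s.kind in ("road_length", "traffic_count", "landuse_area", "distance",
                          "wind_fraction")
        ]
        a = al.build_predictor_matrix([("p", 10.0, 20.0)], build(0.0, 0.0), grid)
        b = al.build_predictor_matrix([("p", 10.0 + dx, 20.0 + dy)], build(dx, dy), grid)
        np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_radius_ladder_enforced(self):
        with pytest.raises(ValueError):
            al.PredictorSpec("bad", "road_length", "major", 200, "+")
        with pytest.raises(ValueError):
            al.PredictorSpec("bad", "landuse_area", "urban", 50, "+")
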