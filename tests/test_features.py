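import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Point, Polygon

import oracles
from lur.errors import (
    DuplicatePredictorError,
    EmptyLayerError,
    GeometryAggregationError,
    MissingLayerError,
    RasterCoverageError,
)
from lur.features import (
    PredictorSpec,
    buffer_aggregate,
    build_matrix,
    distance_transforms,
    nearest_distance,
    raster_buffer_mean,
    standard_specs,
)
from lur.geodata import FeatureLayer, Raster


def sites_at(*xy):
    return pd.DataFrame(
        {"x": [p[0] for p in xy], "y": [p[1] for p in xy]},
        index=[f"S{i}" for i in range(len(xy))],
    )


def random_line(rng, span=600.0):
    pts = rng.uniform(-span, span, size=(rng.integers(2, 5), 2))
    return LineString(pts)


# ------------------------------------------------------------ buffer_aggregate

def test_point_outside_radius_not_counted():
    layer = FeatureLayer("grill", "point", [Point(200.0, 0.0)])
    out = buffer_aggregate(layer, sites_at((0, 0)), 100, "count")
    assert out[0] == 0.0


def test_point_on_boundary_counts_inside():
    layer = FeatureLayer("grill", "point", [Point(100.0, 0.0)])
    out = buffer_aggregate(layer, sites_at((0, 0)), 100, "count")
    assert out[0] == 1.0


def test_polygon_covering_disc_gives_disc_area():
    big = Polygon([(-500, -500), (500, -500), (500, 500), (-500, 500)])
    layer = FeatureLayer("lu_residential", "polygon", [big])
    out = buffer_aggregate(layer, sites_at((0, 0)), 100, "area")
    assert out[0] == pytest.approx(math.pi * 100**2, rel=3e-4)


def test_clipped_length_matches_densified_oracle():
    rng = np.random.default_rng(21)
    for _ in range(10):
        line = random_line(rng)
        layer = FeatureLayer("road", "line", [line])
        site = rng.uniform(-100, 100, 2)
        r = 300.0
        got = buffer_aggregate(layer, sites_at(tuple(site)), r, "length")[0]
        want = oracles.densified_clipped_length(line, site, r)
        assert got == pytest.approx(want, abs=max(0.005 * want, 0.25))


def test_geometry_aggregation_mismatch():
    layer = FeatureLayer("grill", "point", [Point(0, 0)])
    with pytest.raises(GeometryAggregationError):
        buffer_aggregate(layer, sites_at((0, 0)), 100, "length")


def test_empty_layer_aggregates_to_zero():
    layer = FeatureLayer("grill", "point", [])
    out = buffer_aggregate(layer, sites_at((0, 0), (5, 5)), 100, "count")
    np.testing.assert_array_equal(out, [0.0, 0.0])


# ------------------------------------------------------------ nearest_distance

def test_perpendicular_foot_distance():
    layer = FeatureLayer("road", "line", [LineString([(3, 0), (3, 10)])])
    assert nearest_distance(layer, sites_at((0, 0)))[0] == pytest.approx(3.0, abs=1e-12)


def test_site_on_feature_distance_zero():
    layer = FeatureLayer("road", "line", [LineString([(0, 0), (10, 0)])])
    assert nearest_distance(layer, sites_at((4, 0)))[0] == 0.0


def test_nearest_distance_matches_segment_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        geoms = [random_line(rng) for _ in range(4)]
        layer = FeatureLayer("road", "line", geoms)
        site = rng.uniform(-200, 200, 2)
        got = nearest_distance(layer, sites_at(tuple(site)))[0]
        want = oracles.brute_force_nearest(site, geoms)
        assert got == pytest.approx(want, abs=1e-9)


def test_empty_layer_is_typed_error():
    with pytest.raises(EmptyLayerError):
        nearest_distance(FeatureLayer("road", "line", []), sites_at((0, 0)))


# --------------------------------------------------------- distance_transforms

def test_transform_arithmetic():
    inv, inv2 = distance_transforms(50.0, floor=1.0)
    assert inv == pytest.approx(0.02)
    assert inv2 == pytest.approx(4e-4)


def test_transform_floor_engages():
    inv, inv2 = distance_transforms(0.0, floor=1.0)
    assert inv == 1.0 and inv2 == 1.0


@given(
    st.floats(min_value=1.0, max_value=1e6),
    st.floats(min_value=0.0, max_value=1e6),
)
def test_transforms_monotone_nonincreasing(d1, delta):
    i1, s1 = distance_transforms(d1)
    i2, s2 = distance_transforms(d1 + delta)
    assert i2 <= i1 and s2 <= s1


# ----------------------------------------------------------- raster_buffer_mean

def grid_raster(values):
    return Raster(np.asarray(values, dtype=float), xll=-500, yll=-500, cell_size=30)


def test_constant_raster_mean():
    raster = grid_raster(np.full((34, 34), 0.4))
    out = raster_buffer_mean(raster, sites_at((0, 0), (40, -60)), 150)
    np.testing.assert_allclose(out, 0.4)


def test_raster_mean_within_bounds():
    rng = np.random.default_rng(2)
    vals = rng.uniform(-1, 1, (34, 34))
    raster = grid_raster(vals)
    out = raster_buffer_mean(raster, sites_at((10, 10)), 200)
    assert vals.min() <= out[0] <= vals.max()


def test_raster_mean_matches_cell_scan_oracle():
    rng = np.random.default_rng(9)
    vals = rng.uniform(-1, 1, (34, 34))
    raster = grid_raster(vals)
    for _ in range(5):
        site = rng.uniform(-150, 150, 2)
        r = rng.choice([100, 150, 200])
        got = raster_buffer_mean(raster, sites_at(tuple(site)), r)[0]
        want = oracles.raster_scan_mean(vals, -500, -500, 30, site, r)
        assert got == pytest.approx(want, abs=1e-12)


def test_buffer_exits_raster_names_site():
    raster = grid_raster(np.zeros((10, 10)))
    with pytest.raises(RasterCoverageError, match="S0"):
        raster_buffer_mean(raster, sites_at((0, 0)), 10000)


# ------------------------------------------------------------------ build_matrix

@pytest.fixture()
def toy_world():
    rng = np.random.default_rng(13)
    layers = {
        "grill": FeatureLayer("grill", "point", [Point(*rng.uniform(0, 800, 2)) for _ in range(40)]),
        "road": FeatureLayer("road", "line", [random_line(rng, 400) for _ in range(6)]),
        "lu_residential": FeatureLayer(
            "lu_residential", "polygon",
            [Polygon([(0, 0), (300, 0), (300, 300), (0, 300)])],
        ),
    }
    raster = Raster(rng.uniform(-1, 1, (60, 60)), xll=-400, yll=-400, cell_size=30)
    sites = sites_at((200, 200), (400, 300), (600, 500))
    return layers, raster, sites


def test_build_matrix_bookkeeping(toy_world):
    layers, raster, sites = toy_world
    specs = standard_specs(
        point_layers={"grill": "+"},
        line_layers={"road": "+"},
        polygon_layers={"lu_residential": "+"},
        raster_sign="-",
        vector_radii=(100, 300),
        raster_radii=(100, 200),
    )
    pm = build_matrix(specs, layers, sites, raster)
    # 2 vector specs x (2 radii + 2 transforms) + polygons x 2 radii + raster x 2
    assert pm.frame.shape == (3, 2 * 4 + 2 + 2)
    assert set(pm.specs) == set(pm.frame.columns)
    grill_counts = pm.frame["GRILL_100"]
    assert (grill_counts >= 0).all() and (grill_counts == grill_counts.astype(int)).all()


def test_matrix_monotone_in_radius(toy_world):
    layers, raster, sites = toy_world
    specs = []
    for r in (25, 50, 100, 300, 500):
        specs.append(PredictorSpec(f"GRILL_{r}", "grill", "count", r))
        specs.append(PredictorSpec(f"ROAD_{r}", "road", "length", r))
        specs.append(PredictorSpec(f"LU_{r}", "lu_residential", "area", r))
    pm = build_matrix(specs, layers, sites, raster)
    radii = (25, 50, 100, 300, 500)
    for prefix in ("GRILL", "ROAD", "LU"):
        for r1, r2 in zip(radii, radii[1:]):
            assert (pm.frame[f"{prefix}_{r2}"] >= pm.frame[f"{prefix}_{r1}"] - 1e-9).all()


def test_clip_bounds(toy_world):
    layers, raster, sites = toy_world
    specs = [
        PredictorSpec("ROAD_300", "road", "length", 300),
        PredictorSpec("LU_300", "lu_residential", "area", 300),
    ]
    pm = build_matrix(specs, layers, sites, raster)
    assert (pm.frame["ROAD_300"] <= layers["road"].total_length() + 1e-9).all()
    assert (pm.frame["LU_300"] <= math.pi * 300**2 + 1e-9).all()


def test_translation_invariance(toy_world):
    import shapely.affinity as aff

    layers, raster, sites = toy_world
    specs = standard_specs(
        point_layers={"grill": "+"}, line_layers={"road": "+"},
        polygon_layers={"lu_residential": "+"}, raster_sign="-",
        vector_radii=(100, 300), raster_radii=(100, 200),
    )
    pm = build_matrix(specs, layers, sites, raster)
    dx, dy = 12345.0, -6789.0
    moved_layers = {
        k: FeatureLayer(k, v.geom_type, [aff.translate(g, dx, dy) for g in v.geometries])
        for k, v in layers.items()
    }
    moved_raster = Raster(raster.values, raster.xll + dx, raster.yll + dy, raster.cell_size)
    moved_sites = sites.assign(x=sites["x"] + dx, y=sites["y"] + dy)
    pm2 = build_matrix(specs, moved_layers, moved_sites, moved_raster)
    np.testing.assert_allclose(pm2.frame.to_numpy(), pm.frame.to_numpy(), atol=1e-9)


def test_missing_layer_names_category(toy_world):
    layers, raster, sites = toy_world
    specs = [PredictorSpec("BUS_100", "bus_stop", "count", 100)]
    with pytest.raises(MissingLayerError, match="bus_stop"):
        build_matrix(specs, layers, sites, raster)


def test_duplicate_names_rejected(toy_world):
    layers, raster, sites = toy_world
    specs = [
        PredictorSpec("GRILL_100", "grill", "count", 100),
        PredictorSpec("GRILL_100", "grill", "count", 300),
    ]
    with pytest.raises(DuplicatePredictorError):
        build_matrix(specs, layers, sites, raster)


def test_distance_family_consistency(toy_world):
    layers, raster, sites = toy_world
    specs = [
        PredictorSpec("ROAD_D", "road", "distance"),
        PredictorSpec("ROAD_INVD", "road", "inverse_distance"),
        PredictorSpec("ROAD_INVD2", "road", "inverse_sq_distance"),
    ]
    pm = build_matrix(specs, layers, sites, raster)
    d = np.maximum(pm.frame["ROAD_D"], 1.0)
    np.testing.assert_allclose(pm.frame["ROAD_INVD"], 1 / d, rtol=1e-12)
    np.testing.assert_allclose(pm.frame["ROAD_INVD2"], 1 / d**2, rtol=1e-12)
    assert (pm.frame["ROAD_INVD"] > 0).all()


def test_spec_validation():
    with pytest.raises(ValueError):
        PredictorSpec("X", "grill", "count", None)
    with pytest.raises(GeometryAggregationError):
        PredictorSpec("X", "grill", "sum", 100)
    with pytest.raises(ValueError):
        PredictorSpec("X", "grill", "count", 100, expected_sign="?")
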