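"""Projection, delineation, zonal statistics, and covariate correlations."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import cjspersist as cp
from cjspersist.populations import PopulationSet, _assign_by_centroid
from cjspersist.projection import DEFAULT_PROJECTION, AlbersEqualArea, haversine_m
from cjspersist.rasters import DegenerateScalingError, Raster
from cjspersist.records import ConfigurationError

from .conftest import make_records
from .helpers import per_cell_zonal_mean, union_find_components


class TestProjection:
    def test_forward_inverse_round_trip(self, rng):
        lon = rng.uniform(-95, -75, 50)
        lat = rng.uniform(25, 40, 50)
        x, y = DEFAULT_PROJECTION.forward(lon, lat)
        lon2, lat2 = DEFAULT_PROJECTION.inverse(x, y)
        np.testing.assert_allclose(lon, lon2, atol=1e-9)
        np.testing.assert_allclose(lat, lat2, atol=1e-9)

    def test_haversine_one_degree_latitude(self):
        # one degree of latitude on the authalic sphere
        d = haversine_m(-82.0, 31.0, -82.0, 32.0)
        assert abs(d - np.pi * 6_371_007.2 / 180.0) < 1.0

    def test_equal_area_property(self):
        # a 1-degree lon/lat quad: projected area must match the spherical area
        proj = AlbersEqualArea()
        lons = np.linspace(-83.0, -82.0, 200)
        ring = (
            [(l, 30.0) for l in lons]
            + [(-82.0, la) for la in np.linspace(30.0, 31.0, 200)]
            + [(l, 31.0) for l in lons[::-1]]
            + [(-83.0, la) for la in np.linspace(31.0, 30.0, 200)]
        )
        xy = [proj.forward(lo, la) for lo, la in ring]
        area = Polygon(xy).area
        R = 6_371_007.2
        sphere = R**2 * np.radians(1.0) * (np.sin(np.radians(31.0)) - np.sin(np.radians(30.0)))
        assert abs(area - sphere) / sphere < 1e-4


def records_at_xy(xy):
    """Record table whose projected coordinates are (approximately) xy meters."""
    lon, lat = DEFAULT_PROJECTION.inverse(xy[:, 0], xy[:, 1])
    return make_records(
        [(f"r{i:03d}", "A", "2001-02-03", float(lon[i]), float(lat[i])) for i in range(len(xy))]
    )


def random_xy(rng, n=200, span_km=60.0):
    x0, y0 = DEFAULT_PROJECTION.forward(-82.0, 31.0)
    return np.column_stack(
        [x0 + rng.uniform(0, span_km * 1000.0, n), y0 + rng.uniform(0, span_km * 1000.0, n)]
    )


class TestDelineation:
    def pair(self, gap_km):
        x0, y0 = DEFAULT_PROJECTION.forward(-82.0, 31.0)
        return records_at_xy(np.array([[x0, y0], [x0 + gap_km * 1000.0, y0]]))

    def test_overlapping_discs_merge(self):
        assert len(cp.delineate_populations(self.pair(4.9), 2.5)) == 1

    def test_separated_discs_stay_apart(self):
        assert len(cp.delineate_populations(self.pair(5.1), 2.5)) == 2

    @pytest.mark.parametrize("buffer_km", [1.0, 2.5, 5.0])
    def test_count_matches_union_find_oracle(self, rng, buffer_km):
        xy = random_xy(rng)
        pops = cp.delineate_populations(records_at_xy(xy), buffer_km)
        # discs overlap when centers are closer than 2r (in the projected plane)
        assert len(pops) == union_find_components(xy, 2.0 * buffer_km * 1000.0)

    def test_isolated_disc_area(self):
        pops = cp.delineate_populations(self.pair(100.0), 2.5)
        for a in pops.table["area_km2"]:
            assert abs(a - np.pi * 2.5**2) / (np.pi * 2.5**2) < 0.01

    def test_every_record_assigned_once(self, rng):
        xy = random_xy(rng, n=100)
        recs = records_at_xy(xy)
        pops = cp.delineate_populations(recs, 2.5)
        assert sorted(pops.membership.index) == sorted(recs["record_id"])
        assert pops.table["n_records"].sum() == 100

    def test_polygon_count_monotone_in_buffer(self, rng):
        xy = random_xy(rng, n=120)
        recs = records_at_xy(xy)
        counts = [len(cp.delineate_populations(recs, b)) for b in (0.5, 1.0, 2.5, 5.0, 10.0)]
        assert counts == sorted(counts, reverse=True)

    def test_total_area_subadditive(self, rng):
        xy = random_xy(rng, n=80, span_km=20.0)
        pops = cp.delineate_populations(records_at_xy(xy), 2.5)
        assert pops.table["area_km2"].sum() <= 80 * np.pi * 2.5**2 + 1e-6

    def test_zero_records_empty_set(self):
        pops = cp.delineate_populations(make_records([]), 2.5)
        assert len(pops) == 0


def one_pop_at(x, y):
    poly = Point(x, y).buffer(2500.0)
    import pandas as pd

    table = pd.DataFrame(
        [{"pop_id": "pop0000", "geometry": poly, "centroid_x": x, "centroid_y": y, "area_km2": poly.area / 1e6, "n_records": 1}]
    )
    return PopulationSet(table, pd.Series(["pop0000"], index=["r0"]), 2.5, DEFAULT_PROJECTION)


class TestAssignments:
    layers = [("A", box(0, 0, 10_000, 10_000)), ("B", box(10_000, 0, 20_000, 10_000))]

    def test_centroid_containment(self):
        pops = one_pop_at(5_000, 5_000)
        cp.assign_ecoregion(pops, self.layers)
        assert pops.table.loc[0, "ecoregion"] == "A" and not pops.table.loc[0, "ecoregion_flag"]

    def test_outside_everything_takes_nearest_with_flag(self):
        pops = one_pop_at(21_000, 5_000)
        cp.assign_ecoregion(pops, self.layers)
        assert pops.table.loc[0, "ecoregion"] == "B" and pops.table.loc[0, "ecoregion_flag"]

    def test_shared_boundary_takes_first_layer(self):
        pops = one_pop_at(10_000, 5_000)
        cp.assign_ecoregion(pops, self.layers)
        assert pops.table.loc[0, "ecoregion"] == "A" and pops.table.loc[0, "ecoregion_flag"]

    def test_empty_ecoregion_layer_rejected(self):
        with pytest.raises(ConfigurationError):
            cp.assign_ecoregion(one_pop_at(0, 0), [])

    def test_protected_none_when_outside(self):
        pops = one_pop_at(50_000, 50_000)
        cp.assign_protected(pops, [("national forest", box(0, 0, 10_000, 10_000))])
        assert pops.table.loc[0, "protected_category"] == "none"

    def test_protected_category_mapping_and_priority(self):
        pops = one_pop_at(5_000, 5_000)
        cp.assign_protected(
            pops,
            [("X ranch", box(0, 0, 10_000, 10_000)), ("Y forest", box(0, 0, 10_000, 10_000))],
            category_map={"Y forest": "national forest"},
            category_priority=("national forest", "other"),
        )
        assert pops.table.loc[0, "protected_category"] == "national forest"
        assert pops.table.loc[0, "protected_flag"]


class TestZonalMean:
    def test_constant_raster(self):
        r = Raster(np.full((50, 50), 0.7), -5_000.0, -5_000.0, 200.0)
        pops = one_pop_at(0.0, 0.0)
        assert cp.zonal_mean(pops, r)[0] == pytest.approx(0.7)

    def test_two_half_planes(self):
        # polygon symmetric across the boundary between 0.2- and 0.4-valued halves
        vals = np.where(np.arange(100)[None, :] < 50, 0.2, 0.4) * np.ones((100, 1))
        r = Raster(vals, -10_000.0, -10_000.0, 200.0)
        pops = one_pop_at(0.0, 0.0)
        assert cp.zonal_mean(pops, r)[0] == pytest.approx(0.3)

    def test_matches_per_cell_oracle(self, rng):
        import pandas as pd

        for _ in range(5):
            r = Raster(rng.random((30, 30)), 0.0, 0.0, 100.0)
            pts = rng.uniform(500, 2500, (4, 2))
            poly = Polygon(pts).convex_hull.buffer(rng.uniform(100, 600))
            table = pd.DataFrame(
                [{"pop_id": "p", "geometry": poly, "centroid_x": poly.centroid.x, "centroid_y": poly.centroid.y,
                  "area_km2": poly.area / 1e6, "n_records": 1}]
            )
            pops = PopulationSet(table, pd.Series(["p"], index=["r0"]), 2.5, DEFAULT_PROJECTION)
            assert cp.zonal_mean(pops, r)[0] == pytest.approx(per_cell_zonal_mean(r, poly), abs=1e-12)

    def test_no_cell_center_falls_back_to_nearest(self):
        r = Raster(np.arange(4.0).reshape(2, 2), 0.0, 0.0, 1000.0)
        import pandas as pd

        tiny = Point(10.0, 10.0).buffer(1.0)  # contains no cell center
        table = pd.DataFrame(
            [{"pop_id": "p", "geometry": tiny, "centroid_x": 10.0, "centroid_y": 10.0, "area_km2": 0.0, "n_records": 1}]
        )
        pops = PopulationSet(table, pd.Series(["p"], index=["r0"]), 2.5, DEFAULT_PROJECTION)
        cp.zonal_mean(pops, r, column="h")
        assert pops.table.loc[0, "h"] == 2.0  # lower-left cell value (row 1, col 0)
        assert pops.table.loc[0, "h_flag"]


class TestRasters:
    def test_ascii_round_trip(self, tmp_path, rng):
        vals = rng.random((7, 5))
        vals[2, 3] = np.nan
        r = Raster(vals, 1000.0, 2000.0, 250.0)
        r.write_ascii(tmp_path / "r.asc")
        r2 = Raster.read_ascii(tmp_path / "r.asc")
        np.testing.assert_allclose(r.values, r2.values, rtol=1e-6)
        assert (r2.x0, r2.y0, r2.cell) == (1000.0, 2000.0, 250.0)

    def test_winter_mean_constant(self):
        grids = {}
        for wy in range(2000, 2003):
            for key in [(wy - 1, 12), (wy, 1), (wy, 2)]:
                grids[key] = Raster(np.full((3, 3), 100.0), 0, 0, 1000.0)
        out = cp.winter_precip_mean(grids, (2000, 2002))
        np.testing.assert_allclose(out.values, 100.0)

    def test_winter_mean_month_values(self):
        grids = {}
        month_val = {12: 30.0, 1: 60.0, 2: 90.0}
        for wy in range(2000, 2004):
            for m, v in month_val.items():
                key = (wy - 1, 12) if m == 12 else (wy, m)
                grids[key] = Raster(np.full((2, 2), v), 0, 0, 1000.0)
        out = cp.winter_precip_mean(grids, (2000, 2003))
        np.testing.assert_allclose(out.values, 60.0)

    def test_winter_mean_matches_stacking_oracle(self, rng):
        grids = {}
        stack = []
        for wy in range(1995, 1999):
            for m in (12, 1, 2):
                key = (wy - 1, 12) if m == 12 else (wy, m)
                g = rng.random((4, 6)) * 100
                grids[key] = Raster(g, 0, 0, 500.0)
                stack.append(g)
        out = cp.winter_precip_mean(grids, (1995, 1998))
        np.testing.assert_allclose(out.values, np.mean(stack, axis=0), atol=1e-12)

    def test_winter_mean_missing_month_named(self):
        grids = {(1999, 12): Raster(np.ones((2, 2)), 0, 0, 1000.0), (2000, 1): Raster(np.ones((2, 2)), 0, 0, 1000.0)}
        with pytest.raises(KeyError, match="month=2"):
            cp.winter_precip_mean(grids, (2000, 2000))

    def test_scale_01(self):
        np.testing.assert_allclose(cp.scale_01([10.0, 20.0, 30.0]), [0.0, 0.5, 1.0])
        out = cp.scale_01(np.array([3.0, -1.0, 7.0, 2.0]))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_scale_01_constant_raises(self):
        with pytest.raises(DegenerateScalingError):
            cp.scale_01(np.full(5, 2.0))


class TestCorrelations:
    def make_pops(self, h, w, v):
        import pandas as pd

        table = pd.DataFrame({"pop_id": [f"p{i}" for i in range(len(h))], "h": h, "w": w, "v": v})
        table["geometry"] = [Point(i * 1e4, 0).buffer(2500.0) for i in range(len(h))]
        table["centroid_x"] = 0.0
        table["centroid_y"] = 0.0
        return PopulationSet(table, pd.Series(dtype=object), 2.5, DEFAULT_PROJECTION)

    def test_perfect_negative(self, rng):
        h = rng.random(20)
        pops = self.make_pops(h, rng.random(20), 1.0 - h)
        corr = cp.covariate_correlations(pops)
        assert corr.loc["h", "v"] == pytest.approx(-1.0)

    def test_independent_samples_small_r(self, rng):
        pops = self.make_pops(rng.random(4000), rng.random(4000), rng.random(4000))
        corr = cp.covariate_correlations(pops)
        assert abs(corr.loc["h", "w"]) < 0.06

    def test_toy_table_matches_formula(self):
        h = np.array([0.1, 0.3, 0.2, 0.8, 0.5, 0.9])
        w = np.array([0.2, 0.1, 0.4, 0.6, 0.6, 0.7])
        v = np.array([0.9, 0.8, 0.6, 0.2, 0.3, 0.1])
        pops = self.make_pops(h, w, v)
        corr = cp.covariate_correlations(pops)

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

        assert corr.loc["h", "w"] == pytest.approx(pearson(h, w), abs=1e-12)
        assert corr.loc["w", "v"] == pytest.approx(pearson(w, v), abs=1e-12)

    def test_too_few_populations(self):
        with pytest.raises(ConfigurationError):
            cp.covariate_correlations(self.make_pops([0.1], [0.2], [0.3]))
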