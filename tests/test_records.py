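"""Record ingestion and cleaning-rule behavior."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from cjspersist.projection import DEFAULT_PROJECTION
from cjspersist.records import (
    CleaningReport,
    ConfigurationError,
    dedup_effort,
    dedup_target,
    filter_nontarget_species,
    filter_range,
    filter_season,
    filter_uncertainty,
    read_records,
    unproject_geometry,
)

from .conftest import make_records
from .helpers import union_find_components

D = "2001-02-03"


def square_lonlat(center_lon=-82.0, center_lat=31.0, half_km=50.0):
    """A roughly square lon/lat polygon built by unprojecting a metric square."""
    from shapely.geometry import box

    x, y = DEFAULT_PROJECTION.forward(center_lon, center_lat)
    h = half_km * 1000.0
    return unproject_geometry(box(x - h, y - h, x + h, y + h))


class TestReadRecords:
    def test_well_formed_rows_are_all_read(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "species,event_date,lon,lat,coord_uncertainty_m\n"
            "A,2001-01-01,-82.0,31.0,100\nA,2002-02-02,-82.1,31.1,\nB,2003-03-03,-82.2,31.2,50\n"
        )
        recs, errs = read_records(p)
        assert len(recs) == 3 and len(errs) == 0
        assert np.isnan(recs.loc[1, "coord_uncertainty_m"])
        assert recs.loc[0, "event_date"] == dt.date(2001, 1, 1)

    def test_out_of_bounds_latitude_becomes_row_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("species,event_date,lon,lat\nA,2001-01-01,-82.0,95.0\nA,2001-01-02,-82.0,31.0\n")
        recs, errs = read_records(p)
        assert len(recs) == 1
        assert len(errs) == 1 and "coordinates" in errs.loc[0, "reason"]

    def test_empty_file_with_header_is_fine(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("species,event_date,lon,lat\n")
        recs, errs = read_records(p)
        assert len(recs) == 0 and len(errs) == 0

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("species,lon,lat\nA,-82.0,31.0\n")
        with pytest.raises(ConfigurationError):
            read_records(p)

    def test_column_map_renames(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("taxon,when,x,y\nA,2001-01-01,-82.0,31.0\n")
        recs, _ = read_records(p, column_map={"species": "taxon", "event_date": "when", "lon": "x", "lat": "y"})
        assert recs.loc[0, "species"] == "A"


class TestRangeFilter:
    poly = square_lonlat()

    def offset_point(self, km_outside):
        x, y = DEFAULT_PROJECTION.forward(-82.0, 31.0)
        lon, lat = DEFAULT_PROJECTION.inverse(x + (50.0 + km_outside) * 1000.0, y)
        return float(lon), float(lat)

    @pytest.mark.parametrize("km_outside,kept", [(9.0, True), (11.0, False), (-10.0, True)])
    def test_tolerance_boundary(self, km_outside, kept):
        lon, lat = self.offset_point(km_outside)
        recs = make_records([("a", "A", D, lon, lat)])
        out = filter_range(recs, self.poly, tolerance_km=10.0)
        assert (len(out) == 1) is kept

    def test_empty_polygon_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_range(make_records([("a", "A", D, -82.0, 31.0)]), Polygon())


class TestUncertaintyFilter:
    @pytest.mark.parametrize(
        "unc,max_m,drop_missing,kept",
        [
            (6000.0, 5000.0, False, False),  # above the target threshold
            (np.nan, 5000.0, False, True),  # missing is retained for the target
            (np.nan, 2500.0, True, False),  # missing is dropped for effort records
            (5000.0, 5000.0, False, True),  # at the threshold (inclusive)
            (2400.0, 2500.0, True, True),
        ],
    )
    def test_threshold_and_missing_rules(self, unc, max_m, drop_missing, kept):
        recs = make_records([("a", "A", D, -82.0, 31.0, unc)])
        out = filter_uncertainty(recs, max_m, drop_missing)
        assert (len(out) == 1) is kept


def offset_latlon(lat, north_m):
    """A latitude ``north_m`` meters north of ``lat``."""
    from cjspersist.projection import EARTH_RADIUS_M

    return lat + np.degrees(north_m / EARTH_RADIUS_M)


class TestDedupTarget:
    def test_close_same_day_pair_collapses(self):
        recs = make_records(
            [("a", "A", D, -82.0, 31.0), ("b", "A", D, -82.0, offset_latlon(31.0, 5.0))]
        )
        assert len(dedup_target(recs, 10.0)) == 1

    def test_far_same_day_pair_survives(self):
        recs = make_records(
            [("a", "A", D, -82.0, 31.0), ("b", "A", D, -82.0, offset_latlon(31.0, 15.0))]
        )
        assert len(dedup_target(recs, 10.0)) == 2

    def test_different_days_never_deduplicate(self):
        recs = make_records([("a", "A", D, -82.0, 31.0), ("b", "A", "2001-02-04", -82.0, 31.0)])
        assert len(dedup_target(recs, 10.0)) == 2

    def test_chain_matches_union_find_oracle(self, rng):
        # same-day chains with mixed gaps: retained set = single-linkage clusters
        n = 40
        lat0 = 31.0
        lats = np.array([offset_latlon(lat0, v) for v in np.cumsum(rng.uniform(2.0, 20.0, n))])
        recs = make_records([(f"r{i:02d}", "A", D, -82.0, lats[i]) for i in range(n)])
        out = dedup_target(recs, 10.0)
        # oracle in the same (geodesic) metric the rule is defined in
        from cjspersist.projection import haversine_m
        from .helpers import union_find_from_distances

        lon, lat = recs["lon"].to_numpy(), recs["lat"].to_numpy()
        d = [[float(haversine_m(lon[i], lat[i], lon[j], lat[j])) for j in range(n)] for i in range(n)]
        expected = union_find_from_distances(d, 10.0)
        assert len(out) == expected

    def test_row_order_invariance(self, rng):
        lats = [offset_latlon(31.0, v) for v in [0, 5, 30, 33, 200]]
        recs = make_records([(f"r{i}", "A", D, -82.0, lats[i]) for i in range(5)])
        shuffled = recs.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = dedup_target(recs, 10.0)["record_id"].sort_values().tolist()
        b = dedup_target(shuffled, 10.0)["record_id"].sort_values().tolist()
        assert a == b

    def test_source_priority_picks_representative(self):
        recs = make_records(
            [("z1", "A", D, -82.0, 31.0, np.nan, np.nan, "gbif"), ("a2", "A", D, -82.0, 31.0, np.nan, np.nan, "museum")]
        )
        out = dedup_target(recs, 10.0, source_priority=("museum", "gbif"))
        assert out["record_id"].tolist() == ["a2"]


class TestDedupEffort:
    def test_two_species_one_event(self):
        recs = make_records(
            [("a", "A", D, -82.0, 31.0, 10.0, "obs1", "s"), ("b", "B", D, -82.0, 31.0, 10.0, "obs1", "s")]
        )
        assert len(dedup_effort(recs)) == 1

    def test_different_observers_are_distinct_events(self):
        recs = make_records(
            [("a", "A", D, -82.0, 31.0, 10.0, "obs1", "s"), ("b", "A", D, -82.0, 31.0, 10.0, "obs2", "s")]
        )
        assert len(dedup_effort(recs)) == 2

    def test_consecutive_days_are_distinct_events(self):
        recs = make_records(
            [("a", "A", D, -82.0, 31.0, 10.0, "obs1", "s"), ("b", "A", "2001-02-04", -82.0, 31.0, 10.0, "obs1", "s")]
        )
        assert len(dedup_effort(recs)) == 2

    def test_missing_observer_falls_back_to_source(self):
        recs = make_records(
            [("a", "A", D, -82.0, 31.0, 10.0, np.nan, "gbif"), ("b", "B", D, -82.0, 31.0, 10.0, np.nan, "gbif"),
             ("c", "B", D, -82.0, 31.0, 10.0, np.nan, "inat")]
        )
        assert len(dedup_effort(recs)) == 2


class TestSeasonFilter:
    @pytest.mark.parametrize(
        "date,kept",
        [("2001-03-15", True), ("2001-07-01", False), ("2001-11-01", True), ("2001-04-30", True),
         ("2001-10-31", False), ("2001-05-01", False), ("2001-12-25", True)],
    )
    def test_window_spanning_year_boundary(self, date, kept):
        recs = make_records([("a", "A", date, -82.0, 31.0)])
        out = filter_season(recs, (11, 1), (4, 30))
        assert (len(out) == 1) is kept

    def test_non_wrapping_window(self):
        recs = make_records([("a", "A", "2001-06-15", -82.0, 31.0), ("b", "A", "2001-01-15", -82.0, 31.0)])
        out = filter_season(recs, (5, 1), (8, 31))
        assert out["record_id"].tolist() == ["a"]


class TestSpeciesRegionFilter:
    species_map = {"restricted": ["SC"], "open": "all"}

    def test_restricted_species_kept_in_allowed_state(self):
        recs = make_records([("a", "restricted", D, -82.0, 31.0, 10.0, "o", "s", "SC")])
        assert len(filter_nontarget_species(recs, self.species_map)) == 1

    def test_restricted_species_dropped_elsewhere(self):
        recs = make_records([("a", "restricted", D, -82.0, 31.0, 10.0, "o", "s", "GA")])
        assert len(filter_nontarget_species(recs, self.species_map)) == 0

    def test_unrestricted_species_kept_anywhere(self):
        recs = make_records([("a", "open", D, -82.0, 31.0, 10.0, "o", "s", np.nan)])
        assert len(filter_nontarget_species(recs, self.species_map)) == 1

    def test_unlisted_species_dropped(self):
        recs = make_records([("a", "someone-else", D, -82.0, 31.0)])
        assert len(filter_nontarget_species(recs, self.species_map)) == 0

    def test_state_resolved_from_polygon_when_missing(self):
        poly = square_lonlat()
        recs = make_records([("a", "restricted", D, -82.0, 31.0)])
        kept = filter_nontarget_species(recs, self.species_map, state_polygons={"SC": poly})
        assert len(kept) == 1
        report = CleaningReport()
        dropped = filter_nontarget_species(recs, self.species_map, state_polygons={}, report=report)
        assert len(dropped) == 0 and "unresolved_state=1" in report.entries[0]["note"]


class TestProperties:
    def _sample(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(50):
            rows.append(
                (
                    f"r{i:03d}", "A", f"2001-{rng.integers(1, 13):02d}-{rng.integers(1, 28):02d}",
                    -82.0 + rng.uniform(-1, 1), 31.0 + rng.uniform(-1, 1),
                    float(rng.choice([np.nan, 100.0, 3000.0, 8000.0])), "o", "s", "GA",
                )
            )
        return make_records(rows)

    @pytest.mark.parametrize(
        "op",
        [
            lambda df: filter_uncertainty(df, 5000.0, False),
            lambda df: filter_uncertainty(df, 2500.0, True),
            lambda df: filter_season(df, (11, 1), (4, 30)),
            lambda df: dedup_target(df, 10.0),
            dedup_effort,
        ],
    )
    def test_cleaning_ops_are_idempotent(self, op):
        once = op(self._sample())
        twice = op(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_report_counts_reconcile(self):
        df = self._sample()
        report = CleaningReport()
        out = filter_uncertainty(df, 5000.0, False, report=report)
        out = filter_season(out, (11, 1), (4, 30), report=report)
        for e in report.entries:
            assert e["dropped"] + e["retained"] == e["input"]
        assert report.entries[0]["input"] == len(df)
        assert report.entries[-1]["retained"] == len(out)
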