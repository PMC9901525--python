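import numpy as np
import pandas as pd
import pytest
from scipy import stats

from storkmig import segmentation
from storkmig._geo import gc_dist_km


def _roost_daily(displacements, start="2016-07-31", lat0=39.5):
    """Daily series moving due south; displacements[k] is the travel on the
    (k+1)-th day after the initial roost day."""
    n = len(displacements) + 1
    lat = lat0 - np.concatenate([[0.0], np.cumsum(displacements)]) / 110.574
    return pd.DataFrame({
        "bird_id": "b1",
        "date": pd.date_range(start, periods=n, freq="D"),
        "lon": -6.0, "lat": lat, "gap": False,
        "displacement_km": np.concatenate([[np.nan], gc_dist_km(
            -6.0, lat[:-1], -6.0, lat[1:])]),
    })


class TestNightRoosts:
    def test_last_daylight_fix_is_roost(self):
        # noon and late-evening fixes in Iberia; 22:00 UTC is after sunset
        tracks = pd.DataFrame({
            "bird_id": "b1",
            "timestamp": pd.to_datetime(["2016-08-01T08:00Z", "2016-08-01T18:00Z",
                                         "2016-08-01T22:00Z"]),
            "lon": [-8.0, -7.5, -7.4], "lat": [39.5, 39.0, 38.9]})
        daily = segmentation.night_roosts(tracks)
        assert len(daily) == 1
        assert daily["lat"].iloc[0] == 39.0  # the 18:00 fix, not the night one

    def test_missing_day_carries_roost_with_gap_flag(self):
        tracks = pd.DataFrame({
            "bird_id": "b1",
            "timestamp": pd.to_datetime(["2016-08-01T12:00Z", "2016-08-03T12:00Z"]),
            "lon": [-8.0, -7.0], "lat": [39.5, 38.5]})
        daily = segmentation.night_roosts(tracks)
        assert len(daily) == 3
        assert daily["gap"].tolist() == [False, True, False]
        assert daily["lat"].iloc[1] == 39.5  # carried forward
        assert daily["displacement_km"].iloc[1] == 0.0

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            segmentation.night_roosts(pd.DataFrame(columns=["bird_id", "timestamp",
                                                            "lon", "lat"]))


class TestRangeKernel:
    def test_outlier_excluded_from_isopleth(self):
        rng = np.random.default_rng(0)
        lon = np.concatenate([rng.normal(-8.0, 0.01, 200), [-3.0]])
        lat = np.concatenate([rng.normal(39.5, 0.01, 200), [43.0]])
        poly = segmentation.estimate_range_kernel(lon, lat, level=0.90)
        assert poly.contains(-8.0, 39.5)
        assert not poly.contains(-3.0, 43.0)

    def test_gaussian_cloud_area_matches_analytic(self):
        # 90% isopleth of an isotropic Gaussian: area = pi * sigma^2 * chi2_2(0.9)
        rng = np.random.default_rng(1)
        sigma_km = 5.0
        n = 10_000
        lat0 = 39.5
        x = rng.normal(0, sigma_km, n)
        y = rng.normal(0, sigma_km, n)
        lon = -8.0 + x / (110.574 * np.cos(np.deg2rad(lat0)))
        lat = lat0 + y / 110.574
        poly = segmentation.estimate_range_kernel(lon, lat, level=0.90, grid_n=128)
        # polygon area back in km^2
        km_x = 110.574 * np.cos(np.deg2rad(lat0))
        area_km2 = poly.polygon.area * km_x * 110.574
        expected = np.pi * sigma_km ** 2 * stats.chi2.ppf(0.90, df=2)
        assert area_km2 == pytest.approx(expected, rel=0.15)

    def test_open_isopleth_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            segmentation.estimate_range_kernel(rng.normal(-8, 0.1, 100),
                                               rng.normal(39, 0.1, 100), level=1.0)

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError, match="fallback"):
            segmentation.estimate_range_kernel([-8.0] * 5, [39.0] * 5)


class TestDetectWindow:
    def test_rule_trace_start_on_second_day(self):
        # displacements per travel day: 5, 70, 80, 90, 10 -> the first 3-day
        # run above 60 km starts on day 2
        daily = _roost_daily([5, 70, 80, 90, 10, 5, 5, 5])
        breeding = (-6.0, 39.5, 30.0)  # centroid fallback
        wintering = (-6.0, daily["lat"].iloc[-1], 30.0)
        ev = segmentation.detect_migration_window(daily, breeding, wintering)
        assert ev.start_date == pd.Timestamp("2016-08-02")

    def test_all_slow_days_no_event(self):
        daily = _roost_daily([10, 20, 30, 10, 5])
        ev = segmentation.detect_migration_window(
            daily, (-6.0, 39.5, 30.0), (-6.0, 20.0, 30.0))
        assert not ev.complete
        assert any("incomplete" in d or "never" in d for d in ev.diagnostics)

    def test_end_is_day_before_wintering_run(self):
        daily = _roost_daily([70, 80, 90, 100, 5, 4, 3, 2])
        dest_lat = daily["lat"].iloc[4]
        ev = segmentation.detect_migration_window(
            daily, (-6.0, 39.5, 30.0), (-6.0, dest_lat, 60.0))
        assert ev.start_date == pd.Timestamp("2016-08-01")
        assert ev.end_date == pd.Timestamp("2016-08-04")
        assert ev.destination[1] == pytest.approx(daily["lat"].iloc[4])


class TestClassifyDays:
    def _event(self, daily):
        return segmentation.MigrationEvent(
            bird_id="b1", year=2016,
            start_date=daily["date"].iloc[1], end_date=daily["date"].iloc[4],
            destination=(0.0, 0.0))

    def test_exact_threshold_is_stopover(self):
        daily = _roost_daily([5, 37.0, 38.0, 90, 100, 5])
        daily["displacement_km"] = [np.nan, 5, 37.0, 38.0, 90, 100, 5]
        out = segmentation.classify_days(daily, self._event(daily))
        assert out["day_type"].iloc[2] == "stopover"   # exactly 37 km
        assert out["day_type"].iloc[3] == "migratory"  # 38 km

    def test_day_types_partition_window(self):
        daily = _roost_daily([70, 10, 80, 90, 20, 5])
        ev = self._event(daily)
        out = segmentation.classify_days(daily, ev)
        inside = out[(out["date"] >= ev.start_date) & (out["date"] <= ev.end_date)]
        n_days = (ev.end_date - ev.start_date).days + 1
        assert (inside["day_type"].isin(["migratory", "stopover"])).all()
        assert len(inside) == n_days
        assert (out.loc[out["date"] > ev.end_date, "day_type"] == "stationary").all()


class TestPartitionLegs:
    def _tracks(self, lats, lons=None, start="2016-08-01"):
        ts = pd.date_range(start + "T10:00", periods=len(lats), freq="D", tz="UTC")
        return pd.DataFrame({"bird_id": "b1", "timestamp": ts,
                             "lon": lons if lons is not None else [-5.8] * len(lats),
                             "lat": lats})

    def _event(self, n, start="2016-08-01"):
        return segmentation.MigrationEvent(
            bird_id="b1", year=2016, start_date=pd.Timestamp(start),
            end_date=pd.Timestamp(start) + pd.Timedelta(days=n - 1),
            destination=(-6.0, 16.0))

    def test_strait_crossing_interpolated_to_boundary(self):
        tracks = self._tracks([39.0, 36.2, 35.8, 33.0, 30.0])
        ev = segmentation.partition_legs(tracks, self._event(5))
        assert ev.leg1_end_date == pd.Timestamp("2016-08-03")
        assert ev.leg1_crossing[1] == pytest.approx(36.0, abs=1e-9)

    def test_atlas_line_point_on_curve(self):
        # the Atlas boundary passes exactly through (-5, 33.22)
        assert 0.58 * (-5) + 36.12 == pytest.approx(33.22)
        tracks = self._tracks([39.0, 35.0, 33.5, 32.9, 30.0],
                              lons=[-5.0, -5.0, -5.0, -5.0, -5.0])
        ev = segmentation.partition_legs(tracks, self._event(5))
        lon_c, lat_c = ev.leg2_crossing
        assert lat_c == pytest.approx(0.58 * lon_c + 36.12, abs=0.01)

    def test_boundary_never_crossed_diagnosed(self):
        tracks = self._tracks([39.0, 38.5, 38.0])
        ev = segmentation.partition_legs(tracks, self._event(3))
        assert ev.leg1_end_date is None
        assert any("Strait" in d for d in ev.diagnostics)

    def test_time_translation_invariance(self):
        lats = [39.0, 36.5, 35.5, 33.0, 31.5, 25.0, 20.0]
        ev0 = segmentation.partition_legs(self._tracks(lats), self._event(7))
        shift = 11
        ev1 = segmentation.partition_legs(
            self._tracks(lats, start="2016-08-12"), self._event(7, "2016-08-12"))
        assert (ev1.leg1_end_date - ev0.leg1_end_date).days == shift
        assert (ev1.leg2_end_date - ev0.leg2_end_date).days == shift
        assert ev1.leg1_crossing == ev0.leg1_crossing


class TestCohortAgainstTruth:
    def test_leg_bounds_partition_migration_window(self, cohort, segmented):
        for ev in segmented["events"]:
            assert ev.complete and not ev.diagnostics
            bounds = ev.leg_bounds()
            days = []
            for leg in (1, 2, 3):
                t0, t1 = bounds[leg]
                days.extend(pd.date_range(t0, t1, freq="D"))
            expected = list(pd.date_range(ev.start_date, ev.end_date, freq="D"))
            assert days == expected

    def test_dates_match_generator_truth(self, cohort, segmented):
        truth = cohort["truth"].birds.set_index("bird_id")
        for ev in segmented["events"]:
            t = truth.loc[ev.bird_id]
            for got, want in ((ev.start_date, t["start_date"]),
                              (ev.end_date, t["end_date"]),
                              (ev.leg1_end_date, t["leg1_end_date"]),
                              (ev.leg2_end_date, t["leg2_end_date"])):
                assert abs((got - want).days) <= 1

    def test_crossings_lie_on_their_boundaries(self, segmented):
        for ev in segmented["events"]:
            assert ev.leg1_crossing[1] == pytest.approx(36.0, abs=0.01)
            lon, lat = ev.leg2_crossing
            assert lat == pytest.approx(0.58 * lon + 36.12, abs=0.01)
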