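import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from storkmig import metrics
from storkmig.segmentation import MigrationEvent

R = 6371.0088


def haversine_oracle(lon1, lat1, lon2, lat2):
    """Independent reference implementation via the haversine formula."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * R * np.arcsin(np.sqrt(a))


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert metrics.great_circle_km(-6.0, 30.0, -6.0, 30.0) == 0.0

    def test_quarter_circumference(self):
        assert metrics.great_circle_km(0.0, 0.0, 90.0, 0.0) == pytest.approx(
            np.pi * R / 2, abs=0.05)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(lon1=st.floats(-180, 180), lat1=st.floats(-89, 89),
           lon2=st.floats(-180, 180), lat2=st.floats(-89, 89))
    def test_matches_haversine_oracle(self, lon1, lat1, lon2, lat2):
        got = metrics.great_circle_km(lon1, lat1, lon2, lat2)
        want = haversine_oracle(lon1, lat1, lon2, lat2)
        assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_symmetry(self):
        a = metrics.great_circle_km(-8.0, 39.0, -6.0, 16.0)
        b = metrics.great_circle_km(-6.0, 16.0, -8.0, 39.0)
        assert a == pytest.approx(b, rel=1e-12)


def _track_event(lats, lons, start="2016-08-01"):
    """Track with one fix/day plus an event windowing all days, legs by thirds."""
    n = len(lats)
    ts = pd.date_range(start + "T10:00", periods=n, freq="D", tz="UTC")
    tracks = pd.DataFrame({"bird_id": "b1", "timestamp": ts, "lon": lons, "lat": lats})
    ev = MigrationEvent(
        bird_id="b1", year=2016, start_date=ts[0].tz_localize(None).normalize(),
        end_date=ts[-1].tz_localize(None).normalize(),
        destination=(lons[-1], lats[-1]),
        leg1_end_date=ts[n // 3].tz_localize(None).normalize(),
        leg1_crossing=(lons[n // 3], lats[n // 3]),
        leg2_end_date=ts[2 * n // 3].tz_localize(None).normalize(),
        leg2_crossing=(lons[2 * n // 3], lats[2 * n // 3]))
    return tracks, ev


class TestBeeline:
    def test_whole_route_via_gibraltar_crossing(self):
        lats = [39.0, 36.0, 33.0, 30.0, 25.0, 20.0, 17.0]
        lons = [-8.0, -5.6, -6.0, -6.5, -7.0, -6.8, -6.5]
        tracks, ev = _track_event(lats, lons)
        got = metrics.beeline_km(tracks, ev, "all")
        want = (metrics.great_circle_km(-8.0, 39.0, *ev.leg1_crossing)
                + metrics.great_circle_km(*ev.leg1_crossing, *ev.destination))
        assert got == pytest.approx(want, rel=1e-12)

    def test_degenerate_start_at_crossing(self):
        lats = [36.0, 33.0, 30.0, 25.0, 20.0, 17.0]
        lons = [-5.6] * 6
        tracks, ev = _track_event(lats, lons)
        ev.leg1_crossing = (lons[0], lats[0])
        got = metrics.beeline_km(tracks, ev, "all")
        assert got == pytest.approx(
            metrics.great_circle_km(-5.6, 36.0, *ev.destination), rel=1e-12)

    def test_collinear_meridian_legs_sum_to_direct(self):
        lats = [39.0, 36.0, 33.0, 30.0, 27.0, 24.0, 21.0, 18.0, 15.0]
        lons = [-6.0] * 9
        tracks, ev = _track_event(lats, lons)
        legs = sum(metrics.beeline_km(tracks, ev, k) for k in (1, 2, 3))
        direct = metrics.great_circle_km(-6.0, 39.0, -6.0, 15.0)
        # along a meridian the per-leg beelines abut: legs only overlap by the
        # fix spacing between a leg's last day and the next leg's first day
        assert legs == pytest.approx(direct, rel=0.01)

    def test_leg_beelines_need_not_sum_to_whole(self):
        lats = [39.0, 36.0, 33.0, 30.0, 25.0, 20.0, 17.0]
        lons = [-8.0, -5.6, -9.0, -4.0, -9.0, -4.0, -6.5]
        tracks, ev = _track_event(lats, lons)
        whole = metrics.beeline_km(tracks, ev, "all")
        legs = sum(metrics.beeline_km(tracks, ev, k) for k in (1, 2, 3))
        assert legs != pytest.approx(whole, rel=1e-3)  # inequality is allowed


class TestCumulative:
    def _daily(self, day_types, start="2016-08-01"):
        return pd.DataFrame({
            "bird_id": "b1",
            "date": pd.date_range(start, periods=len(day_types), freq="D"),
            "day_type": day_types, "gap": False})

    def test_collinear_fixes_sum(self):
        # 3 fixes on one migratory day, 10 km apart going north
        step = 10.0 / (R * np.pi / 180.0)
        tracks = pd.DataFrame({
            "bird_id": "b1",
            "timestamp": pd.to_datetime(["2016-08-01T08:00Z", "2016-08-01T10:00Z",
                                         "2016-08-01T12:00Z"]),
            "lon": -6.0, "lat": [30.0, 30.0 + step, 30.0 + 2 * step]})
        daily = self._daily(["migratory"])
        got = metrics.cumulative_km(tracks, daily, "b1",
                                    pd.Timestamp("2016-08-01"), pd.Timestamp("2016-08-01"))
        assert got == pytest.approx(20.0, rel=1e-6)

    def test_stopover_days_contribute_nothing(self):
        tracks = pd.DataFrame({
            "bird_id": "b1",
            "timestamp": pd.to_datetime(["2016-08-01T08:00Z", "2016-08-01T12:00Z"]),
            "lon": [-6.0, -5.0], "lat": [30.0, 31.0]})
        daily = self._daily(["stopover"])
        assert metrics.cumulative_km(tracks, daily, "b1",
                                     pd.Timestamp("2016-08-01"),
                                     pd.Timestamp("2016-08-01")) == 0.0


class TestStraightness:
    def test_arithmetic(self):
        assert metrics.straightness(450.0, 900.0) == 0.5

    def test_detour_strictly_decreases(self):
        assert metrics.straightness(500.0, 700.0) > metrics.straightness(500.0, 800.0)

    def test_zero_cumulative_rejected(self):
        with pytest.raises(ValueError):
            metrics.straightness(10.0, 0.0)

    def test_clip_keeps_open_interval(self):
        s = metrics.straightness(1000.0000001, 1000.0)
        assert 0 < s < 1


class TestMeanFlightOdba:
    def _classified(self, rows):
        return pd.DataFrame(rows, columns=["bird_id", "timestamp", "burst_id",
                                           "label_source", "flight", "odba"])

    def test_single_flight_burst(self):
        c = self._classified([
            ("b1", pd.Timestamp("2016-08-01T10:00Z"), "x1", "accelerometer", True, 0.2)])
        assert metrics.mean_flight_odba(c, "b1", pd.Timestamp("2016-08-01"),
                                        pd.Timestamp("2016-08-01")) == 0.2

    def test_non_flight_bursts_excluded(self):
        t = pd.Timestamp("2016-08-01T10:00Z")
        c = self._classified([
            ("b1", t, "x1", "accelerometer", True, 0.1),
            ("b1", t, "x2", "accelerometer", True, 0.3),
            ("b1", t, "x3", "accelerometer", False, 0.9),
            ("b1", t, None, "speed_rule", True, np.nan)])
        got = metrics.mean_flight_odba(c, "b1", pd.Timestamp("2016-08-01"),
                                       pd.Timestamp("2016-08-01"))
        assert got == pytest.approx(0.2)

    def test_no_qualifying_burst_is_missing(self):
        c = self._classified([
            ("b1", pd.Timestamp("2016-08-01T10:00Z"), None, "speed_rule", True, np.nan)])
        assert np.isnan(metrics.mean_flight_odba(
            c, "b1", pd.Timestamp("2016-08-01"), pd.Timestamp("2016-08-01")))


@pytest.fixture(scope="module")
def summaries(cohort, segmented, classified):
    ages = dict(zip(cohort["truth"].birds["bird_id"], cohort["truth"].birds["age"]))
    return metrics.summarise(cohort["tracks"], segmented["events"],
                             segmented["daily"], classified=classified, ages=ages)


class TestSummarise:
    def test_duration_partition_and_bounds(self, summaries):
        ok = summaries[summaries["diagnostic"] == ""]
        assert len(ok) > 0
        assert (ok["duration_days"] ==
                ok["migratory_days"] + ok["stopover_days"]).all()
        assert ((ok["straightness"] > 0) & (ok["straightness"] <= 1)).all()
        assert (ok["beeline_km"] <= ok["cumulative_km"] + 1e-9).all()

    def test_durations_match_generator_truth(self, cohort, summaries):
        truth = cohort["truth"].birds.set_index("bird_id")
        for _, row in summaries[summaries["leg"] == "all"].iterrows():
            t = truth.loc[row["bird_id"]]
            want = (t["end_date"] - t["start_date"]).days + 1
            assert abs(row["duration_days"] - want) <= 2

    def test_one_row_per_bird_leg(self, summaries, segmented):
        n_birds = len({e.bird_id for e in segmented["events"]})
        assert len(summaries) == 4 * n_birds

    def test_incomplete_coverage_flagged_not_dropped(self, cohort, segmented,
                                                     classified):
        tracks = cohort["tracks"]
        ev = segmented["events"][0]
        daily = segmented["daily"].copy()
        sel = (daily["bird_id"] == ev.bird_id) & (daily["date"] == ev.start_date
                                                  + pd.Timedelta(days=2))
        daily.loc[sel, "gap"] = True
        out = metrics.summarise(tracks, [ev], daily, classified=classified)
        flagged = out[out["diagnostic"] == "incomplete daily coverage"]
        assert len(flagged) >= 1
        assert "duration_days" not in flagged.columns or flagged["duration_days"].isna().all()

    def test_order_invariance_of_metrics(self, cohort, segmented):
        ev = segmented["events"][0]
        tracks = cohort["tracks"]
        sub = tracks[tracks["bird_id"] == ev.bird_id]
        shuffled = sub.sample(frac=1.0, random_state=0)
        a = metrics.beeline_km(sub, ev, "all")
        b = metrics.beeline_km(shuffled, ev, "all")
        assert a == b
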