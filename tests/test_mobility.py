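"""Weekly index, filters, aggregation and daily moving-average series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geomobility.mobility import (
    aggregate_region_week,
    build_user_weeks,
    daily_moving_average,
    detect_data_loss_weeks,
    log1p_summary,
    week_of,
    weekly_index,
)
from tests.conftest import ev, events_frame, ts

# sigma of the 3-point toy week, frozen from an independent Karney-type
# geodesic (R geosphere::distGeo) + population-std brute force
TOY_WEEK = [(39.0, -76.6), (39.1, -76.7), (38.95, -76.5)]
TOY_WEEK_SIGMA = 4.826430682628017


class TestWeekOf:
    @pytest.mark.parametrize(
        "stamp,monday",
        [
            ("2020-03-16T00:00:00", "2020-03-16"),  # Monday maps to itself
            ("2020-03-22T23:59:59", "2020-03-16"),  # Sunday closes the week
            ("2020-03-23T00:00:01", "2020-03-23"),  # next week boundary
        ],
    )
    def test_monday_start_weeks(self, stamp, monday):
        assert week_of(ts(stamp)).isoformat() == monday

    def test_non_utc_timestamps_are_converted(self):
        from datetime import datetime, timedelta, timezone

        tz = timezone(timedelta(hours=-5))
        # Sunday 23:00 -05:00 is already Monday 04:00 UTC
        stamp = datetime(2020, 3, 22, 23, 0, tzinfo=tz)
        assert week_of(stamp).isoformat() == "2020-03-23"


class TestWeeklyIndex:
    def test_stationary_user_scores_zero(self):
        assert weekly_index([(39.0, -76.6)] * 5) == 0.0

    def test_ring_of_equidistant_points_scores_near_zero(self):
        # 4 points on a small ring around a common center: all distances equal
        center = (39.0, -76.6)
        r = 0.05
        pts = [
            (center[0] + r, center[1]),
            (center[0] - r, center[1]),
            (center[0], center[1] + r / np.cos(np.radians(center[0]))),
            (center[0], center[1] - r / np.cos(np.radians(center[0]))),
        ]
        assert weekly_index(pts) < 0.05  # km; ellipsoid breaks exact symmetry

    def test_toy_week_matches_frozen_oracle(self):
        assert weekly_index(TOY_WEEK) == pytest.approx(TOY_WEEK_SIGMA, abs=1e-6)

    def test_permutation_invariant(self):
        pts = TOY_WEEK + [(39.2, -76.8)]
        assert weekly_index(pts) == pytest.approx(weekly_index(pts[::-1]), abs=1e-12)

    def test_longitude_rotation_invariant(self):
        shifted = [(lat, lon + 37.0) for lat, lon in TOY_WEEK]
        assert weekly_index(shifted) == pytest.approx(weekly_index(TOY_WEEK), abs=1e-6)

    def test_doubling_displacements_doubles_index(self):
        home = (39.0, -76.6)
        pts = [(39.02, -76.58), (38.98, -76.63), (39.01, -76.57)]
        doubled = [(home[0] + 2 * (la - home[0]), home[1] + 2 * (lo - home[1]))
                   for la, lo in pts]
        ratio = weekly_index(doubled) / weekly_index(pts)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_below_minimum_points_raises(self):
        with pytest.raises(ValueError):
            weekly_index([(39.0, -76.6), (39.1, -76.7)])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(38.0, 40.0), st.floats(-78.0, -76.0)),
        min_size=3, max_size=8,
    ))
    def test_nonnegative_and_zero_iff_equal_distances(self, pts):
        idx = weekly_index(pts)
        assert idx >= 0.0


class TestBuildUserWeeks:
    def test_toy_stream_hand_counts(self, toy_filter_stream):
        res = build_user_weeks(toy_filter_stream)
        assert sorted(res.users["user_id"]) == ["A", "C", "D"]
        assert len(res.user_weeks) == 4
        per_user = res.user_weeks.groupby("user_id").size().to_dict()
        assert per_user == {"A": 1, "C": 1, "D": 2}

    def test_user_below_overall_threshold_absent(self, toy_filter_stream):
        res = build_user_weeks(toy_filter_stream)
        assert "B" not in set(res.users["user_id"])
        assert "E" not in set(res.users["user_id"])

    def test_thin_week_dropped_but_counts_toward_centroid(self):
        # 5 events in week 1 near home, 2 events in week 2 far away
        events = [ev("u", f"2020-03-0{2 + i}T12:00:00", 39.0, -76.6) for i in range(5)]
        events += [ev("u", "2020-03-09T12:00:00", 45.0, -90.0),
                   ev("u", "2020-03-10T12:00:00", 45.0, -90.0)]
        res = build_user_weeks(events_frame(events))
        assert len(res.user_weeks) == 1  # week 2 dropped
        urow = res.users.iloc[0]
        assert urow["n_weeks"] == 1
        # the dropped-week events still pull the all-time centroid north-west
        assert urow["centroid_lat"] > 39.5

    def test_M_is_mean_of_weekly_indices(self):
        events = []
        # week 1: dispersion; week 2: different dispersion
        for i in range(3):
            events.append(ev("u", f"2020-03-0{2 + i}T12:00:00", 39.0 + 0.05 * i, -76.6))
        for i in range(3):
            events.append(ev("u", f"2020-03-{9 + i:02d}T12:00:00", 39.0 + 0.1 * i, -76.6))
        res = build_user_weeks(events_frame(events))
        m = res.users.iloc[0]
        assert m["M_km"] == pytest.approx(res.user_weeks["weekly_index_km"].mean())

    def test_excluded_weeks_removed(self, toy_filter_stream):
        from datetime import date

        res = build_user_weeks(
            toy_filter_stream, exclude_weeks={date(2020, 3, 2)}
        )
        assert set(res.user_weeks["week_start"]) == {date(2020, 3, 9), date(2020, 3, 16)}

    def test_empty_input_permitted(self):
        res = build_user_weeks(events_frame([]))
        assert res.user_weeks.empty and res.users.empty


class TestDataLossWeeks:
    @staticmethod
    def totals(records, users=None):
        from datetime import date, timedelta

        weeks = [date(2019, 1, 7) + timedelta(weeks=i) for i in range(len(records))]
        return pd.DataFrame({
            "week_start": weeks,
            "n_users": users if users is not None else [max(1, r // 100) for r in records],
            "n_records": records,
        })

    def test_identical_counts_no_exclusions(self):
        assert detect_data_loss_weeks(self.totals([10000] * 20)) == set()

    def test_planted_low_week_excluded(self):
        records = [10000 + (i % 5) * 10 for i in range(19)] + [50]
        t = self.totals(records)
        excluded = detect_data_loss_weeks(t)
        assert excluded == {t["week_start"].iloc[-1]}
        # and it is exactly the mean - 2.807*sd rule
        from scipy.stats import norm

        x = np.array(records, float)
        assert 50 < x.mean() - norm.ppf(0.9975) * x.std(ddof=1)

    def test_smooth_trend_without_outlier_keeps_all(self):
        records = [10000 + 100 * i for i in range(20)]
        assert detect_data_loss_weeks(self.totals(records)) == set()

    def test_low_user_count_alone_triggers_exclusion(self):
        records = [10000] * 20
        users = [100 + (i % 3) for i in range(19)] + [2]
        t = self.totals(records, users)
        assert detect_data_loss_weeks(t) == {t["week_start"].iloc[-1]}

    def test_too_few_weeks_warns_and_keeps_all(self):
        with pytest.warns(UserWarning):
            assert detect_data_loss_weeks(self.totals([100, 200, 300])) == set()


class TestRegionAggregation:
    def test_two_point_stats(self):
        from datetime import date

        uw = pd.DataFrame({
            "user_id": ["u1", "u2"],
            "week_start": [date(2020, 3, 2)] * 2,
            "n": [3, 3],
            "weekly_index_km": [0.0, 10.0],
        })
        out = aggregate_region_week(uw, {"u1": "A", "u2": "A"})
        row = out.iloc[0]
        assert (row["mean_km"], row["variance"], row["n_users"]) == (5.0, 25.0, 2)

    def test_unassigned_users_skipped(self):
        from datetime import date

        uw = pd.DataFrame({
            "user_id": ["u1", "u2"],
            "week_start": [date(2020, 3, 2)] * 2,
            "n": [3, 3],
            "weekly_index_km": [1.0, 2.0],
        })
        out = aggregate_region_week(uw, {"u1": "A"})
        assert len(out) == 1 and out.iloc[0]["n_users"] == 1

    def test_national_equals_user_weighted_regional_combination(self):
        from datetime import date

        rng = np.random.default_rng(3)
        n = 30
        uw = pd.DataFrame({
            "user_id": [f"u{i}" for i in range(n)],
            "week_start": [date(2020, 3, 2)] * n,
            "n": [3] * n,
            "weekly_index_km": rng.exponential(10.0, n),
        })
        assignment = {f"u{i}": ("A" if i % 3 else "B") for i in range(n)}
        regional = aggregate_region_week(uw, assignment)
        national = aggregate_region_week(uw, {u: "ALL" for u in assignment})
        combined = (regional["mean_km"] * regional["n_users"]).sum() / regional["n_users"].sum()
        assert combined == pytest.approx(national.iloc[0]["mean_km"], rel=1e-12)

    def test_mean_between_min_and_max_user_index(self):
        from datetime import date

        rng = np.random.default_rng(4)
        uw = pd.DataFrame({
            "user_id": [f"u{i}" for i in range(10)],
            "week_start": [date(2020, 3, 2)] * 10,
            "n": [3] * 10,
            "weekly_index_km": rng.exponential(5.0, 10),
        })
        out = aggregate_region_week(uw, {f"u{i}": "A" for i in range(10)})
        v = uw["weekly_index_km"]
        assert v.min() <= out.iloc[0]["mean_km"] <= v.max()


class TestDailyMovingAverage:
    @staticmethod
    def daily_events(days, lat_offsets):
        events = []
        for d in range(days):
            day = pd.Timestamp("2020-03-02") + pd.Timedelta(days=d)
            for j, off in enumerate(lat_offsets):
                events.append(ev("u", f"{day.date()}T{8 + j:02d}:00:00", 39.0 + off, -76.6))
        return events_frame(events)

    def test_constant_pattern_gives_constant_series(self):
        df = self.daily_events(30, [0.0, 0.05, 0.10])
        out = daily_moving_average(df)
        assert len(out) == 30 - 6
        assert out["index_km"].std() < 1e-9

    def test_first_incomplete_window_days_not_emitted(self):
        df = self.daily_events(10, [0.0, 0.05, 0.10])
        out = daily_moving_average(df)
        first = out["day"].min()
        assert (first - df["timestamp"].dt.date.min()).days == 6

    def test_step_smooths_over_window_length(self):
        # dispersion collapses to zero halfway: the series ramps down over 7 days
        events = []
        for d in range(28):
            day = pd.Timestamp("2020-03-02") + pd.Timedelta(days=d)
            offs = [0.0, 0.05, 0.10] if d < 14 else [0.0, 0.0, 0.0]
            for j, off in enumerate(offs):
                events.append(ev("u", f"{day.date()}T{8 + j:02d}:00:00", 39.0 + off, -76.6))
        out = daily_moving_average(events_frame(events)).set_index("day")["index_km"]
        vals = out.to_numpy()
        assert vals[0] > 0 and vals[-1] == pytest.approx(0.0, abs=1e-9)
        # windows fully before the step: days 8-13 -> first 8 emitted values
        assert np.allclose(vals[:8], vals[0])
        # windows fully after the step -> exactly 0
        assert np.allclose(vals[-8:], 0.0, atol=1e-9)
        # the 6-day transition stays bounded by the plateau level
        assert (vals[8:-8] <= vals[0] + 1e-9).all() and (vals[8:-8] >= 0).all()


class TestLog1pSummary:
    def test_all_zero_indices(self):
        s = log1p_summary([0.0] * 10)
        assert all(v == 0.0 for v in s.values())

    def test_closed_form_transform(self):
        s = log1p_summary([0.0, np.e - 1.0])
        assert s["whisker_low"] == 0.0
        assert s["whisker_high"] == pytest.approx(1.0)

    def test_median_commutes_with_monotone_transform(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(1.0, 1.5, 10001)
        s = log1p_summary(x)
        assert s["median"] == pytest.approx(np.log1p(np.median(x)), rel=1e-12)
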