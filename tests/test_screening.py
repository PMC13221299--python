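"""Daily aggregation, edge trimming, wear filters, SD trimming, summaries."""

import numpy as np
import pandas as pd
import pytest

import pedbc as pb
from pedbc.screening import EXCLUSION_REASONS


def epoch(subject, ts, kind, category=None, duration=0.0, steps=0):
    return {
        "subject_id": subject,
        "timestamp": ts,
        "kind": kind,
        "category": category,
        "duration_min": duration,
        "steps": steps,
    }


class TestAggregateDaily:
    def test_single_activity_epoch(self):
        days = pb.aggregate_daily(
            pd.DataFrame([epoch("A", "2021-01-05 10:00", "activity", "light", 30)])
        )
        assert len(days) == 1
        row = days.iloc[0]
        assert row.light_min == 30 and row.monitored_min == 30
        assert row.date == pd.Timestamp("2021-01-05")

    def test_sleep_episode_spanning_midnight_credits_wake_day(self):
        days = pb.aggregate_daily(
            pd.DataFrame([epoch("A", "2021-01-05 21:00", "sleep", duration=570)])
        )
        row = days.iloc[0]
        assert row.date == pd.Timestamp("2021-01-06")
        assert row.sleep_min == 570

    def test_morning_sleep_credits_same_day(self):
        days = pb.aggregate_daily(
            pd.DataFrame([epoch("A", "2021-01-06 00:30", "sleep", duration=360)])
        )
        assert days.iloc[0].date == pd.Timestamp("2021-01-06")

    def test_afternoon_sleep_outside_window_dropped(self):
        days = pb.aggregate_daily(
            pd.DataFrame(
                [
                    epoch("A", "2021-01-05 14:00", "sleep", duration=60),
                    epoch("A", "2021-01-05 10:00", "activity", "light", 30),
                ]
            )
        )
        assert days.iloc[0].sleep_min == 0

    def test_full_day_of_category_epochs(self):
        rows = [
            epoch("A", "2021-01-05 00:00", "activity", "sedentary", 800),
            epoch("A", "2021-01-05 13:20", "activity", "light", 500),
            epoch("A", "2021-01-05 21:40", "activity", "moderate", 100),
            epoch("A", "2021-01-05 23:20", "activity", "vigorous", 40),
        ]
        days = pb.aggregate_daily(pd.DataFrame(rows))
        assert days.iloc[0].monitored_min == 1440

    def test_overlapping_activity_epochs_raise(self):
        rows = [
            epoch("A", "2021-01-05 10:00", "activity", "light", 120),
            epoch("A", "2021-01-05 11:00", "activity", "moderate", 30),
        ]
        with pytest.raises(ValueError, match="overlap"):
            pb.aggregate_daily(pd.DataFrame(rows))

    def test_steps_summed_per_day(self):
        rows = [
            epoch("A", "2021-01-05 09:00", "steps", steps=4000),
            epoch("A", "2021-01-05 18:00", "steps", steps=3000),
        ]
        assert pb.aggregate_daily(pd.DataFrame(rows)).iloc[0].steps == 7000


class TestTrimEdgeDays:
    def _days(self, n, subject="A"):
        return pd.DataFrame(
            {
                "subject_id": subject,
                "date": pd.date_range("2021-01-04", periods=n),
                "monitored_min": 1360.0,
                "light_min": 250.0,
                "moderate_min": 60.0,
                "vigorous_min": 30.0,
                "sedentary_min": 1020.0,
                "steps": 8000,
                "sleep_min": 480.0,
            }
        )

    def test_eleven_days_keep_middle_five(self):
        kept, excluded = pb.trim_edge_days(self._days(11))
        assert len(kept) == 5 and len(excluded) == 6
        assert kept.date.min() == pd.Timestamp("2021-01-07")
        assert kept.date.max() == pd.Timestamp("2021-01-11")
        assert (excluded.reason == "edge_day").all()

    def test_six_days_all_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="all excluded"):
            kept, excluded = pb.trim_edge_days(self._days(6))
        assert len(kept) == 0 and len(excluded) == 6

    def test_zero_edge_is_identity(self):
        kept, excluded = pb.trim_edge_days(self._days(4), n_edge=0)
        assert len(kept) == 4 and len(excluded) == 0


class TestWearFilters:
    def _day(self, monitored, light=250.0, moderate=60.0, vigorous=30.0):
        return pd.DataFrame(
            [
                {
                    "subject_id": "A",
                    "date": pd.Timestamp("2021-01-07"),
                    "sedentary_min": monitored - light - moderate - vigorous,
                    "light_min": light,
                    "moderate_min": moderate,
                    "vigorous_min": vigorous,
                    "monitored_min": monitored,
                    "steps": 8000,
                    "sleep_min": 480.0,
                }
            ]
        )

    def test_relative_durations(self):
        day = self._day(1296.0, light=100.0, moderate=30.0, vigorous=14.0).iloc[0]
        rel = pb.relative_durations(day)
        assert rel["monitored"] == pytest.approx(0.9)
        assert rel["total_activity"] == pytest.approx(0.1)
        zero = self._day(0.0, light=0.0, moderate=0.0, vigorous=0.0).iloc[0]
        assert all(v == 0 for v in pb.relative_durations(zero).values())

    def test_exact_080_monitored_excluded(self):
        kept, excl = pb.apply_wear_filters(self._day(1152.0))
        assert len(kept) == 0 and excl.iloc[0].reason == "low_monitor"

    def test_low_activity_reason_order(self):
        day = self._day(0.85 * 1440, light=40.0, moderate=20.0, vigorous=12.0)
        kept, excl = pb.apply_wear_filters(day)
        assert len(kept) == 0 and excl.iloc[0].reason == "low_activity"

    def test_passing_day_kept(self):
        kept, excl = pb.apply_wear_filters(self._day(0.9 * 1440))
        assert len(kept) == 1 and len(excl) == 0

    def test_loosening_monitor_threshold_never_shrinks_kept_set(self):
        rng = np.random.default_rng(3)
        days = pd.concat(
            [self._day(m) for m in rng.uniform(600, 1440, 40)], ignore_index=True
        )
        kept_strict, _ = pb.apply_wear_filters(days, monitor_threshold=0.8)
        kept_loose, _ = pb.apply_wear_filters(days, monitor_threshold=0.7)
        strict_ids = set(kept_strict.monitored_min)
        loose_ids = set(kept_loose.monitored_min)
        assert strict_ids <= loose_ids


class TestSDFilter:
    def test_hand_worked_example(self):
        values = [10.0] * 9 + [100.0]
        mask, (lo, hi) = pb.apply_sd_filter(values)
        assert lo == pytest.approx(19 - 2 * 28.4605, abs=1e-3)
        assert hi == pytest.approx(19 + 2 * 28.4605, abs=1e-3)
        assert mask.sum() == 9 and not mask[-1]

    def test_all_equal_kept_with_warning(self):
        with pytest.warns(UserWarning, match="zero SD"):
            mask, _ = pb.apply_sd_filter([5.0, 5.0, 5.0])
        assert mask.all()

    def test_boundary_value_kept_inclusively(self):
        # seven 0s with +/-4 at the ends: sd = 2, bounds exactly [-4, 4]
        values = [0.0] * 7 + [-4.0, 4.0]
        mask, (lo, hi) = pb.apply_sd_filter(values)
        assert (lo, hi) == (pytest.approx(-4.0), pytest.approx(4.0))
        assert mask.all()


class TestSummaries:
    def test_participant_year_means(self):
        days = pd.DataFrame(
            {
                "subject_id": ["A", "A"],
                "wave": [1, 1],
                "steps": [6000, 8000],
                "light_min": [100.0, 120.0],
                "moderate_min": [40.0, 60.0],
                "vigorous_min": [10.0, 30.0],
                "sleep_min": [460.0, 500.0],
            }
        )
        out = pb.participant_year_means(days)
        row = out.iloc[0]
        assert row.steps_per_day == 7000
        assert row.activity_min == pytest.approx(180.0)
        assert row.mvpa_min == pytest.approx(70.0)
        assert row.sleep_min == pytest.approx(480.0)

    @pytest.mark.parametrize(
        "mvpa,expected",
        [([70, 80], 1.0), ([10, 20], 0.0), ([70, 70, 70, 70, 70, 50], 5 / 6)],
    )
    def test_mvpa_compliance(self, mvpa, expected):
        df = pd.DataFrame({"mvpa_min": mvpa})
        assert pb.mvpa_compliance(df) == pytest.approx(expected)

    def test_mvpa_empty_raises(self):
        with pytest.raises(ValueError):
            pb.mvpa_compliance(pd.DataFrame({"mvpa_min": [np.nan]}))


class TestEndToEndFixture:
    def test_designed_exclusion_counts(self, screening_fixture):
        result = pb.screen_days(screening_fixture)
        counts = result.excluded.reason.value_counts().to_dict()
        assert counts == {
            "edge_day": 18,
            "low_monitor": 1,
            "low_activity": 1,
            "steps_outlier": 1,
            "sleep_outlier": 1,
        }
        assert len(result.retained) == 11
        assert set(result.excluded.reason) <= set(EXCLUSION_REASONS)

    def test_partition_property(self, screening_fixture):
        result = pb.screen_days(screening_fixture)
        inputs = set(zip(screening_fixture.subject_id, screening_fixture.date))
        retained = set(zip(result.retained.subject_id, result.retained.date))
        excluded = set(zip(result.excluded.subject_id, result.excluded.date))
        assert retained | excluded == inputs
        assert retained & excluded == set()

    def test_order_invariance(self, screening_fixture):
        shuffled = screening_fixture.sample(frac=1.0, random_state=5)
        a = pb.screen_days(screening_fixture)
        b = pb.screen_days(shuffled)
        key = lambda df: sorted(zip(df.subject_id, df.date))
        assert key(a.retained) == key(b.retained)
        pd.testing.assert_frame_equal(a.summaries, b.summaries)

    def test_fully_trimmed_subject_gets_null_summary(self):
        days = pd.DataFrame(
            {
                "subject_id": "A",
                "wave": 1,
                "date": pd.date_range("2021-01-04", periods=5),
                "sedentary_min": 1020.0,
                "light_min": 250.0,
                "moderate_min": 60.0,
                "vigorous_min": 30.0,
                "monitored_min": 1360.0,
                "steps": 8000,
                "sleep_min": 480.0,
            }
        )
        with pytest.warns(UserWarning):
            result = pb.screen_days(days)
        assert len(result.summaries) == 1
        assert result.summaries.iloc[0][["steps_per_day", "sleep_min"]].isna().all()

    def test_generated_traces_partition(self):
        traces = []
        for i, subject in enumerate(["S1", "S2", "S3", "S4"]):
            t = pb.generate_device_days(subject, seed=9)
            t["wave"] = 1
            traces.append(t)
        days = pd.concat(traces, ignore_index=True)
        result = pb.screen_days(days)
        assert len(result.retained) + len(result.excluded) == len(days)
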