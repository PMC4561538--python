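import math

import numpy as np
import pandas as pd
import pytest

from mapsmini.accelerometry import (
    FREEDSON_ADULT_MODERATE_CPM,
    AccelConfig,
    AgeGroup,
    DailySummary,
    EpochSeries,
    LocationIntervals,
    WearMask,
    detect_nonwear,
    filter_nonschool,
    freedson_youth_cutpoint,
    link_neighborhood,
    mean_daily_mvpa,
    mvpa_minutes,
    read_epoch_csv,
    summarize_days,
    write_epoch_csv,
)

MON_7AM = "2010-04-05T07:00:00"  # a Monday


def series_60s(counts, start=MON_7AM, pid="P1"):
    return EpochSeries.from_start(pid, 60, start, counts)


def brute_force_nonwear(counts, epoch_length, window_minutes):
    """Independent oracle: enumerate every maximal zero run and flag those
    lasting at least the window."""
    n = len(counts)
    wear = [True] * n
    window_epochs = math.ceil(window_minutes * 60 / epoch_length)
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if j - i >= window_epochs:
                for k in range(i, j):
                    wear[k] = False
            i = j
        else:
            i += 1
    return wear


class TestDetectNonwear:
    def test_forty_five_minute_zero_run_flagged_at_45_window(self):
        s = series_60s([0] * 45)
        assert not detect_nonwear(s, 45).wear.any()  # boundary inclusive

    def test_nineteen_minute_zero_run_kept_at_20_window(self):
        s = series_60s([100] + [0] * 19 + [100])
        assert detect_nonwear(s, 20).wear.all()

    def test_all_nonzero_is_all_wear(self):
        s = series_60s([5, 10, 3, 900])
        assert detect_nonwear(s, 20).wear.all()

    def test_single_nonzero_epoch_terminates_run(self):
        # two 15-min zero runs split by one active epoch: neither reaches 20
        s = series_60s([0] * 15 + [50] + [0] * 15)
        assert detect_nonwear(s, 20).wear.all()
        # without the interruption the 31-epoch run is flagged
        s2 = series_60s([0] * 31)
        assert not detect_nonwear(s2, 20).wear.any()

    def test_empty_series_gives_empty_mask(self):
        assert len(detect_nonwear(series_60s([]), 20)) == 0

    @pytest.mark.parametrize("epoch_length,window", [(60, 20), (30, 20), (60, 45), (30, 30)])
    def test_matches_bruteforce_oracle_on_random_series(self, epoch_length, window):
        rng = np.random.default_rng(60 * epoch_length + window)
        for _ in range(40):
            n = int(rng.integers(1, 400))
            counts = rng.choice([0, 0, 0, 40, 900], size=n)
            s = EpochSeries.from_start("P1", epoch_length, MON_7AM, counts)
            got = detect_nonwear(s, window).wear.tolist()
            assert got == brute_force_nonwear(counts, epoch_length, window)


class TestValidDay:
    def make_day(self, wear_minutes):
        # wear_minutes of counts=100 beginning at midnight, zeros after
        counts = [100] * wear_minutes + [0] * (1440 - wear_minutes)
        return EpochSeries.from_start("P1", 60, "2010-04-05T00:00:00", counts)

    @pytest.mark.parametrize("wear_minutes,valid", [(600, True), (599, False)])
    def test_ten_hour_threshold_is_inclusive(self, wear_minutes, valid):
        s = self.make_day(wear_minutes)
        cfg = AccelConfig.for_age_group("older_adult")
        mask = detect_nonwear(s, cfg.nonwear_window)
        days = summarize_days(s, mask, cfg)
        assert len(days) == 1
        assert days[0].wear_minutes == wear_minutes
        assert days[0].valid is valid

    def test_zero_wear_day_invalid_with_zero_mvpa(self):
        s = self.make_day(0)
        cfg = AccelConfig.for_age_group("older_adult")
        day = summarize_days(s, detect_nonwear(s, cfg.nonwear_window), cfg)[0]
        assert not day.valid and day.mvpa_minutes == 0.0


class TestMvpaMinutes:
    def test_two_30s_epochs_above_cutpoint_is_one_minute(self):
        s = EpochSeries.from_start("P1", 30, MON_7AM, [1000, 1000, 10, 10])
        mask = WearMask(np.ones(4, dtype=bool))
        # 1000 counts/30 s = 2000 cpm >= 1952
        per_day = mvpa_minutes(s, mask, FREEDSON_ADULT_MODERATE_CPM)
        assert per_day.sum() == pytest.approx(1.0)

    def test_no_epoch_above_cutpoint(self):
        s = series_60s([100, 200, 300])
        assert mvpa_minutes(s, WearMask(np.ones(3, bool)), 1952).sum() == 0.0

    def test_sixty_60s_epochs_above_cutpoint_is_sixty_minutes(self):
        s = series_60s([2000] * 60)
        assert mvpa_minutes(s, WearMask(np.ones(60, bool)), 1952).sum() == pytest.approx(60.0)

    def test_nonwear_epochs_never_count(self):
        s = series_60s([2000] * 10)
        mask = WearMask(np.array([True] * 5 + [False] * 5))
        assert mvpa_minutes(s, mask, 1952).sum() == pytest.approx(5.0)

    def test_monotone_in_cutpoint_and_additive_over_days(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 4000, size=2880)
        s = EpochSeries.from_start("P1", 60, "2010-04-05T00:00:00", counts)
        mask = WearMask(np.ones(len(s), bool))
        cuts = [500, 1000, 1952, 3000]
        totals = [mvpa_minutes(s, mask, c).sum() for c in cuts]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        per_day = mvpa_minutes(s, mask, 1952)
        assert len(per_day) == 2 and per_day.sum() == pytest.approx(totals[2])

    def test_nonpositive_cutpoint_rejected(self):
        s = series_60s([10])
        with pytest.raises(ValueError):
            mvpa_minutes(s, WearMask(np.ones(1, bool)), 0)


class TestClockWindows:
    def test_weekday_window_boundaries(self):
        # Tuesday 2010-04-06, one epoch at 14:59 and one at 15:00
        s = EpochSeries.from_start("P1", 60, "2010-04-06T14:59:00", [10, 20])
        kept = filter_nonschool(s)
        assert kept.timestamps.hour.tolist() == [15]

    def test_weekend_fully_included(self):
        s = EpochSeries.from_start("P1", 60, "2010-04-10T09:00:00", [10] * 5)  # Saturday
        assert len(filter_nonschool(s)) == 5

    def test_late_evening_excluded(self):
        s = EpochSeries.from_start("P1", 60, "2010-04-06T22:59:00", [10, 20, 30])
        kept = filter_nonschool(s)
        assert kept.timestamps.hour.tolist() == [22]  # 23:00+ excluded

    def test_idempotent(self):
        s = EpochSeries.from_start("P1", 60, "2010-04-06T12:00:00", list(range(1, 601)))
        once = filter_nonschool(s)
        twice = filter_nonschool(once)
        assert (once.timestamps == twice.timestamps).all()
        assert (once.counts == twice.counts).all()


class TestNeighborhoodLinkage:
    def test_no_intervals_keeps_nothing(self):
        s = series_60s([10] * 5)
        iv = LocationIntervals("P1", [])
        assert len(link_neighborhood(s, iv)) == 0

    def test_covering_interval_keeps_everything(self):
        s = series_60s([10] * 5)
        iv = LocationIntervals("P1", [(pd.Timestamp("2010-04-05T00:00:00"),
                                       pd.Timestamp("2010-04-06T00:00:00"))])
        assert len(link_neighborhood(s, iv)) == 5

    def test_half_open_interval_convention(self):
        s = series_60s([10] * 10)  # epochs start 07:00 .. 07:09
        iv = LocationIntervals("P1", [(pd.Timestamp("2010-04-05T07:03:00"),
                                       pd.Timestamp("2010-04-05T07:06:00"))])
        kept = link_neighborhood(s, iv)
        # membership oracle over epoch start times
        expected = [t for t in s.timestamps
                    if iv.intervals[0][0] <= t < iv.intervals[0][1]]
        assert list(kept.timestamps) == expected
        assert len(kept) == 3  # 07:03, 07:04, 07:05; the epoch at the end is out

    def test_output_is_subset_of_input(self):
        rng = np.random.default_rng(1)
        s = series_60s(rng.integers(0, 100, 300).tolist())
        iv = LocationIntervals("P1", [(pd.Timestamp("2010-04-05T08:00:00"),
                                       pd.Timestamp("2010-04-05T09:30:00"))])
        kept = link_neighborhood(s, iv)
        assert set(kept.timestamps) <= set(s.timestamps)

    def test_interval_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            LocationIntervals("P1", [(pd.Timestamp("2010-04-05T09:00:00"),
                                      pd.Timestamp("2010-04-05T08:00:00"))])


class TestMeanDailyMvpa:
    def day(self, mvpa, valid=True):
        return DailySummary(date=pd.Timestamp("2010-04-05").date(), wear_minutes=700,
                            valid=valid, mvpa_minutes=mvpa, mvpa_minutes_windowed=mvpa,
                            mvpa_minutes_neighborhood=None)

    def test_mean_over_valid_days(self):
        assert mean_daily_mvpa([self.day(30), self.day(50)]) == 40.0

    def test_single_zero_valid_day(self):
        assert mean_daily_mvpa([self.day(0)]) == 0.0

    def test_invalid_days_excluded_from_mean(self):
        days = [self.day(30), self.day(50), self.day(500, valid=False)]
        assert mean_daily_mvpa(days) == 40.0

    def test_no_valid_days_returns_excluded_not_zero(self):
        assert mean_daily_mvpa([self.day(30, valid=False)]) is None


class TestConfigAndCutpoints:
    def test_youth_cutpoint_equation(self):
        # direct solution of the youth MET regression at age 10, 4 METs
        cpm = freedson_youth_cutpoint(10, 4.0)
        mets = 2.757 + 0.0015 * cpm - 0.08957 * 10 - 0.000038 * cpm * 10
        assert mets == pytest.approx(4.0)

    def test_default_configs_by_group(self):
        child = AccelConfig.for_age_group("child")
        adol = AccelConfig.for_age_group("adolescent")
        older = AccelConfig.for_age_group("older_adult")
        assert (child.nonwear_window, adol.nonwear_window, older.nonwear_window) == (20, 30, 45)
        assert older.cutpoint_counts_per_min == FREEDSON_ADULT_MODERATE_CPM
        with pytest.raises(ValueError, match="adult"):
            AccelConfig.for_age_group("adult")

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            AccelConfig("child", nonwear_window=0, cutpoint_counts_per_min=1000)
        with pytest.raises(ValueError):
            AccelConfig("child", nonwear_window=20, cutpoint_counts_per_min=1000,
                        min_valid_hours=25)


def test_epoch_csv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    series = {
        "A": EpochSeries.from_start("A", 30, MON_7AM, rng.integers(0, 500, 100)),
        "B": EpochSeries.from_start("B", 60, MON_7AM, rng.integers(0, 500, 50)),
    }
    path = write_epoch_csv(series, tmp_path / "epochs.csv")
    back = read_epoch_csv(path)
    assert set(back) == {"A", "B"}
    for pid in series:
        assert back[pid].epoch_length == series[pid].epoch_length
        assert (back[pid].counts == series[pid].counts).all()
        assert (back[pid].timestamps == series[pid].timestamps).all()
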