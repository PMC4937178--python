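"""Beats-in-zone counting and adaptive weekly-target bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiofit import (
    HRSeries,
    HRZone,
    TrainingWeekState,
    ValidationError,
    adaptive_daily_target,
    count_mbeats,
    day_progress,
    record_day,
    record_day_total,
    weekly_percent,
)

WEEK = ("T", "R", "T", "R", "T", "R", "R")
ZONE = HRZone(110, 130)


def constant_series(hr: float, seconds: int) -> HRSeries:
    return HRSeries(np.arange(seconds, dtype=float), np.full(seconds, float(hr)))


class TestCountMbeats:
    def test_thirty_minutes_at_120_bpm_gives_3600(self):
        assert count_mbeats(constant_series(120, 1800), ZONE) == pytest.approx(3600.0)

    def test_out_of_zone_counts_nothing(self):
        assert count_mbeats(constant_series(95, 1800), ZONE) == 0.0

    def test_empty_series_counts_zero(self):
        assert count_mbeats(HRSeries(np.empty(0), np.empty(0)), ZONE) == 0.0

    def test_matches_per_sample_brute_force(self):
        rng = np.random.default_rng(42)
        t = np.arange(600.0)
        hr = rng.uniform(80, 160, size=600)
        series = HRSeries(t, hr)
        expected = 0.0
        for i in range(600):
            dt = (t[i + 1] - t[i]) if i < 599 else 1.0
            if ZONE.lower <= hr[i] <= ZONE.upper:
                expected += hr[i] / 60.0 * dt
        assert count_mbeats(series, ZONE) == pytest.approx(expected, abs=1e-9)

    def test_gap_samples_contribute_zero_beats(self):
        # 10 in-zone seconds, then a 60 s dropout, then 10 more
        t = np.concatenate([np.arange(10.0), np.arange(70.0, 80.0)])
        series = HRSeries(t, np.full(20, 120.0))
        # sample at t=9 is followed by a 61 s gap and must not count
        assert count_mbeats(series, ZONE) == pytest.approx(19 * 2.0)

    def test_implausible_samples_excluded(self):
        series = HRSeries(np.arange(3.0), np.array([120.0, 5.0, 120.0]))
        assert count_mbeats(series, HRZone(1, 200)) == pytest.approx(4.0)

    def test_unordered_timestamps_rejected(self):
        with pytest.raises(ValidationError):
            HRSeries(np.array([0.0, 2.0, 1.0]), np.full(3, 120.0))

    @given(st.integers(2, 200), st.integers(0, 10**6))
    def test_additive_over_disjoint_segments(self, n, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(float(n))
        hr = rng.uniform(90, 150, size=n)
        series = HRSeries(t, hr)
        cut = n // 2
        left = HRSeries(t[:cut], hr[:cut]) if cut else HRSeries(np.empty(0), np.empty(0))
        right = HRSeries(t[cut:], hr[cut:])
        total = count_mbeats(series, ZONE)
        assert total == pytest.approx(count_mbeats(left, ZONE) + count_mbeats(right, ZONE), abs=1e-9)

    def test_linearity_in_sample_spacing(self):
        # doubling every dt doubles the beats at fixed HR
        base = constant_series(120, 300)
        stretched = HRSeries(base.t * 2.0, base.hr, nominal_rate=0.5)
        assert count_mbeats(stretched, ZONE) == pytest.approx(2 * count_mbeats(base, ZONE))


class TestAdaptiveTargets:
    def test_fresh_week_splits_target_over_training_days(self):
        state = TrainingWeekState.start(10800, WEEK)
        assert adaptive_daily_target(state) == 3600.0

    def test_rest_day_targets_zero(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 3600)
        assert state.day_types[1].value == "R"
        assert adaptive_daily_target(state) == 0.0

    def test_strong_first_day_redistributes_remainder(self):
        # 7000 of 10,800 on day one leaves 3800 over 2 training days -> 1900
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 7000)
        state = record_day_total(state, 1, 0)
        assert adaptive_daily_target(state) == 1900.0

    def test_exceeded_weekly_target_clamps_daily_targets_to_zero(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 12000)
        for day in range(1, 7):
            assert adaptive_daily_target(state) == 0.0
            state = record_day_total(state, day, 0)

    def test_rest_day_bonus_lowers_next_training_target(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 3600)
        state = record_day_total(state, 1, 1000)   # bonus beats on a rest day
        assert adaptive_daily_target(state) == pytest.approx((10800 - 4600) / 2)

    def test_no_training_days_left_returns_zero_with_outstanding_target(self, caplog):
        state = TrainingWeekState.start(10800, ("T", "R", "R", "R", "R", "R", "R"))
        state = record_day_total(state, 0, 100)
        state = record_day_total(state, 1, 0)
        with caplog.at_level("WARNING", logger="cardiofit.mbeats"):
            assert adaptive_daily_target(state) == 0.0

    @given(
        achievements=st.lists(st.floats(0, 6000), min_size=7, max_size=7),
        weekly=st.floats(1000, 20000),
    )
    def test_conservation_of_remaining_targets(self, achievements, weekly):
        """Planned remaining daily targets always cover the outstanding weekly total."""
        state = TrainingWeekState.start(weekly, WEEK)
        for day, got in enumerate(achievements):
            planned = 0.0
            probe = state
            for d in range(probe.current_day_index, 7):
                tgt = adaptive_daily_target(probe)
                planned += tgt
                probe = record_day_total(probe, d, tgt)
            if state.remaining_training_days() > 0:
                assert planned == pytest.approx(state.remaining_target, abs=1e-6)
            state = record_day_total(state, day, got)


class TestWeekBookkeeping:
    def test_out_of_order_recording_rejected(self):
        state = TrainingWeekState.start(10800, WEEK)
        with pytest.raises(ValidationError):
            record_day_total(state, 3, 100)

    def test_empty_series_records_zero(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day(state, 0, HRSeries(np.empty(0), np.empty(0)), ZONE)
        assert state.achieved[0] == 0.0

    def test_weekly_percent_after_full_week(self):
        state = TrainingWeekState.start(10800, WEEK)
        per_day = (3600, 0, 3600, 500, 3600, 0, 0)
        for day, got in enumerate(per_day):
            state = record_day_total(state, day, got)
        assert weekly_percent(state) == pytest.approx(100 * sum(per_day) / 10800)

    def test_exceeding_the_week_is_representable(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 12280)
        assert weekly_percent(state) == pytest.approx(113.7, abs=0.05)

    def test_half_the_target_is_fifty_percent(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 5400)
        assert weekly_percent(state) == 50.0

    def test_zero_weekly_target_percent_rejected(self):
        state = TrainingWeekState.start(0.0, WEEK)
        with pytest.raises(ValidationError):
            weekly_percent(state)

    def test_rest_day_progress_reports_target_met(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 3600)
        state = record_day_total(state, 1, 0)
        progress = day_progress(state, 1, 0.0)
        assert progress.percent_of_target == 100.0

    def test_training_day_progress_fraction(self):
        state = TrainingWeekState.start(10800, WEEK)
        state = record_day_total(state, 0, 1800)
        assert day_progress(state, 0, 3600.0).percent_of_target == 50.0
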