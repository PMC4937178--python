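"""Beats-in-zone (mBeats) accounting over heart-rate streams, and weekly targets.

mBeats are the heart beats accumulated while the heart rate lies inside a
personalized target zone.  A wearable reports bpm samples, not beat events, so
beats are integrated per sample as ``hr/60 * dt`` (left-Riemann), counting a
sample only when its HR falls inside the zone.  Gaps longer than
``gap_threshold_s`` contribute zero beats — missing data is never interpolated.

The weekly target (from the prescription) is split over planned training days;
each morning the remaining weekly mBeats are divided equally over the
remaining training days, so a strong day lowers subsequent daily targets and
beats collected on a rest day count as a bonus toward the week.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import ValidationError

log = logging.getLogger(__name__)

HR_VALID_LOW = 25.0    # bpm, exclusive; below is sensor noise / dropout
HR_VALID_HIGH = 250.0  # bpm, exclusive
DEFAULT_GAP_THRESHOLD_S = 5.0


@dataclass(frozen=True)
class HRSeries:
    """A uniformly-sampled (nominally 1 Hz) heart-rate stream.

    ``t`` holds seconds since stream start, strictly increasing; ``hr`` the
    bpm sample at each instant.  Samples outside (25, 250) bpm are kept but
    flagged invalid and excluded from beat counting.
    """

    t: np.ndarray
    hr: np.ndarray
    nominal_rate: float = 1.0   # samples per second

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        hr = np.asarray(self.hr, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "hr", hr)
        if t.ndim != 1 or hr.ndim != 1 or t.shape != hr.shape:
            raise ValidationError("t and hr must be 1-D arrays of equal length")
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValidationError(f"timestamps not strictly increasing at sample {bad}")
        if len(t) and not (np.all(np.isfinite(t)) and np.all(np.isfinite(hr))):
            raise ValidationError("non-finite values in series")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of physiologically plausible samples."""
        return (self.hr > HR_VALID_LOW) & (self.hr < HR_VALID_HIGH)

    @property
    def dt(self) -> np.ndarray:
        """Per-sample exposure in seconds; the final sample gets the nominal step."""
        if len(self.t) == 0:
            return np.empty(0)
        return np.append(np.diff(self.t), 1.0 / self.nominal_rate)

    def gaps(self, gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S) -> list[tuple[float, float]]:
        """Recording gaps as (start time, duration) pairs; never interpolated."""
        dt = self.dt
        idx = np.flatnonzero(dt > gap_threshold_s)
        return [(float(self.t[i]), float(dt[i])) for i in idx]

    @property
    def duration_s(self) -> float:
        if len(self.t) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0] + 1.0 / self.nominal_rate)


@dataclass(frozen=True)
class HRZone:
    """Closed personal heart-rate zone [lower, upper] in bpm."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError(f"zone lower {self.lower} must be below upper {self.upper}")

    @classmethod
    def around(cls, target_hr: float, below: float = 10.0, above: float = 10.0) -> "HRZone":
        """Zone centred on the target HR; +/-10 bpm default width."""
        return cls(lower=target_hr - below, upper=target_hr + above)

    def contains(self, hr: np.ndarray) -> np.ndarray:
        return (hr >= self.lower) & (hr <= self.upper)


def count_mbeats(
    series: HRSeries,
    zone: HRZone,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
) -> float:
    """Heart beats accumulated while HR lies inside the zone.

    Per-sample left-Riemann accounting: each sample contributes
    ``hr/60 * dt`` beats when inside the zone and valid.  Samples followed by
    a gap longer than ``gap_threshold_s`` contribute nothing.  Empty series
    count zero.
    """
    if len(series) == 0:
        return 0.0
    dt = series.dt
    mask = zone.contains(series.hr) & series.valid & (dt <= gap_threshold_s)
    return float(np.sum(series.hr[mask] / 60.0 * dt[mask]))


class DayType(str, Enum):
    TRAINING = "T"
    REST = "R"

    @classmethod
    def parse(cls, value: "str | DayType") -> "DayType":
        if isinstance(value, DayType):
            return value
        v = str(value).strip().upper()
        if v in ("T", "TRAINING"):
            return cls.TRAINING
        if v in ("R", "REST"):
            return cls.REST
        raise ValidationError(f"unrecognized day type {value!r}; expected T or R")


@dataclass(frozen=True)
class DayProgress:
    """Achieved mBeats against the day's target.

    A rest day has a zero target: it reports 100% when nothing was collected
    (the day's goal is trivially met) and the achieved beats count as bonus
    toward the week otherwise.
    """

    day_target: float
    achieved: float
    percent_of_target: float


@dataclass(frozen=True)
class TrainingWeekState:
    """One week of planned days and recorded mBeats against the weekly target.

    Immutable; :func:`record_day` returns the advanced state.  ``achieved``
    holds ``None`` for days not yet recorded.
    """

    weekly_target: float
    day_types: tuple[DayType, ...]
    achieved: tuple["float | None", ...]
    current_day_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "day_types", tuple(DayType.parse(d) for d in self.day_types)
        )
        object.__setattr__(self, "achieved", tuple(self.achieved))
        if len(self.day_types) != 7 or len(self.achieved) != 7:
            raise ValidationError("a week has exactly 7 day types and 7 achieved slots")
        if self.weekly_target < 0:
            raise ValidationError("weekly_target must be non-negative")
        if not 0 <= self.current_day_index <= 7:
            raise ValidationError("current_day_index must lie in [0, 7]")
        for i, a in enumerate(self.achieved):
            if a is not None and a < 0:
                raise ValidationError(f"negative achieved mBeats on day {i}")
            if a is not None and i >= self.current_day_index:
                raise ValidationError(f"day {i} recorded but current day is {self.current_day_index}")

    @classmethod
    def start(cls, weekly_target: float, day_types) -> "TrainingWeekState":
        """Fresh week with nothing recorded."""
        return cls(
            weekly_target=float(weekly_target),
            day_types=tuple(DayType.parse(d) for d in day_types),
            achieved=(None,) * 7,
            current_day_index=0,
        )

    @property
    def achieved_total(self) -> float:
        return float(sum(a for a in self.achieved if a is not None))

    @property
    def remaining_target(self) -> float:
        return max(self.weekly_target - self.achieved_total, 0.0)

    def remaining_training_days(self) -> int:
        """Training days from the current day (inclusive) to the week's end."""
        return sum(
            1
            for i in range(self.current_day_index, 7)
            if self.day_types[i] is DayType.TRAINING
        )


def adaptive_daily_target(state: TrainingWeekState) -> float:
    """Today's mBeats target: remaining weekly mBeats split over remaining training days.

    Rest days always target 0.  If the week's training days are exhausted with
    target still outstanding, returns 0 and logs a warning.
    """
    if state.current_day_index >= 7:
        return 0.0
    if state.day_types[state.current_day_index] is DayType.REST:
        return 0.0
    n_remaining = state.remaining_training_days()
    if n_remaining == 0:
        if state.remaining_target > 0:
            log.warning(
                "weekly target cannot be completed: %.0f mBeats remain but no training days left",
                state.remaining_target,
            )
        return 0.0
    return state.remaining_target / n_remaining


def record_day_total(
    state: TrainingWeekState, day_index: int, mbeats: float
) -> TrainingWeekState:
    """Record a day's achieved mBeats and advance the week.

    Days must be recorded in order; rest-day beats count fully toward the
    weekly total (bonus), so they lower subsequent adaptive daily targets.
    """
    if day_index != state.current_day_index:
        raise ValidationError(
            f"days must be recorded in order: expected day {state.current_day_index}, "
            f"got {day_index}"
        )
    if day_index >= 7:
        raise ValidationError("week already complete")
    if mbeats < 0:
        raise ValidationError("achieved mBeats cannot be negative")
    achieved = list(state.achieved)
    achieved[day_index] = float(mbeats)
    return replace(state, achieved=tuple(achieved), current_day_index=day_index + 1)


def record_day(
    state: TrainingWeekState,
    day_index: int,
    series: HRSeries,
    zone: HRZone,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
) -> TrainingWeekState:
    """Count the day's in-zone beats from its HR stream and record them."""
    return record_day_total(state, day_index, count_mbeats(series, zone, gap_threshold_s))


def day_progress(state: TrainingWeekState, day_index: int, day_target: float) -> DayProgress:
    """Achieved-vs-target summary for a recorded day."""
    if not 0 <= day_index < 7:
        raise ValidationError("day_index must lie in [0, 7)")
    achieved = state.achieved[day_index]
    if achieved is None:
        raise ValidationError(f"day {day_index} has not been recorded")
    if day_target < 0:
        raise ValidationError("day_target must be non-negative")
    if day_target == 0:
        percent = 100.0
    else:
        percent = 100.0 * achieved / day_target
    return DayProgress(day_target=day_target, achieved=achieved, percent_of_target=percent)


def weekly_percent(state: TrainingWeekState) -> float:
    """Achieved weekly mBeats as a percentage of the weekly target (may exceed 100)."""
    if state.weekly_target <= 0:
        raise ValidationError("weekly_target must be positive to express a percentage")
    return 100.0 * state.achieved_total / state.weekly_target
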