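"""Submaximal fitness tests computed from heart-rate traces.

Two field tests are implemented:

* **Ruffier-Dickson squat test** — 45 s of paced squats (40 bends/min)
  followed by 3 min of seated recovery.  Three parameters are read off the
  trace: P0, the mean HR over the final 15 s of rest before the squats; P1,
  the maximum HR in the first 15 s of recovery; and P2, the mean HR over
  recovery seconds 60-75.  The recovery index is

      RDI = ((P1 − 70) + 2·(P2 − P0)) / 10

  Lower is fitter (faster recovery, lower peak).

* **Ebbeling single-stage treadmill walk** — 4 min flat at a speed keeping HR
  between 50% and 75% of the age-predicted maximum (220 − age), then 4-5 min
  at the same speed on a 5% incline.  If the minute-7 and minute-8 HRs differ
  by more than 6 bpm the stage is extended one minute.  The steady-state HR
  feeds a VO2max regression:

      VO2max = 15.1 + 21.8·speed − 0.327·HR − 0.263·speed·age
               + 0.00504·HR·age + 5.98·sex      (speed mph, sex 0=F / 1=M)

All analysis windows are half-open [a, b) in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .errors import CoverageError, ValidationError
from .mbeats import HRSeries
from .profiles import Sex, estimate_hr_max

P0_WINDOW_S = 15.0          # final 15 s of rest
P1_WINDOW = (0.0, 15.0)     # recovery, max
P2_WINDOW = (60.0, 75.0)    # recovery, mean
STEADY_STATE_TOLERANCE_BPM = 6.0


class SquatParams(NamedTuple):
    p0: float
    p1: float
    p2: float


def _window(series: HRSeries, a: float, b: float, name: str) -> np.ndarray:
    """Samples with t in [a, b); errors name the offending window."""
    if len(series) == 0:
        raise CoverageError(f"{name} window [{a:g}, {b:g}) s: series is empty")
    end = series.t[-1] + 1.0 / series.nominal_rate
    if series.t[0] > a or end < b:
        raise CoverageError(
            f"{name} window [{a:g}, {b:g}) s not covered: series spans "
            f"[{series.t[0]:g}, {end:g}) s"
        )
    mask = (series.t >= a) & (series.t < b)
    if not mask.any():
        raise CoverageError(f"{name} window [{a:g}, {b:g}) s contains no samples")
    return series.hr[mask]


def extract_squat_params(rest_series: HRSeries, recovery_series: HRSeries) -> SquatParams:
    """Read (P0, P1, P2) off the squat-test rest and recovery traces.

    ``rest_series`` must cover at least the final 15 s before the squats;
    ``recovery_series`` starts at the end of exercise (its first timestamp is
    recovery t=0) and must cover 75 s.
    """
    if len(rest_series) == 0:
        raise CoverageError("rest window: series is empty")
    rest_end = rest_series.t[-1] + 1.0 / rest_series.nominal_rate
    p0 = float(np.mean(_window(rest_series, rest_end - P0_WINDOW_S, rest_end, "rest")))
    t0 = recovery_series.t[0] if len(recovery_series) else 0.0
    p1 = float(np.max(_window(recovery_series, t0 + P1_WINDOW[0], t0 + P1_WINDOW[1], "recovery 0-15 s")))
    p2 = float(np.mean(_window(recovery_series, t0 + P2_WINDOW[0], t0 + P2_WINDOW[1], "recovery 60-75 s")))
    return SquatParams(p0=p0, p1=p1, p2=p2)


def ruffier_dickson_index(p0: float, p1: float, p2: float) -> float:
    """RDI = ((P1 − 70) + 2·(P2 − P0)) / 10; lower values indicate better recovery."""
    if p0 <= 0 or p1 <= 0 or p2 <= 0:
        raise ValidationError("P0, P1, P2 must be positive heart rates")
    return ((p1 - 70.0) + 2.0 * (p2 - p0)) / 10.0


@dataclass(frozen=True)
class SquatTestResult:
    p0: float
    p1: float
    p2: float
    rdi: float

    def __post_init__(self) -> None:
        expected = ruffier_dickson_index(self.p0, self.p1, self.p2)
        if self.rdi != expected:
            raise ValidationError(f"rdi {self.rdi} inconsistent with parameters ({expected})")


def squat_test(rest_series: HRSeries, recovery_series: HRSeries) -> SquatTestResult:
    """Full squat-test analysis: parameter extraction plus the recovery index."""
    p0, p1, p2 = extract_squat_params(rest_series, recovery_series)
    return SquatTestResult(p0=p0, p1=p1, p2=p2, rdi=ruffier_dickson_index(p0, p1, p2))


def ebbeling_vo2max(speed_mph: float, hr_bpm: float, age: float, sex: "Sex | int | str") -> float:
    """Estimated VO2max (mL/kg/min) from the single-stage treadmill walk.

    ``sex`` accepts the Sex enum, "F"/"M", or the regression's 0/1 dummy code.
    """
    if speed_mph <= 0:
        raise ValidationError("treadmill speed must be positive (mph)")
    if hr_bpm <= 0:
        raise ValidationError("HR must be positive")
    code = Sex.parse(sex).code
    return (
        15.1
        + 21.8 * speed_mph
        - 0.327 * hr_bpm
        - 0.263 * speed_mph * age
        + 0.00504 * hr_bpm * age
        + 5.98 * code
    )


def check_walk_speed(hr_observed: float, age: float) -> bool:
    """True when HR sits in [50%, 75%] of the age-predicted maximum (closed bounds)."""
    hr_max = estimate_hr_max(age)
    return 0.50 * hr_max <= hr_observed <= 0.75 * hr_max


class SteadyState(Enum):
    END_TEST = "end_test"
    EXTEND_ONE_MINUTE = "extend_one_minute"


def steady_state_decision(hr_min7: float, hr_min8: float) -> SteadyState:
    """End the walk when minute-7 and minute-8 HR differ by no more than 6 bpm."""
    if abs(hr_min8 - hr_min7) <= STEADY_STATE_TOLERANCE_BPM:
        return SteadyState.END_TEST
    return SteadyState.EXTEND_ONE_MINUTE


@dataclass(frozen=True)
class TreadmillTestResult:
    speed: float        # mph
    stage_hr: float     # steady-state HR fed into the regression, bpm
    hr_min7: float
    hr_min8: float
    extended: bool      # ninth minute used
    vo2max: float


def treadmill_test(
    trace: HRSeries,
    speed_mph: float,
    age: float,
    sex: "Sex | int | str",
) -> TreadmillTestResult:
    """Analyze a treadmill-walk HR trace (t=0 at walk start, seconds).

    Minute-7 and minute-8 HRs are 60-s means over [360, 420) and [420, 480);
    if they differ by more than 6 bpm the ninth minute [480, 540) must be
    present and becomes the stage HR window.  The stage HR — the mean of the
    final minute of the incline stage — feeds the VO2max regression.
    """
    hr_min7 = float(np.mean(_window(trace, 360.0, 420.0, "minute 7")))
    hr_min8 = float(np.mean(_window(trace, 420.0, 480.0, "minute 8")))
    decision = steady_state_decision(hr_min7, hr_min8)
    if decision is SteadyState.END_TEST:
        extended = False
        stage_hr = hr_min8
    else:
        extended = True
        stage_hr = float(np.mean(_window(trace, 480.0, 540.0, "minute 9")))
    return TreadmillTestResult(
        speed=float(speed_mph),
        stage_hr=stage_hr,
        hr_min7=hr_min7,
        hr_min8=hr_min8,
        extended=extended,
        vo2max=ebbeling_vo2max(speed_mph, stage_hr, age, sex),
    )
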