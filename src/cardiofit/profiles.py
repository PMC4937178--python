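"""Participant profiles and age-predicted maximal heart rate.

A profile carries the demographic and resting physiology every downstream
computation needs: the Karvonen target-heart-rate formula uses ``hr_rest`` and
``hr_max``; the submaximal treadmill test uses age and sex; fitness
classification uses the estimated VO2max.  ``hr_max`` defaults to the
age-predicted 220 − age but can be overridden with a measured maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError

AGE_MIN = 1          # years, exclusive lower bound is 0
AGE_MAX = 119        # years, ages >= 120 rejected


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().upper()
        if v in ("F", "FEMALE", "0"):
            return cls.FEMALE
        if v in ("M", "MALE", "1"):
            return cls.MALE
        raise ValidationError(f"unrecognized sex {value!r}; expected F or M")

    @property
    def code(self) -> int:
        """Dummy coding used by the treadmill VO2max regression: 0=female, 1=male."""
        return 0 if self is Sex.FEMALE else 1


def estimate_hr_max(age: float) -> float:
    """Age-predicted maximal heart rate, 220 − age (bpm)."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValidationError(f"age {age} outside validated range ({AGE_MIN}-{AGE_MAX})")
    return 220.0 - float(age)


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics and resting physiology for one participant.

    Parameters
    ----------
    age : int
        Years; must lie in (0, 120).
    sex : Sex or str
        ``F`` or ``M``.
    height_m, weight_kg : float
        Anthropometrics (meters, kilograms).
    hr_rest : float
        Resting heart rate, bpm; must be positive and below ``hr_max``.
    vo2max_estimate : float, optional
        Estimated maximal oxygen uptake, mL/kg/min.  Required only for
        fitness classification.
    hr_max_override : float, optional
        Measured maximal HR; when absent ``hr_max`` is 220 − age.
    """

    age: int
    sex: Sex
    height_m: float
    weight_kg: float
    hr_rest: float
    vo2max_estimate: float | None = None
    hr_max_override: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not AGE_MIN <= self.age <= AGE_MAX:
            raise ValidationError(
                f"age {self.age} outside validated range ({AGE_MIN}-{AGE_MAX})"
            )
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise ValidationError("height and weight must be positive")
        if not 0 < self.hr_rest < self.hr_max:
            raise ValidationError(
                f"hr_rest {self.hr_rest} must lie in (0, hr_max={self.hr_max})"
            )
        if self.vo2max_estimate is not None and self.vo2max_estimate <= 0:
            raise ValidationError("vo2max_estimate must be positive when given")

    @property
    def hr_max(self) -> float:
        if self.hr_max_override is not None:
            return float(self.hr_max_override)
        return 220.0 - float(self.age)

    @property
    def hr_reserve(self) -> float:
        """Heart rate reserve (HRR): hr_max − hr_rest, bpm."""
        return self.hr_max - self.hr_rest
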