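"""Exercise prescription: Karvonen target HR, FITT selection, weekly mBeats target.

The training intensity is expressed as a fraction of heart-rate reserve
(HRR = hr_max − hr_rest).  The Karvonen method converts that fraction into a
target heart rate::

    target_hr = (hr_max − hr_rest) * intensity + hr_rest

A participant is first classified into a fitness band from estimated VO2max
(:mod:`cardiofit.tables`), the band is mapped to FITT ranges, and the minimum
of each range (intensity, session duration, weekly frequency) is prescribed.
The weekly training-load target in mBeats — heart beats to be accumulated
inside the personal HR zone — is the product::

    weekly_mbeats_target = target_hr [bpm] * session_minutes * frequency_per_week

e.g. a sedentary prescription of 120 bpm x 30 min x 3/wk = 10,800 mBeats.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .profiles import ParticipantProfile, Sex, estimate_hr_max
from .tables import ClassificationTable, FittTable

__all__ = [
    "estimate_hr_max",
    "karvonen_target_hr",
    "FitnessClassification",
    "classify_fitness",
    "ExercisePrescription",
    "prescribe",
]


def karvonen_target_hr(hr_max: float, hr_rest: float, intensity_fraction: float) -> float:
    """Target heart rate at a given fraction of heart-rate reserve (bpm).

    Strictly increasing in ``intensity_fraction``, from ``hr_rest`` (fraction
    → 0) to ``hr_max`` (fraction → 1).
    """
    if hr_rest >= hr_max:
        raise ValidationError(f"hr_rest {hr_rest} must be below hr_max {hr_max}")
    if hr_rest <= 0:
        raise ValidationError("hr_rest must be positive")
    if not 0 < intensity_fraction < 1:
        raise ValidationError(
            f"intensity_fraction {intensity_fraction} outside the open interval (0, 1)"
        )
    return (hr_max - hr_rest) * intensity_fraction + hr_rest


@dataclass(frozen=True)
class FitnessClassification:
    """An ordered fitness band plus provenance of the table that produced it."""

    category: str
    rank: int           # 0 = lowest band
    source_table: str


def classify_fitness(
    profile: ParticipantProfile,
    table: ClassificationTable | None = None,
) -> FitnessClassification:
    """Deterministic band lookup from estimated VO2max within the age/sex stratum.

    Values below the lowest cutoff clamp to the lowest band, values above the
    highest cutoff to the highest.
    """
    if table is None:
        table = ClassificationTable.default()
    if profile.vo2max_estimate is None:
        raise ValidationError("profile has no vo2max_estimate; run a fitness test first")
    category, rank = table.band(profile.vo2max_estimate, profile.sex, profile.age)
    return FitnessClassification(category=category, rank=rank, source_table=table.name)


@dataclass(frozen=True)
class ExercisePrescription:
    """Intensity, target HR, session duration, weekly frequency, weekly mBeats.

    ``weekly_mbeats_target`` is always exactly
    ``target_hr * session_minutes * frequency_per_week``; the constructor
    recomputes and enforces the identity.
    """

    intensity_fraction: float
    target_hr: float            # bpm, kept as a real; round only for display
    session_minutes: float
    frequency_per_week: int
    weekly_mbeats_target: float

    def __post_init__(self) -> None:
        if not 0 < self.intensity_fraction < 1:
            raise ValidationError("intensity_fraction must lie in (0, 1)")
        if self.target_hr <= 0 or self.session_minutes <= 0 or self.frequency_per_week < 1:
            raise ValidationError("target_hr, session_minutes, frequency must be positive")
        expected = self.target_hr * self.session_minutes * self.frequency_per_week
        if self.weekly_mbeats_target != expected:
            raise ValidationError(
                f"weekly_mbeats_target {self.weekly_mbeats_target} != "
                f"target_hr*minutes*frequency = {expected}"
            )

    @classmethod
    def from_components(
        cls,
        intensity_fraction: float,
        target_hr: float,
        session_minutes: float,
        frequency_per_week: int,
    ) -> "ExercisePrescription":
        return cls(
            intensity_fraction=intensity_fraction,
            target_hr=float(target_hr),
            session_minutes=float(session_minutes),
            frequency_per_week=int(frequency_per_week),
            weekly_mbeats_target=float(target_hr)
            * float(session_minutes)
            * int(frequency_per_week),
        )

    def to_dict(self) -> dict:
        return {
            "intensity_fraction": self.intensity_fraction,
            "target_hr": self.target_hr,
            "session_minutes": self.session_minutes,
            "frequency_per_week": self.frequency_per_week,
            "weekly_mbeats_target": self.weekly_mbeats_target,
        }


def prescribe(
    profile: ParticipantProfile,
    classification: FitnessClassification,
    fitt_table: FittTable | None = None,
) -> ExercisePrescription:
    """Map a fitness band to FITT ranges and prescribe the minimum of each range.

    The minimum is taken independently per dimension (intensity, duration,
    frequency).  Target HR comes from the Karvonen formula on the profile's
    resting HR and (age-predicted or measured) maximal HR.
    """
    if fitt_table is None:
        fitt_table = FittTable.default()
    row = fitt_table.row(classification.category)
    intensity = row.intensity[0]
    minutes = row.duration_min[0]
    frequency = row.frequency[0]
    target = karvonen_target_hr(profile.hr_max, profile.hr_rest, intensity)
    if not profile.hr_rest < target <= profile.hr_max:
        raise ValidationError("target HR fell outside (hr_rest, hr_max]")  # unreachable guard
    return ExercisePrescription.from_components(intensity, target, minutes, frequency)
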