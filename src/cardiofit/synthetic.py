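"""Synthetic heart-rate streams, test sessions, step counts, and cohorts.

Every consumer-facing computation in this package operates on wearable data
that cannot be redistributed, so this module generates physiologically
plausible stand-ins with known ground truth:

* **Exercise-bout kinetics** — HR responds to exercise onset and offset with
  first-order (mono-exponential) dynamics: it rises toward the Karvonen
  target with time constant ``onset_tau`` and decays back to rest with
  ``recovery_tau``.  Fitter personas have faster kinetics (smaller taus),
  lower resting HR, and a smaller HR excursion for the same relative load.
* **Measurement noise** — additive Gaussian bpm noise on top of the clean
  trajectory; ground truth is always computed on the noise-free trace.
* **Cohorts** — pre/post outcome tables for a three-arm training study
  (step-goal app, HR-zone app, supervised gym), built from group baselines,
  per-group time effects, a subject random intercept, and residual noise.

All generators are pure functions of (parameters, seed): the global seed fans
out into named substreams, so adding a generator never perturbs another's
draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitness_tests import ebbeling_vo2max, extract_squat_params, ruffier_dickson_index
from .mbeats import HRSeries, HRZone, count_mbeats
from .prescription import karvonen_target_hr
from .profiles import Sex

SQUAT_REST_S = 180.0
SQUAT_EXERCISE_S = 45.0      # 45 s paced squats at 40 bends/min
SQUAT_RECOVERY_S = 180.0     # 3-minute recovery

GROUPS = ("Step-App", "CF-App", "Super-CF")
OUTCOMES = ("vo2max", "sbp", "dbp", "hr_rest", "hr_peak", "hr_recovery")


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent named random stream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def vo2max_from_fitness(fitness_level: float) -> float:
    """Map the abstract fitness level in [0, 1] to an estimated VO2max.

    20 mL/kg/min at the sedentary end, 45 at the top — spanning the study
    population's inclusion range (< 45 mL/kg/min).
    """
    return 20.0 + 25.0 * float(fitness_level)


@dataclass(frozen=True)
class PersonaParams:
    """Physiological parameters of one simulated wearer.

    ``recovery_tau`` and ``onset_tau`` are the first-order HR time constants
    in seconds; both shrink with fitness (fit hearts respond and recover
    faster).  ``noise_sd`` is the bpm standard deviation of sensor noise.
    ``onset_tau`` may be exactly 0, meaning an instantaneous step to the
    exercise target (the fast-kinetics limit).
    """

    hr_rest: float
    hr_max: float
    fitness_level: float
    recovery_tau: float
    onset_tau: float
    noise_sd: float = 2.0
    daily_steps_mean: float = 8000.0
    daily_steps_sd: float = 2500.0

    def __post_init__(self) -> None:
        if not 0 < self.hr_rest < self.hr_max:
            raise ValidationError("need 0 < hr_rest < hr_max")
        if not 0.0 <= self.fitness_level <= 1.0:
            raise ValidationError("fitness_level must lie in [0, 1]")
        if self.recovery_tau <= 0 or self.onset_tau < 0:
            raise ValidationError("recovery_tau must be > 0 and onset_tau >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.daily_steps_mean <= 0 or self.daily_steps_sd < 0:
            raise ValidationError("bad step-count parameters")

    @classmethod
    def from_fitness(
        cls, fitness_level: float, age: float = 45.0, noise_sd: float = 2.0
    ) -> "PersonaParams":
        """Persona whose resting HR, kinetics, and habitual steps track fitness."""
        f = float(fitness_level)
        if not 0.0 <= f <= 1.0:
            raise ValidationError("fitness_level must lie in [0, 1]")
        return cls(
            hr_rest=80.0 - 20.0 * f,
            hr_max=220.0 - float(age),
            fitness_level=f,
            recovery_tau=60.0 - 40.0 * f,
            onset_tau=45.0 - 25.0 * f,
            noise_sd=noise_sd,
            daily_steps_mean=6000.0 + 5000.0 * f,
            daily_steps_sd=2500.0,
        )


@dataclass(frozen=True)
class SimulatedSession:
    """A generated HR trace plus its noise-free ground truth.

    ``truth`` holds the quantities downstream estimators should recover;
    ``segments`` maps protocol phase names to [start, end) second bounds on
    the trace.  Regeneration with the same parameters and seed is
    bit-identical.
    """

    series: HRSeries
    truth: dict
    seed: int
    segments: dict = field(default_factory=dict)

    def segment(self, name: str) -> HRSeries:
        """Slice one protocol phase (timestamps kept absolute)."""
        try:
            a, b = self.segments[name]
        except KeyError:
            raise ValidationError(f"session has no segment {name!r}") from None
        mask = (self.series.t >= a) & (self.series.t < b)
        return HRSeries(self.series.t[mask], self.series.hr[mask], self.series.nominal_rate)


def _approach(t: np.ndarray, start: float, target: float, tau: float) -> np.ndarray:
    """First-order approach from ``start`` toward ``target``; tau=0 is a step."""
    if tau == 0.0:
        return np.full_like(t, target, dtype=float)
    return target + (start - target) * np.exp(-t / tau)


def simulate_bout(
    persona: PersonaParams,
    intensity_fraction: float,
    duration_s: float,
    seed: int,
    recovery_s: float = 0.0,
    zone: HRZone | None = None,
) -> SimulatedSession:
    """One exercise bout at a Karvonen intensity, sampled at 1 Hz.

    HR rises from rest toward the Karvonen target with ``onset_tau``; when
    ``recovery_s`` > 0 an exponential recovery tail back toward rest is
    appended.  Ground truth (in-zone beats, total beats) is computed on the
    noise-free trace against ``zone`` (default: target +/- 10 bpm).
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if recovery_s < 0:
        raise ValidationError("recovery_s must be non-negative")
    target = karvonen_target_hr(persona.hr_max, persona.hr_rest, intensity_fraction)
    if zone is None:
        zone = HRZone.around(target)

    n_bout = int(round(duration_s))
    n_rec = int(round(recovery_s))
    t = np.arange(n_bout + n_rec, dtype=float)
    clean = np.empty_like(t)
    clean[:n_bout] = _approach(t[:n_bout], persona.hr_rest, target, persona.onset_tau)
    if n_rec:
        hr_end = float(
            _approach(np.array([float(n_bout)]), persona.hr_rest, target, persona.onset_tau)[0]
        )
        clean[n_bout:] = _approach(
            t[n_bout:] - n_bout, hr_end, persona.hr_rest, persona.recovery_tau
        )
    clean = np.clip(clean, persona.hr_rest, persona.hr_max)

    rng = substream(seed, "bout")
    hr = clean + rng.normal(0.0, persona.noise_sd, size=clean.shape)
    series = HRSeries(t, hr)
    clean_series = HRSeries(t, clean)
    truth = {
        "target_hr": target,
        "zone": (zone.lower, zone.upper),
        "in_zone_beats": count_mbeats(clean_series, zone),
        "total_beats": float(np.sum(clean) / 60.0),   # 1-s exposure per sample
    }
    segments = {"bout": (0.0, float(n_bout)), "recovery": (float(n_bout), float(n_bout + n_rec))}
    return SimulatedSession(series=series, truth=truth, seed=int(seed), segments=segments)


def simulate_squat_test(persona: PersonaParams, seed: int) -> SimulatedSession:
    """Squat-test session: 180 s rest, 45 s squats, 180 s recovery at 1 Hz.

    The squat load drives HR toward ``hr_rest + (0.85 − 0.2·fitness)·reserve``
    with ``onset_tau``; recovery decays back to rest with ``recovery_tau``.
    Truth carries the noise-free (P0, P1, P2) and the recovery index, so
    estimator round-trips can be checked exactly at zero noise.
    """
    n_rest = int(SQUAT_REST_S)
    n_ex = int(SQUAT_EXERCISE_S)
    n_rec = int(SQUAT_RECOVERY_S)
    reserve = persona.hr_max - persona.hr_rest
    ex_target = persona.hr_rest + (0.85 - 0.2 * persona.fitness_level) * reserve

    t = np.arange(n_rest + n_ex + n_rec, dtype=float)
    clean = np.empty_like(t)
    clean[:n_rest] = persona.hr_rest
    t_ex = t[n_rest : n_rest + n_ex] - n_rest
    clean[n_rest : n_rest + n_ex] = _approach(t_ex, persona.hr_rest, ex_target, persona.onset_tau)
    hr_end = float(
        _approach(np.array([float(n_ex)]), persona.hr_rest, ex_target, persona.onset_tau)[0]
    )
    t_rec = t[n_rest + n_ex :] - (n_rest + n_ex)
    clean[n_rest + n_ex :] = _approach(t_rec, hr_end, persona.hr_rest, persona.recovery_tau)
    clean = np.clip(clean, persona.hr_rest, persona.hr_max)

    rec0 = n_rest + n_ex
    p0 = float(np.mean(clean[n_rest - 15 : n_rest]))
    p1 = float(np.max(clean[rec0 : rec0 + 15]))
    p2 = float(np.mean(clean[rec0 + 60 : rec0 + 75]))

    rng = substream(seed, "squat")
    hr = clean + rng.normal(0.0, persona.noise_sd, size=clean.shape)
    series = HRSeries(t, hr)
    truth = {
        "p0": p0,
        "p1": p1,
        "p2": p2,
        "rdi": ruffier_dickson_index(p0, p1, p2),
        "exercise_target_hr": ex_target,
    }
    segments = {
        "rest": (0.0, float(n_rest)),
        "exercise": (float(n_rest), float(rec0)),
        "recovery": (float(rec0), float(len(t))),
    }
    return SimulatedSession(series=series, truth=truth, seed=int(seed), segments=segments)


def simulate_treadmill_test(
    persona: PersonaParams,
    seed: int,
    speed_mph: float = 3.4,
    sex: "Sex | str" = Sex.FEMALE,
) -> SimulatedSession:
    """Treadmill-walk session: 4 min flat then 5 min at 5% incline, 1 Hz.

    The flat stage drives HR toward 60% of the age-predicted maximum (inside
    the protocol's 50-75% window); the incline adds a load that shrinks with
    fitness.  Truth carries the steady-state stage HR and the VO2max the
    regression would return for it.  The persona's age is recovered from its
    age-predicted maximum (220 − hr_max).
    """
    age = 220.0 - persona.hr_max
    flat_target = 0.60 * persona.hr_max
    incline_target = min(flat_target + 8.0 + 12.0 * (1.0 - persona.fitness_level),
                         persona.hr_max - 5.0)

    n_flat, n_total = 240, 540
    t = np.arange(n_total, dtype=float)
    clean = np.empty_like(t)
    clean[:n_flat] = _approach(t[:n_flat], persona.hr_rest, flat_target, persona.onset_tau)
    hr_end = float(
        _approach(np.array([float(n_flat)]), persona.hr_rest, flat_target, persona.onset_tau)[0]
    )
    clean[n_flat:] = _approach(t[n_flat:] - n_flat, hr_end, incline_target, persona.onset_tau)
    clean = np.clip(clean, persona.hr_rest, persona.hr_max)

    rng = substream(seed, "treadmill")
    hr = clean + rng.normal(0.0, persona.noise_sd, size=clean.shape)
    series = HRSeries(t, hr)
    truth = {
        "steady_state_hr": incline_target,
        "vo2max": ebbeling_vo2max(speed_mph, incline_target, age, sex),
        "speed_mph": float(speed_mph),
        "age": age,
    }
    segments = {"flat": (0.0, float(n_flat)), "incline": (float(n_flat), float(n_total))}
    return SimulatedSession(series=series, truth=truth, seed=int(seed), segments=segments)


def simulate_steps(persona: PersonaParams, n_days: int, seed: int) -> np.ndarray:
    """Daily step totals, lognormal around the persona's habitual mean.

    The lognormal reproduces the right skew of free-living step counts; its
    parameters are solved from the persona's arithmetic mean and SD.
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    m, s = persona.daily_steps_mean, persona.daily_steps_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    rng = substream(seed, "steps")
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=int(n_days))


# Group baselines informed by the study population's descriptive statistics
# (three arms, pre/post); between-subject and residual SDs are package defaults.
DEFAULT_BASELINES: dict[str, dict[str, float]] = {
    "vo2max":      {"Step-App": 36.8, "CF-App": 31.7, "Super-CF": 26.9},
    "sbp":         {"Step-App": 124.0, "CF-App": 129.0, "Super-CF": 132.0},
    "dbp":         {"Step-App": 76.9, "CF-App": 83.7, "Super-CF": 87.4},
    "hr_rest":     {"Step-App": 66.0, "CF-App": 70.0, "Super-CF": 74.0},
    "hr_peak":     {"Step-App": 150.0, "CF-App": 155.0, "Super-CF": 160.0},
    "hr_recovery": {"Step-App": 100.0, "CF-App": 106.0, "Super-CF": 112.0},
}

# Post-minus-pre time effects per arm (default cohort conditions).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "vo2max":      {"Step-App": 0.95, "CF-App": 1.70, "Super-CF": 1.85},
    "sbp":         {"Step-App": 1.19, "CF-App": -3.23, "Super-CF": -5.75},
    "dbp":         {"Step-App": -2.12, "CF-App": -4.31, "Super-CF": -3.54},
    "hr_rest":     {"Step-App": -2.74, "CF-App": -3.33, "Super-CF": -7.84},
    "hr_peak":     {"Step-App": -2.0, "CF-App": -3.0, "Super-CF": -5.0},
    "hr_recovery": {"Step-App": -5.01, "CF-App": -3.42, "Super-CF": -11.71},
}

# Between-subject (random intercept) and residual (test-retest) SDs.
DEFAULT_SD_BETWEEN: dict[str, float] = {
    "vo2max": 5.0, "sbp": 10.0, "dbp": 7.0,
    "hr_rest": 7.0, "hr_peak": 10.0, "hr_recovery": 9.0,
}
DEFAULT_SD_RESIDUAL: dict[str, float] = {
    "vo2max": 1.5, "sbp": 4.0, "dbp": 3.0,
    "hr_rest": 3.0, "hr_peak": 4.0, "hr_recovery": 4.0,
}


def null_effects() -> dict:
    """Effect specification with every time effect set to zero (null cohorts)."""
    return {o: {g: 0.0 for g in GROUPS} for o in OUTCOMES}


def simulate_cohort(
    n_per_group: int,
    group_effects: "dict | None" = None,
    seed: int = 0,
    outcomes: "tuple[str, ...] | None" = None,
) -> pd.DataFrame:
    """Tidy long pre/post table for a three-arm training study.

    Each subject's value is ``group baseline + random intercept + (post
    effect if post) + residual``.  ``group_effects`` maps outcome name to
    either a scalar (same time effect in every arm) or a per-group mapping;
    ``None`` uses the package defaults, and outcomes missing from the mapping
    get a zero effect.

    Returns columns ``subject, group, time, outcome, value`` with
    ``time`` in {pre, post}.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    outcomes = OUTCOMES if outcomes is None else tuple(outcomes)
    for o in outcomes:
        if o not in DEFAULT_BASELINES:
            raise ValidationError(f"unknown outcome {o!r}")
    effects = DEFAULT_EFFECTS if group_effects is None else group_effects

    rng = substream(seed, "cohort")
    rows = []
    for g in GROUPS:
        for i in range(n_per_group):
            subject = f"{g}-{i:02d}"
            for o in outcomes:
                eff = effects.get(o, 0.0)
                delta = float(eff) if np.isscalar(eff) else float(eff.get(g, 0.0))
                intercept = DEFAULT_BASELINES[o][g] + rng.normal(0.0, DEFAULT_SD_BETWEEN[o])
                pre = intercept + rng.normal(0.0, DEFAULT_SD_RESIDUAL[o])
                post = intercept + delta + rng.normal(0.0, DEFAULT_SD_RESIDUAL[o])
                rows.append((subject, g, "pre", o, pre))
                rows.append((subject, g, "post", o, post))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "outcome", "value"])


def simulate_fitness_cohort(
    n_subjects: int, seed: int, noise_sd: float = 2.0
) -> pd.DataFrame:
    """Cross-sectional cohort linking squat-test recovery to true fitness.

    Draws a fitness level per subject, generates a noisy squat-test session
    from the matching persona, runs the estimator pipeline (parameter
    extraction + recovery index), and pairs the result with the subject's
    true VO2max.  Used to check that the recovery index carries a negative
    association with fitness.
    """
    if n_subjects < 3:
        raise ValidationError("n_subjects must be >= 3")
    rng = substream(seed, "fitness-cohort")
    fitness = rng.uniform(0.05, 0.95, size=int(n_subjects))
    child_seeds = rng.integers(0, 2**31 - 1, size=int(n_subjects))
    rows = []
    for i in range(int(n_subjects)):
        persona = PersonaParams.from_fitness(float(fitness[i]), noise_sd=noise_sd)
        session = simulate_squat_test(persona, int(child_seeds[i]))
        p0, p1, p2 = extract_squat_params(
            session.segment("rest"), session.segment("recovery")
        )
        rows.append(
            {
                "subject": f"S{i:03d}",
                "fitness_level": float(fitness[i]),
                "vo2max_true": vo2max_from_fitness(float(fitness[i])),
                "p0": p0,
                "p1": p1,
                "p2": p2,
                "rdi": ruffier_dickson_index(p0, p1, p2),
            }
        )
    return pd.DataFrame(rows)
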