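"""Readers and writers for the package's plain-text interchange formats.

* HR streams: CSV with header ``t_sec,hr_bpm`` (seconds from stream start).
* Daily steps: CSV with header ``date,steps``.
* Participant profiles: CSV ``id,age,sex,height_m,weight_kg,hr_rest,vo2max``.
* Week state: JSON sidecar that round-trips :class:`TrainingWeekState`.
* Cohort tables: tidy long CSV ``subject,group,time,outcome,value``.

Malformed rows are reported with their 1-based line number.  Floats are
written with ``repr`` so every writer/reader pair round-trips bit-identically.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .mbeats import DayType, HRSeries, TrainingWeekState
from .profiles import ParticipantProfile, Sex

HR_HEADER = ["t_sec", "hr_bpm"]
PROFILE_HEADER = ["id", "age", "sex", "height_m", "weight_kg", "hr_rest", "vo2max"]


def read_hr_csv(path: "str | Path") -> HRSeries:
    """Load a ``t_sec,hr_bpm`` stream; errors name the offending line."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    t: list[float] = []
    hr: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if [h.strip() for h in header] != HR_HEADER:
            raise ValidationError(f"{path}: expected header {','.join(HR_HEADER)!r}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            try:
                ti, hi = float(row[0]), float(row[1])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric cell in {row}") from None
            if t and ti <= t[-1]:
                raise ValidationError(
                    f"{path}:{lineno}: timestamp {ti} not greater than previous {t[-1]}"
                )
            t.append(ti)
            hr.append(hi)
    return HRSeries(np.array(t), np.array(hr))


def write_hr_csv(series: HRSeries, path: "str | Path") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HR_HEADER)
        for ti, hi in zip(series.t, series.hr):
            writer.writerow([repr(float(ti)), repr(float(hi))])


def read_steps_csv(path: "str | Path") -> pd.DataFrame:
    """Load a ``date,steps`` table."""
    df = pd.read_csv(path)
    if list(df.columns) != ["date", "steps"]:
        raise ValidationError(f"{path}: expected header 'date,steps', got {list(df.columns)}")
    if not pd.api.types.is_numeric_dtype(df["steps"]):
        raise ValidationError(f"{path}: non-numeric step counts")
    return df


def read_profiles_csv(path: "str | Path") -> dict[str, ParticipantProfile]:
    """Load participant profiles keyed by id; ``vo2max`` may be blank."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    profiles: dict[str, ParticipantProfile] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if header != PROFILE_HEADER:
            raise ValidationError(
                f"{path}: expected header {','.join(PROFILE_HEADER)!r}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(PROFILE_HEADER):
                raise ValidationError(f"{path}:{lineno}: expected {len(PROFILE_HEADER)} columns")
            pid = row[0].strip()
            if pid in profiles:
                raise ValidationError(f"{path}:{lineno}: duplicate profile id {pid!r}")
            try:
                vo2 = float(row[6]) if row[6].strip() else None
                profiles[pid] = ParticipantProfile(
                    age=int(row[1]),
                    sex=Sex.parse(row[2]),
                    height_m=float(row[3]),
                    weight_kg=float(row[4]),
                    hr_rest=float(row[5]),
                    vo2max_estimate=vo2,
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return profiles


def read_cohort_csv(path: "str | Path") -> pd.DataFrame:
    """Load a tidy long ``subject,group,time,outcome,value`` table."""
    df = pd.read_csv(path)
    expected = ["subject", "group", "time", "outcome", "value"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected header {','.join(expected)!r}")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        raise ValidationError(f"{path}: non-numeric values in 'value' column")
    return df


# ---------------------------------------------------------------------------
# Week-state JSON round trip

def week_state_to_dict(state: TrainingWeekState) -> dict:
    return {
        "weekly_target": state.weekly_target,
        "day_types": [d.value for d in state.day_types],
        "achieved": list(state.achieved),
        "current_day_index": state.current_day_index,
    }


def week_state_from_dict(data: dict) -> TrainingWeekState:
    extra = set(data) - {"weekly_target", "day_types", "achieved", "current_day_index"}
    if extra:
        raise ValidationError(f"unknown week-state keys {sorted(extra)}")
    try:
        return TrainingWeekState(
            weekly_target=float(data["weekly_target"]),
            day_types=tuple(DayType.parse(d) for d in data["day_types"]),
            achieved=tuple(None if a is None else float(a) for a in data["achieved"]),
            current_day_index=int(data["current_day_index"]),
        )
    except KeyError as exc:
        raise ValidationError(f"week state missing key {exc}") from None


def save_week_state(state: TrainingWeekState, path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(week_state_to_dict(state), fh, indent=2)
        fh.write("\n")


def load_week_state(path: "str | Path") -> TrainingWeekState:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: state file does not exist")
    with open(path, encoding="utf-8") as fh:
        return week_state_from_dict(json.load(fh))


def load_week_plan(path: "str | Path") -> tuple[float, tuple[DayType, ...]]:
    """Week plan YAML: ``weekly_target`` plus a 7-entry ``days`` list of T/R."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    extra = set(data) - {"weekly_target", "days"}
    if extra:
        raise ValidationError(f"{path}: unknown keys {sorted(extra)}")
    try:
        days = tuple(DayType.parse(d) for d in data["days"])
        target = float(data["weekly_target"])
    except KeyError as exc:
        raise ValidationError(f"{path}: missing key {exc}") from None
    if len(days) != 7:
        raise ValidationError(f"{path}: a week plan needs exactly 7 days, got {len(days)}")
    return target, days


# ---------------------------------------------------------------------------
# Run configuration

@dataclass(frozen=True)
class RunConfig:
    """Global run options loadable from YAML; unknown keys are rejected."""

    profiles: "str | None" = None
    fitt: "str | None" = None
    classes: "str | None" = None
    zone_below: float = 10.0
    zone_above: float = 10.0
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a YAML mapping")
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("profiles", "fitt", "classes"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{path}: referenced path does not exist: {p}")
        return cfg
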