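"""Classification and FITT lookup tables.

Both tables ship as editable YAML under ``cardiofit/data`` and can be replaced
by user files with the same schema.  Schemas are validated on load; unknown
keys are rejected so typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError
from .profiles import Sex


def _load_yaml(path: "str | Path") -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a YAML mapping at top level")
    return data


def _default_path(name: str) -> Path:
    return Path(str(resources.files("cardiofit").joinpath("data", name)))


@dataclass(frozen=True)
class Stratum:
    sex: Sex
    age_min: int
    age_max: int
    cutoffs: tuple[float, ...]   # upper bounds (exclusive) between bands

    def covers(self, sex: Sex, age: int) -> bool:
        return sex is self.sex and self.age_min <= age <= self.age_max


@dataclass(frozen=True)
class ClassificationTable:
    """Ordered fitness bands per age x sex stratum, keyed on estimated VO2max."""

    name: str
    categories: tuple[str, ...]
    strata: tuple[Stratum, ...]

    @classmethod
    def from_dict(cls, data: dict, *, source: str = "<dict>") -> "ClassificationTable":
        allowed = {"name", "categories", "strata"}
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError(f"{source}: unknown keys {sorted(unknown)}")
        cats = tuple(str(c) for c in data.get("categories", ()))
        if len(cats) < 2 or len(cats) != len(set(cats)):
            raise ValidationError(f"{source}: need >= 2 distinct categories")
        strata = []
        for raw in data.get("strata", ()):
            extra = set(raw) - {"sex", "age_min", "age_max", "cutoffs"}
            if extra:
                raise ValidationError(f"{source}: unknown stratum keys {sorted(extra)}")
            cutoffs = tuple(float(c) for c in raw["cutoffs"])
            if len(cutoffs) != len(cats) - 1:
                raise ValidationError(
                    f"{source}: stratum needs {len(cats) - 1} cutoffs, got {len(cutoffs)}"
                )
            if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
                raise ValidationError(f"{source}: cutoffs must be strictly increasing")
            strata.append(
                Stratum(
                    sex=Sex.parse(raw["sex"]),
                    age_min=int(raw["age_min"]),
                    age_max=int(raw["age_max"]),
                    cutoffs=cutoffs,
                )
            )
        if not strata:
            raise ValidationError(f"{source}: at least one stratum required")
        return cls(name=str(data.get("name", source)), categories=cats, strata=tuple(strata))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "ClassificationTable":
        return cls.from_dict(_load_yaml(path), source=str(path))

    @classmethod
    def default(cls) -> "ClassificationTable":
        return cls.from_yaml(_default_path("classification.yaml"))

    def stratum_for(self, sex: Sex, age: int) -> Stratum:
        for s in self.strata:
            if s.covers(sex, age):
                return s
        raise ValidationError(
            f"classification table {self.name!r} has no stratum for sex={sex.value}, age={age}"
        )

    def band(self, vo2max: float, sex: Sex, age: int) -> tuple[str, int]:
        """Return (category label, 0-based rank); values off-table clamp to the ends."""
        cutoffs = self.stratum_for(sex, age).cutoffs
        rank = sum(vo2max >= c for c in cutoffs)
        return self.categories[rank], rank


@dataclass(frozen=True)
class FittRow:
    intensity: tuple[float, float]      # fraction of HRR, (min, max)
    duration_min: tuple[float, float]   # minutes per session
    frequency: tuple[int, int]          # sessions per week

    def __post_init__(self) -> None:
        lo, hi = self.intensity
        if not 0 < lo <= hi < 1:
            raise ValidationError(f"intensity range {self.intensity} not within (0, 1)")
        if self.duration_min[0] <= 0 or self.duration_min[0] > self.duration_min[1]:
            raise ValidationError(f"bad duration range {self.duration_min}")
        if self.frequency[0] < 1 or self.frequency[0] > self.frequency[1]:
            raise ValidationError(f"bad frequency range {self.frequency}")


@dataclass(frozen=True)
class FittTable:
    """Per-category FITT ranges; prescription uses the minimum of each range."""

    name: str
    rows: dict[str, FittRow]

    @classmethod
    def from_dict(cls, data: dict, *, source: str = "<dict>") -> "FittTable":
        unknown = set(data) - {"name", "rows"}
        if unknown:
            raise ValidationError(f"{source}: unknown keys {sorted(unknown)}")
        rows = {}
        for cat, raw in (data.get("rows") or {}).items():
            extra = set(raw) - {"intensity", "duration_min", "frequency"}
            if extra:
                raise ValidationError(f"{source}: unknown row keys {sorted(extra)} in {cat!r}")
            rows[str(cat)] = FittRow(
                intensity=tuple(float(x) for x in raw["intensity"]),
                duration_min=tuple(float(x) for x in raw["duration_min"]),
                frequency=tuple(int(x) for x in raw["frequency"]),
            )
        if not rows:
            raise ValidationError(f"{source}: FITT table has no rows")
        return cls(name=str(data.get("name", source)), rows=rows)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "FittTable":
        return cls.from_dict(_load_yaml(path), source=str(path))

    @classmethod
    def default(cls) -> "FittTable":
        return cls.from_yaml(_default_path("fitt.yaml"))

    def row(self, category: str) -> FittRow:
        try:
            return self.rows[category]
        except KeyError:
            raise ValidationError(
                f"category {category!r} absent from FITT table {self.name!r}"
            ) from None
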