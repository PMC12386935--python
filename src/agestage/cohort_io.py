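"""Cohort data model and the daily-record file format.

A cohort is a set of individuals followed from oviposition (age 0) to
death, with one census per day.  Each individual-day is one row of a
comma-delimited file with columns ``id,day,stage,eggs,sex``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

__all__ = [
    "StageSchema",
    "IndividualRecord",
    "CohortTable",
    "FormatError",
    "ValidationError",
    "Violation",
    "FAW_SCHEMA",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"

_SEXES = {FEMALE, MALE, UNKNOWN}


class FormatError(ValueError):
    """Raised when a cohort file is structurally unreadable."""


class ValidationError(ValueError):
    """Raised when a cohort file parses but breaks a data-model rule."""


@dataclass(frozen=True)
class StageSchema:
    """Ordered life-stage layout of a cohort.

    Parameters
    ----------
    stages
        Stage labels in developmental order, egg first, adults last.
    optional_stages
        Contiguous block of stages that individuals may skip (the
        supernumerary instars); must directly precede the pupal stage.
    adult_stages
        The terminal adult stages (one per sex).
    female_stage
        The adult stage whose occupants may lay eggs.
    """

    stages: tuple[str, ...]
    optional_stages: tuple[str, ...] = ()
    adult_stages: tuple[str, ...] = ()
    female_stage: str = "ADULT_F"

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("schema needs at least two stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage labels")
        for s in self.optional_stages:
            if s not in self.stages:
                raise ValueError(f"optional stage {s!r} not in stages")
        for s in self.adult_stages:
            if s not in self.stages:
                raise ValueError(f"adult stage {s!r} not in stages")
        n_adult = len(self.adult_stages)
        if n_adult and tuple(self.stages[-n_adult:]) != tuple(self.adult_stages):
            raise ValueError("adult stages must be the last stages")
        if self.adult_stages and self.female_stage not in self.adult_stages:
            raise ValueError("female_stage must be an adult stage")
        if self.optional_stages:
            idx = sorted(self.index(s) for s in self.optional_stages)
            if idx != list(range(idx[0], idx[0] + len(idx))):
                raise ValueError("optional stages must be contiguous")

    @property
    def beta(self) -> int:
        """Number of stages."""
        return len(self.stages)

    def index(self, stage: str) -> int:
        return self.stages.index(stage)

    def is_adult(self, stage: str) -> bool:
        return stage in self.adult_stages


#: Default fall-armyworm-like schema: egg, six obligatory instars, up to two
#: supernumerary instars, pupa, and the two adult stages.
FAW_SCHEMA = StageSchema(
    stages=("EGG", "L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8",
            "PUPA", "ADULT_F", "ADULT_M"),
    optional_stages=("L7", "L8"),
    adult_stages=("ADULT_F", "ADULT_M"),
    female_stage="ADULT_F",
)


@dataclass
class IndividualRecord:
    """One insect's full daily history from oviposition to death.

    ``history`` holds one ``(age_day, stage)`` entry per day alive, ages
    consecutive from 0.  ``death_age`` is last day alive + 1.
    """

    id: str
    sex: str
    history: list[tuple[int, str]]
    daily_eggs: dict[int, int] = field(default_factory=dict)

    @property
    def death_age(self) -> int:
        return self.history[-1][0] + 1 if self.history else 0

    def stage_at(self, age: int) -> str | None:
        if 0 <= age < len(self.history):
            return self.history[age][1]
        return None

    def first_egg_age(self) -> int | None:
        laying = [a for a, e in self.daily_eggs.items() if e > 0]
        return min(laying) if laying else None

    def total_eggs(self) -> int:
        return sum(self.daily_eggs.values())


@dataclass
class CohortTable:
    """A validated cohort: schema plus individual records."""

    schema: StageSchema
    individuals: list[IndividualRecord]

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def omega(self) -> int:
        """Maximum death age (first age at which everyone is dead)."""
        return max(ind.death_age for ind in self.individuals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (self.schema == other.schema
                and self.individuals == other.individuals)


@dataclass(frozen=True)
class Violation:
    individual_id: str
    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.individual_id}] {self.rule}: {self.detail}"


_COLUMNS = ["id", "day", "stage", "eggs", "sex"]


def read_cohort(path, schema: StageSchema = FAW_SCHEMA) -> CohortTable:
    """Read a cohort CSV and return a validated :class:`CohortTable`.

    Raises :class:`FormatError` for structural problems (missing columns,
    empty file, unparsable fields) and :class:`ValidationError` when the
    parsed records break a data-model invariant.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        cohort = _read_cohort_stream(fh, schema)
    violations = validate_cohort(cohort)
    if violations:
        raise ValidationError("; ".join(str(v) for v in violations))
    return cohort


def _read_cohort_stream(fh: io.TextIOBase, schema: StageSchema) -> CohortTable:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise FormatError("empty file: no header row")
    missing = [c for c in _COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")

    rows: dict[str, list[tuple[int, str, int, str]]] = {}
    order: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        ind_id = (row["id"] or "").strip()
        if not ind_id:
            raise FormatError(f"line {lineno}: blank id")
        try:
            day = int(row["day"])
        except (TypeError, ValueError):
            raise FormatError(f"line {lineno}: day {row['day']!r} is not an integer")
        stage = (row["stage"] or "").strip()
        if stage not in schema.stages:
            raise FormatError(f"line {lineno}: unknown stage {stage!r}")
        raw_eggs = (row["eggs"] or "").strip()
        eggs = int(raw_eggs) if raw_eggs else 0
        sex = (row["sex"] or "").strip() or UNKNOWN
        if sex not in _SEXES:
            raise FormatError(f"line {lineno}: unknown sex {sex!r}")
        if ind_id not in rows:
            rows[ind_id] = []
            order.append(ind_id)
        rows[ind_id].append((day, stage, eggs, sex))

    if not rows:
        raise FormatError("no data rows")

    individuals = []
    for ind_id in order:
        recs = sorted(rows[ind_id], key=lambda t: t[0])
        sexes = {s for _, _, _, s in recs}
        if len(sexes) > 1:
            raise FormatError(f"individual {ind_id}: inconsistent sex labels {sexes}")
        history = [(day, stage) for day, stage, _, _ in recs]
        daily_eggs = {day: e for day, _, e, _ in recs if e > 0}
        individuals.append(IndividualRecord(
            id=ind_id, sex=sexes.pop(), history=history, daily_eggs=daily_eggs))
    return CohortTable(schema=schema, individuals=individuals)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as the canonical CSV; round-trips exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for ind in cohort.individuals:
            for age, stage in ind.history:
                eggs = ind.daily_eggs.get(age, 0)
                writer.writerow([ind.id, age, stage, eggs if eggs else "", ind.sex])


def validate_cohort(cohort: CohortTable) -> list[Violation]:
    """Check every data-model invariant; returns violations, never raises."""
    schema = cohort.schema
    out: list[Violation] = []
    seen_ids: set[str] = set()
    for ind in cohort.individuals:
        if ind.id in seen_ids:
            out.append(Violation(ind.id, "unique-id", "duplicate individual id"))
        seen_ids.add(ind.id)
        if ind.sex not in _SEXES:
            out.append(Violation(ind.id, "sex-label", f"unknown sex {ind.sex!r}"))
            continue
        if not ind.history:
            out.append(Violation(ind.id, "nonempty-history", "no daily rows"))
            continue
        ages = [a for a, _ in ind.history]
        if ages != list(range(len(ages))):
            out.append(Violation(
                ind.id, "consecutive-days",
                f"ages {ages[:5]}... must be consecutive from 0"))
        prev = -1
        reached_adult = False
        adult_stage: str | None = None
        for age, stage in ind.history:
            j = schema.index(stage)
            if j < prev:
                out.append(Violation(
                    ind.id, "stage-order",
                    f"regression {schema.stages[prev]}->{stage} at age {age}"))
                break
            prev = j
            if schema.is_adult(stage):
                reached_adult = True
                adult_stage = stage
        if ind.history[0][1] != schema.stages[0]:
            out.append(Violation(
                ind.id, "starts-as-egg",
                f"first stage is {ind.history[0][1]}, expected {schema.stages[0]}"))
        if ind.sex == UNKNOWN and reached_adult:
            out.append(Violation(
                ind.id, "sex-known-if-adult",
                "reached an adult stage but sex is unknown"))
        if ind.sex != UNKNOWN and not reached_adult:
            out.append(Violation(
                ind.id, "sex-unknown-preadult",
                "died pre-adult but carries a sex label"))
        if adult_stage is not None:
            expected = FEMALE if adult_stage == schema.female_stage else MALE
            if ind.sex != expected:
                out.append(Violation(
                    ind.id, "sex-stage-consistent",
                    f"adult stage {adult_stage} but sex={ind.sex}"))
        stage_by_age = dict(ind.history)
        for age, eggs in ind.daily_eggs.items():
            if eggs < 0:
                out.append(Violation(ind.id, "egg-count", f"negative eggs at age {age}"))
            if stage_by_age.get(age) != schema.female_stage:
                out.append(Violation(
                    ind.id, "eggs-only-adult-female",
                    f"eggs at age {age} outside {schema.female_stage}"))
    return out
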