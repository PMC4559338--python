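"""Domain types for two-day 24-h recall cohorts.

Participants carry the survey design information (first-day sample weight,
variance stratum, exclusion flags) plus an optional daily-average supplement
vector; recall days carry dairy servings in cup equivalents and the day's food
nutrient amounts.  Reference tables (age-specific dairy recommendations and
EAR/AI thresholds) are configuration inputs, with defaults matching the 2010
Dietary Guidelines dairy recommendations.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

from .nutrients import NutrientVector

__all__ = [
    "Sex",
    "Participant",
    "RecallDay",
    "RecommendationTable",
    "DRIEntry",
    "DRIThresholds",
    "AgeSexStratum",
    "AGE_GROUPS",
    "apply_exclusions",
    "assign_stratum",
    "validate_recall_days",
]

Sex = str  # "male" | "female"
_SEXES = ("male", "female")

#: Age groups used for reporting: closed ranges in whole years, partitioning
#: ages >= 2 (the last group is open-ended; 200 is a safe ceiling).
AGE_GROUPS: tuple[tuple[str, int, int], ...] = (
    ("2-3", 2, 3),
    ("4-8", 4, 8),
    ("9-18", 9, 18),
    ("19-50", 19, 50),
    ("51-70", 51, 70),
    ("71+", 71, 200),
)


@dataclass(frozen=True)
class AgeSexStratum:
    """Reporting stratum: an age-range label crossed with a sex (or 'all')."""

    age_group: str
    sex: str = "all"

    def __post_init__(self) -> None:
        if self.age_group not in {g for g, _, _ in AGE_GROUPS}:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.sex not in (*_SEXES, "all"):
            raise ValueError(f"unknown sex {self.sex!r}")

    def __str__(self) -> str:
        return f"{self.age_group}/{self.sex}"


def assign_stratum(age_years: int, sex: Sex) -> AgeSexStratum:
    """Map (age in whole years, sex) to its reporting stratum.

    Boundaries are inclusive of both printed endpoints: 18 -> 9-18,
    50 -> 19-50, 70 -> 51-70.  Ages below 2 are out of scope.
    """
    if sex not in _SEXES:
        raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
    if age_years < 2:
        raise ValueError(f"age {age_years} is below the study range (>= 2 years)")
    for label, lo, hi in AGE_GROUPS:
        if lo <= age_years <= hi:
            return AgeSexStratum(label, sex)
    raise ValueError(f"age {age_years} exceeds the supported range")


@dataclass(frozen=True)
class Participant:
    id: str
    age_years: int
    sex: Sex
    sample_weight: float
    variance_stratum: str = "0"
    pregnant: bool = False
    lactating: bool = False
    breastmilk_consumer: bool = False
    unreliable_recall: bool = False
    supplement: NutrientVector = field(default_factory=NutrientVector.zero)

    def __post_init__(self) -> None:
        if self.sample_weight <= 0:
            raise ValueError(f"sample_weight must be positive, got {self.sample_weight}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")

    @property
    def excluded(self) -> bool:
        return (
            self.pregnant
            or self.lactating
            or self.breastmilk_consumer
            or self.unreliable_recall
        )

    @property
    def stratum(self) -> AgeSexStratum:
        return assign_stratum(self.age_years, self.sex)


@dataclass(frozen=True)
class RecallDay:
    """One person-day: dairy servings (cup-eq) and food nutrient amounts."""

    participant_id: str
    sequence: int  # 1 or 2
    weekend: bool
    dairy_total: float
    milk: float = 0.0
    cheese: float = 0.0
    yogurt: float = 0.0
    food: NutrientVector = field(default_factory=NutrientVector.zero)
    subgroups_known: bool = True

    def __post_init__(self) -> None:
        if self.sequence not in (1, 2):
            raise ValueError(f"sequence must be 1 or 2, got {self.sequence}")
        for name in ("dairy_total", "milk", "cheese", "yogurt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.subgroups_known:
            parts = self.milk + self.cheese + self.yogurt
            if abs(parts - self.dairy_total) > 1e-9:
                raise ValueError(
                    f"milk+cheese+yogurt = {parts} != dairy_total = {self.dairy_total}"
                )

    def with_dairy(self, dairy_total: float, food: NutrientVector) -> "RecallDay":
        """Copy with a new dairy total and food vector; subgroup split is
        dropped (only the total drives the modeling scenario)."""
        return replace(
            self,
            dairy_total=dairy_total,
            food=food,
            milk=self.milk,
            cheese=self.cheese,
            yogurt=self.yogurt,
            subgroups_known=False,
        )


def validate_recall_days(days: Sequence[RecallDay]) -> None:
    """Check the at-most-two-days, distinct-sequence contract per participant."""
    seqs: dict[str, set[int]] = {}
    for d in days:
        seen = seqs.setdefault(d.participant_id, set())
        if d.sequence in seen:
            raise ValueError(
                f"participant {d.participant_id}: duplicate recall sequence {d.sequence}"
            )
        seen.add(d.sequence)
        if len(seen) > 2:  # pragma: no cover - unreachable with sequence in {1,2}
            raise ValueError(f"participant {d.participant_id}: more than 2 recall days")


class RecommendationTable:
    """Age-specific recommended dairy cup-equivalents per day.

    Defaults follow the 2010 Dietary Guidelines: 2 cup-eq for ages 2-3,
    2.5 for 4-8, and 3 for everyone 9 years and older.
    """

    DEFAULT: tuple[tuple[int, int, float], ...] = ((2, 3, 2.0), (4, 8, 2.5), (9, 200, 3.0))

    def __init__(self, ranges: Iterable[tuple[int, int, float]] | None = None):
        self.ranges = tuple(ranges) if ranges is not None else self.DEFAULT
        prev_hi, prev_cups = 1, 0.0
        for lo, hi, cups in self.ranges:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError("recommendation age ranges must be contiguous")
            if cups < prev_cups:
                raise ValueError("recommended cup-eq must be non-decreasing in age")
            prev_hi, prev_cups = hi, cups

    def recommended_cups(self, age_years: int) -> float:
        for lo, hi, cups in self.ranges:
            if lo <= age_years <= hi:
                return cups
        raise ValueError(f"age {age_years} outside recommendation table")

    def __repr__(self) -> str:  # stable, content-based (feeds config hashing)
        return f"RecommendationTable({self.ranges!r})"


@dataclass(frozen=True)
class DRIEntry:
    nutrient: str
    sex: str  # "male" | "female" | "all"
    age_lo: int
    age_hi: int
    value: float
    kind: str  # "EAR" | "AI"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("DRI threshold must be > 0")
        if self.kind not in ("EAR", "AI"):
            raise ValueError(f"DRI kind must be EAR or AI, got {self.kind!r}")


class DRIThresholds:
    """Per (nutrient, sex, age) EAR/AI thresholds.

    Values are configuration inputs, loaded from YAML; the package ships no
    authoritative constants.  Each (nutrient, sex, age) must resolve to at
    most one entry.
    """

    def __init__(self, entries: Iterable[DRIEntry]):
        self.entries = tuple(entries)
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1 :]:
                if (
                    a.nutrient == b.nutrient
                    and ("all" in (a.sex, b.sex) or a.sex == b.sex)
                    and a.age_lo <= b.age_hi
                    and b.age_lo <= a.age_hi
                ):
                    raise ValueError(f"overlapping DRI entries for {a.nutrient}")

    def __repr__(self) -> str:  # stable, content-based (feeds config hashing)
        return f"DRIThresholds({self.entries!r})"

    def lookup(self, nutrient: str, sex: Sex, age_years: int) -> DRIEntry | None:
        for e in self.entries:
            if (
                e.nutrient == nutrient
                and e.sex in (sex, "all")
                and e.age_lo <= age_years <= e.age_hi
            ):
                return e
        return None

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Sequence[Mapping]]) -> "DRIThresholds":
        """Build from a YAML-shaped mapping nutrient -> list of entry dicts."""
        entries = []
        for nutrient, rows in raw.items():
            for row in rows:
                entries.append(
                    DRIEntry(
                        nutrient=nutrient,
                        sex=row.get("sex", "all"),
                        age_lo=int(row["age_lo"]),
                        age_hi=int(row["age_hi"]),
                        value=float(row["value"]),
                        kind=str(row["kind"]).upper(),
                    )
                )
        return cls(entries)


def apply_exclusions(
    participants: Iterable[Participant],
) -> tuple[list[Participant], dict[str, int]]:
    """Drop pregnant/lactating females, breast-milk consumers, and unreliable
    recalls.  Returns (retained participants, removal counts per reason).

    A participant excluded for several reasons is counted once per reason.
    Idempotent: applying twice equals applying once.
    """
    kept: list[Participant] = []
    removed: Counter[str] = Counter()
    for p in participants:
        if p.excluded:
            for reason in ("pregnant", "lactating", "breastmilk_consumer", "unreliable_recall"):
                if getattr(p, reason):
                    removed[reason] += 1
        else:
            kept.append(p)
    return kept, dict(removed)
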