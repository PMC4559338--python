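"""The diet-modeling intervention: raise dairy to the recommended servings.

Each recall day whose dairy total falls short of the participant's
age-specific recommendation is topped up to the recommendation, and the
corresponding multiple of the per-cup-equivalent dairy composite is added to
the day's nutrient amounts.  Days already at or above the recommendation are
returned unchanged; intake is never reduced.

The gap is computed and applied per recall day (not on the two-day mean) so
that the day-level structure required by the usual-intake model is preserved;
a config switch (`per_day=False`) applies the participant's mean gap to both
days instead.

Dietary supplements enter afterwards as a constant per-person daily shift on
the usual-intake distribution (supplement use is modeled as habitual).
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .data_model import Participant, RecallDay, RecommendationTable, assign_stratum
from .nutrients import NutrientVector
from .usual_intake import UsualIntakeDistribution

__all__ = [
    "ModelingResult",
    "dairy_gap",
    "augment_recall_day",
    "augment_cohort",
    "add_supplements",
]


@dataclass
class ModelingResult:
    """Outcome of the dairy intervention on a cohort."""

    days: list[RecallDay]  # modified recall days, order preserved
    gaps: dict[tuple[str, int], float]  # (participant_id, sequence) -> cup-eq added
    mean_added_by_stratum: dict[str, float]  # weighted mean cup-eq added per stratum

    @property
    def total_gap(self) -> float:
        return sum(self.gaps.values())


def dairy_gap(
    age_years: int,
    servings: float,
    recommendations: RecommendationTable | None = None,
) -> float:
    """Cup equivalents needed to reach the age-specific recommendation:
    max(0, recommendation - servings).  Never reduces intake."""
    if age_years < 2:
        raise ValueError(f"age {age_years} is below the study range (>= 2 years)")
    if servings < 0:
        raise ValueError("servings must be >= 0")
    rec = (recommendations or RecommendationTable()).recommended_cups(age_years)
    return max(0.0, rec - servings)


def augment_recall_day(
    day: RecallDay,
    age_years: int,
    composite: NutrientVector,
    recommendations: RecommendationTable | None = None,
    gap: float | None = None,
) -> RecallDay:
    """Top a day's dairy up to the recommendation and add gap x composite to
    each nutrient.  With ``gap=None`` the day's own gap is used; passing a
    precomputed gap supports the per-participant-mean variant."""
    if gap is None:
        gap = dairy_gap(age_years, day.dairy_total, recommendations)
    if gap == 0.0:
        return day
    return day.with_dairy(day.dairy_total + gap, day.food + gap * composite)


def augment_cohort(
    participants: Sequence[Participant],
    days: Sequence[RecallDay],
    composite: NutrientVector,
    recommendations: RecommendationTable | None = None,
    per_day: bool = True,
) -> ModelingResult:
    """Apply the intervention to every recall day of a cohort.

    ``per_day=True`` computes each day's own gap; ``per_day=False`` applies
    the participant's mean gap across their days to every day.
    """
    by_id = {p.id: p for p in participants}
    rec = recommendations or RecommendationTable()

    gaps: dict[tuple[str, int], float] = {}
    if per_day:
        for d in days:
            p = by_id[d.participant_id]
            gaps[(p.id, d.sequence)] = dairy_gap(p.age_years, d.dairy_total, rec)
    else:
        person_days: dict[str, list[RecallDay]] = defaultdict(list)
        for d in days:
            person_days[d.participant_id].append(d)
        for pid, ds in person_days.items():
            p = by_id[pid]
            mean_gap = float(
                np.mean([dairy_gap(p.age_years, d.dairy_total, rec) for d in ds])
            )
            for d in ds:
                gaps[(pid, d.sequence)] = mean_gap

    out_days = [
        augment_recall_day(
            d,
            by_id[d.participant_id].age_years,
            composite,
            rec,
            gap=gaps[(d.participant_id, d.sequence)],
        )
        for d in days
    ]

    # survey-weighted mean added servings per age group (sexes combined)
    num: dict[str, float] = defaultdict(float)
    den: dict[str, float] = defaultdict(float)
    for d in days:
        p = by_id[d.participant_id]
        label = assign_stratum(p.age_years, p.sex).age_group
        num[label] += p.sample_weight * gaps[(p.id, d.sequence)]
        den[label] += p.sample_weight
    mean_added = {k: num[k] / den[k] for k in num}
    return ModelingResult(days=out_days, gaps=gaps, mean_added_by_stratum=mean_added)


def add_supplements(
    distribution: UsualIntakeDistribution,
    participants: Iterable[Participant],
    supplements: Mapping[str, NutrientVector] | None = None,
    log: list[str] | None = None,
) -> UsualIntakeDistribution:
    """Shift each pseudo-person's usual intake by its source participant's
    daily supplement amount for the distribution's nutrient.

    ``supplements`` overrides the participants' own supplement vectors when
    given.  A nutrient absent from a supplement vector counts as zero; that
    is logged once per run when a log list is supplied.
    """
    nutrient = distribution.nutrient
    per_source: dict[str, float] = {}
    missing = False
    for p in participants:
        vec = supplements.get(p.id, p.supplement) if supplements is not None else p.supplement
        if nutrient not in vec and len(vec) > 0:
            missing = True
        per_source[p.id] = vec[nutrient]
    if missing and log is not None:
        log.append(f"supplement table has no {nutrient!r} column; treated as zero")
    return distribution.shifted(per_source)
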