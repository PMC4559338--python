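"""Published U.S. population mean intakes used as worked-example inputs.

These are the reported survey-weighted mean usual intakes of Americans by
age group (sexes combined) from the NHANES 2007-2010 dietary-recall analysis
that this package's diet-modeling scenario reproduces: current diets versus
diets modeled to meet the dairy recommendations.  They serve as printed
inputs for the composite-delta identity — the modeled mean of every nutrient
must equal its current mean plus (modeled dairy - current dairy) times the
per-cup-equivalent composite — and for the derived percent-increase figures.

Values are exactly as printed (dairy to 0.01 cup-eq; nutrients to the final
digit shown), so identity checks must allow for rounding propagation.
"""

from __future__ import annotations

import pandas as pd

from .nutrients import DAIRY_COMPOSITE, NutrientVector

__all__ = [
    "AGE_GROUP_ORDER",
    "PUBLISHED_MEANS",
    "published_means_frame",
    "predict_modeled_means",
    "percent_increase",
    "added_servings",
]

AGE_GROUP_ORDER = ("2-3", "4-8", "9-18", "19-50", "51-70", "71+")

#: row -> (current means, modeled means) per age group, in AGE_GROUP_ORDER.
PUBLISHED_MEANS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "dairy": ((2.38, 2.04, 2.05, 1.65, 1.46, 1.28), (2.43, 2.39, 3.00, 3.03, 2.99, 2.91)),
    "calcium": ((1037, 975, 1047, 1025, 933, 814), (1054, 1081, 1329, 1436, 1387, 1300)),
    "magnesium": ((200, 211, 247, 307, 302, 256), (201, 218, 266, 335, 332, 289)),
    "protein": ((53.3, 59.4, 75.2, 87.2, 79.3, 64.3), (53.7, 62.5, 83.3, 98.9, 92.2, 78.1)),
    "vitamin_a": ((581, 579, 598, 599, 664, 658), (587, 615, 692, 736, 815, 819)),
    "vitamin_d": ((7.1, 5.8, 5.3, 4.7, 4.9, 4.7), (7.2, 6.4, 6.7, 6.8, 7.3, 7.2)),
    "potassium": ((2035, 2049, 2261, 2705, 2799, 2457), (2049, 2134, 2485, 3031, 3160, 2843)),
    "energy": ((1456, 1728, 2088, 2276, 2011, 1649), (1460, 1757, 2164, 2388, 2135, 1781)),
    "saturated_fat": ((19.2, 22.3, 26.6, 28.0, 25.5, 20.2), (19.3, 22.7, 27.5, 29.1, 26.9, 21.7)),
    "sodium": ((2113, 2617, 3392, 3742, 3375, 2717), (2124, 2681, 3563, 3992, 3651, 3013)),
}

#: smallest printed digit per row (rounding unit of the published cells).
PRINT_UNIT: dict[str, float] = {
    "dairy": 0.01,
    "calcium": 1.0,
    "magnesium": 1.0,
    "protein": 0.1,
    "vitamin_a": 1.0,
    "vitamin_d": 0.1,
    "potassium": 1.0,
    "energy": 1.0,
    "saturated_fat": 0.1,
    "sodium": 1.0,
}


def published_means_frame() -> pd.DataFrame:
    """The published table as a tidy frame: quantity, age_group, current, modeled."""
    rows = []
    for quantity, (cur, mod) in PUBLISHED_MEANS.items():
        for g, c, m in zip(AGE_GROUP_ORDER, cur, mod):
            rows.append({"quantity": quantity, "age_group": g, "current": c, "modeled": m})
    return pd.DataFrame(rows)


def added_servings(age_group: str) -> float:
    """Mean dairy cup-equivalents added by the intervention in an age group,
    from the published dairy row (modeled minus current)."""
    i = AGE_GROUP_ORDER.index(age_group)
    cur, mod = PUBLISHED_MEANS["dairy"]
    return mod[i] - cur[i]


def predict_modeled_means(
    composite: NutrientVector = DAIRY_COMPOSITE,
) -> pd.DataFrame:
    """Recompute every modeled nutrient mean from published inputs alone:
    current mean + added servings x composite.  Returns a frame with the
    prediction alongside the published modeled value."""
    rows = []
    for nutrient, (cur, mod) in PUBLISHED_MEANS.items():
        if nutrient == "dairy":
            continue
        for i, g in enumerate(AGE_GROUP_ORDER):
            delta = added_servings(g)
            rows.append(
                {
                    "nutrient": nutrient,
                    "age_group": g,
                    "current": cur[i],
                    "predicted_modeled": cur[i] + delta * composite[nutrient],
                    "published_modeled": mod[i],
                    "print_unit": PRINT_UNIT[nutrient],
                }
            )
    return pd.DataFrame(rows)


def percent_increase(quantity: str, age_group: str) -> float:
    """Percent increase of a published mean under the intervention:
    100 * (modeled - current) / current."""
    i = AGE_GROUP_ORDER.index(age_group)
    cur, mod = PUBLISHED_MEANS[quantity]
    return 100.0 * (mod[i] - cur[i]) / cur[i]
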