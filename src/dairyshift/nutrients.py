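"""Nutrient vectors and the per-cup-equivalent dairy composite.

A :class:`NutrientVector` is a componentwise-additive map from nutrient name to
a daily amount in that nutrient's fixed unit.  The unit registry is frozen per
nutrient (energy in kcal, calcium in mg, vitamin D in µg, ...), so two vectors
can always be added without unit bookkeeping.

The :data:`DAIRY_COMPOSITE` is the USDA food-pattern composite for one cup
equivalent of the dairy group (milk, cheese, yogurt on a common serving
scale).  It is the vector that translates added dairy servings into added
nutrients in the diet-modeling scenario, and it can be overridden through
configuration.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping

__all__ = ["NUTRIENT_UNITS", "NutrientVector", "DAIRY_COMPOSITE", "dairy_composite"]

#: Fixed unit per nutrient; amounts are per day.
NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kcal",
    "protein": "g",
    "saturated_fat": "g",
    "calcium": "mg",
    "magnesium": "mg",
    "vitamin_a": "ug_rae",
    "vitamin_d": "ug",
    "potassium": "mg",
    "sodium": "mg",
    # extensible set
    "riboflavin": "mg",
    "vitamin_b12": "ug",
    "phosphorus": "mg",
    "zinc": "mg",
}


class NutrientVector(Mapping[str, float]):
    """Immutable map nutrient-name -> amount/day; componentwise algebra.

    All amounts must be non-negative.  Addition and scalar multiplication act
    componentwise; a nutrient absent from one operand is treated as zero.
    """

    __slots__ = ("_data",)

    def __init__(self, amounts: Mapping[str, float] | None = None, **kw: float):
        data: dict[str, float] = {}
        merged = dict(amounts or {})
        merged.update(kw)
        for name, amount in merged.items():
            if name not in NUTRIENT_UNITS:
                raise KeyError(f"unknown nutrient {name!r}; register a unit first")
            amount = float(amount)
            if amount < 0:
                raise ValueError(f"negative amount for {name}: {amount}")
            data[name] = amount
        self._data = data

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._data.get(name, 0.0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, name: object) -> bool:
        return name in self._data

    # algebra --------------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        keys = set(self._data) | set(other._data)
        return NutrientVector({k: self[k] + other[k] for k in keys})

    def __mul__(self, factor: float) -> "NutrientVector":
        factor = float(factor)
        if factor < 0:
            raise ValueError("cannot scale a NutrientVector by a negative factor")
        return NutrientVector({k: v * factor for k, v in self._data.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        keys = set(self._data) | set(other._data)
        return all(self[k] == other[k] for k in keys)

    def __hash__(self) -> int:  # pragma: no cover - Mapping default is None
        return hash(frozenset(self._data.items()))

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v:g}" for k, v in sorted(self._data.items()))
        return f"NutrientVector({body})"

    def isclose(self, other: "NutrientVector", tol: float = 1e-9) -> bool:
        keys = set(self._data) | set(other._data)
        return all(abs(self[k] - other[k]) <= tol for k in keys)

    @classmethod
    def zero(cls) -> "NutrientVector":
        return cls({})


#: USDA dairy composite: nutrients contributed by 1.0 cup equivalent of dairy.
DAIRY_COMPOSITE = NutrientVector(
    energy=81.0,
    protein=8.5,
    saturated_fat=0.87,
    calcium=298.0,
    magnesium=20.0,
    vitamin_a=99.0,
    vitamin_d=1.55,
    potassium=237.0,
    sodium=181.0,
)


def dairy_composite(overrides: Mapping[str, float] | None = None) -> NutrientVector:
    """Return the dairy composite, optionally overriding entries from config."""
    if not overrides:
        return DAIRY_COMPOSITE
    merged = dict(DAIRY_COMPOSITE)
    merged.update(overrides)
    return NutrientVector(merged)
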