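"""Flat-file I/O for recall cohorts, supplements, and YAML configuration.

Recall files are plain CSV, one row per person-day:

    participant_id, age_years, sex, weight, stratum_id, seq, weekend,
    dairy_total, milk, cheese, yogurt, <nutrient>_<unit>...

Nutrient columns carry their unit as a header suffix (``calcium_mg``,
``vitamin_d_ug``), which is checked against the package unit registry at read
time.  Optional boolean flag columns (``pregnant``, ``lactating``,
``breastmilk_consumer``, ``unreliable_recall``) default to false when absent.

Supplement files are CSV keyed on ``participant_id`` with the same nutrient
column dialect, holding daily-average amounts.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
import yaml

from .data_model import (
    DRIThresholds,
    Participant,
    RecallDay,
    RecommendationTable,
    validate_recall_days,
)
from .nutrients import NUTRIENT_UNITS, NutrientVector, dairy_composite

__all__ = [
    "nutrient_column",
    "read_recalls",
    "write_recalls",
    "read_supplements",
    "write_supplements",
    "write_table",
    "load_config",
]

_FLAG_COLUMNS = ("pregnant", "lactating", "breastmilk_consumer", "unreliable_recall")
_REQUIRED = (
    "participant_id",
    "age_years",
    "sex",
    "weight",
    "seq",
    "weekend",
    "dairy_total",
)


def nutrient_column(name: str) -> str:
    """Header for a nutrient column, e.g. calcium -> 'calcium_mg'."""
    return f"{name}_{NUTRIENT_UNITS[name]}"


def _parse_nutrient_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map nutrient name -> column header for recognized nutrient columns."""
    lookup = {nutrient_column(n): n for n in NUTRIENT_UNITS}
    return {lookup[c]: c for c in columns if c in lookup}


class RecallParseError(ValueError):
    pass


def read_recalls(path: str | Path) -> tuple[list[Participant], list[RecallDay]]:
    """Read a recall CSV into participants and recall days.

    Raises :class:`RecallParseError` naming the missing column or the
    offending row (1-based data line numbers) for malformed input.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise RecallParseError(f"missing required column {col!r} in {path}")
    nut_cols = _parse_nutrient_columns(df.columns)

    serving_cols = ["dairy_total"] + [c for c in ("milk", "cheese", "yogurt") if c in df.columns]
    for col in serving_cols + list(nut_cols.values()):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise RecallParseError(
                f"negative value in column {col!r} at data row {int(bad[0]) + 1} of {path}"
            )

    participants: dict[str, Participant] = {}
    days: list[RecallDay] = []
    for idx, row in df.iterrows():
        pid = str(row["participant_id"])
        if pid not in participants:
            flags = {f: bool(row[f]) if f in df.columns else False for f in _FLAG_COLUMNS}
            try:
                participants[pid] = Participant(
                    id=pid,
                    age_years=int(row["age_years"]),
                    sex=str(row["sex"]),
                    sample_weight=float(row["weight"]),
                    variance_stratum=str(row["stratum_id"]) if "stratum_id" in df.columns else "0",
                    **flags,
                )
            except ValueError as exc:
                raise RecallParseError(f"data row {int(idx) + 1} of {path}: {exc}") from exc
        food = NutrientVector({n: float(row[c]) for n, c in nut_cols.items()})
        has_subgroups = all(c in df.columns and pd.notna(row[c]) for c in ("milk", "cheese", "yogurt"))
        try:
            days.append(
                RecallDay(
                    participant_id=pid,
                    sequence=int(row["seq"]),
                    weekend=bool(row["weekend"]),
                    dairy_total=float(row["dairy_total"]),
                    milk=float(row["milk"]) if has_subgroups else 0.0,
                    cheese=float(row["cheese"]) if has_subgroups else 0.0,
                    yogurt=float(row["yogurt"]) if has_subgroups else 0.0,
                    subgroups_known=has_subgroups,
                )
            )
            days[-1] = _with_food(days[-1], food)
        except ValueError as exc:
            raise RecallParseError(f"data row {int(idx) + 1} of {path}: {exc}") from exc
    validate_recall_days(days)
    return list(participants.values()), days


def _with_food(day: RecallDay, food: NutrientVector) -> RecallDay:
    import dataclasses

    return dataclasses.replace(day, food=food)


def write_recalls(
    participants: Sequence[Participant],
    days: Sequence[RecallDay],
    path: str | Path,
    nutrients: Sequence[str] | None = None,
) -> None:
    """Write participants x recall days back to the CSV dialect (round-trips)."""
    by_id = {p.id: p for p in participants}
    if nutrients is None:
        seen: list[str] = []
        for d in days:
            for n in d.food:
                if n not in seen:
                    seen.append(n)
        nutrients = seen
    rows = []
    for d in days:
        p = by_id[d.participant_id]
        row: dict[str, object] = {
            "participant_id": p.id,
            "age_years": p.age_years,
            "sex": p.sex,
            "weight": p.sample_weight,
            "stratum_id": p.variance_stratum,
            "seq": d.sequence,
            "weekend": int(d.weekend),
            "dairy_total": d.dairy_total,
            "milk": d.milk if d.subgroups_known else "",
            "cheese": d.cheese if d.subgroups_known else "",
            "yogurt": d.yogurt if d.subgroups_known else "",
        }
        for f in _FLAG_COLUMNS:
            row[f] = int(getattr(p, f))
        for n in nutrients:
            row[nutrient_column(n)] = d.food[n]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_supplements(path: str | Path) -> dict[str, NutrientVector]:
    """Read daily-average supplement amounts keyed on participant id."""
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise RecallParseError(f"missing required column 'participant_id' in {path}")
    nut_cols = _parse_nutrient_columns(df.columns)
    out: dict[str, NutrientVector] = {}
    for _, row in df.iterrows():
        out[str(row["participant_id"])] = NutrientVector(
            {n: float(row[c]) for n, c in nut_cols.items() if pd.notna(row[c])}
        )
    return out


def write_supplements(supplements: Mapping[str, NutrientVector], path: str | Path) -> None:
    nutrients = sorted({n for v in supplements.values() for n in v})
    rows = [
        {"participant_id": pid, **{nutrient_column(n): v[n] for n in nutrients}}
        for pid, v in supplements.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table(report: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a report table as CSV, optionally preceded by a '#' comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        report.to_csv(fh, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML config; resolve recommendation/DRI/composite sections into
    package objects under keys 'recommendations', 'dri', 'composite'."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "recommendations" in raw:
        out["recommendations"] = RecommendationTable(
            [(int(r["age_lo"]), int(r["age_hi"]), float(r["cups"])) for r in raw["recommendations"]]
        )
    if "dri" in raw:
        out["dri"] = DRIThresholds.from_mapping(raw["dri"])
    out["composite"] = dairy_composite(raw.get("composite"))
    return out
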