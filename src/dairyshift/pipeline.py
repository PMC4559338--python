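"""End-to-end orchestration: simulate/ingest -> filter -> estimate -> model
dairy -> re-estimate -> adequacy comparison -> report bundle.

``run_analysis`` reproduces the full diet-modeling flow on a cohort and
returns (and optionally writes) the report tables:

* ``dairy_intake`` — mean milk/cheese/yogurt/total dairy servings and the
  percent of each stratum's usual dairy intake below its recommendation;
* ``mean_intakes`` — survey-weighted current vs modeled mean daily intake per
  nutrient and stratum (these obey the composite-delta identity exactly on
  the raw person-days);
* ``adequacy`` — percent below the EAR (or at/above the AI) per nutrient,
  stratum, scenario and source (food vs food+supplements), with bootstrap
  SE, 95% CI, and the non-overlap significance marker;
* ``manifest`` — seeds, config hash and version for reproducibility.

Every stage is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .adequacy import (
    PrevalenceEstimate,
    bootstrap_se,
    ci_nonoverlap,
    prevalence_at_or_above,
    prevalence_below,
)
from .data_model import (
    AGE_GROUPS,
    DRIThresholds,
    Participant,
    RecallDay,
    RecommendationTable,
    apply_exclusions,
    assign_stratum,
)
from .diet_model import add_supplements, augment_cohort
from .nutrients import DAIRY_COMPOSITE, NutrientVector
from .synthetic import CohortConfig, generate_cohort
from .usual_intake import (
    UsualIntakeDistribution,
    fit_amount_model,
    fit_consumption_model,
    simulate_usual_distribution,
)

__all__ = ["RunConfig", "PipelineResult", "run_analysis", "percent_below_recommendation",
           "fit_nutrient_distribution", "fit_dairy_distribution"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    nutrients: tuple[str, ...] = ("calcium", "magnesium", "vitamin_a", "vitamin_d")
    report_only: tuple[str, ...] = ("energy", "saturated_fat", "sodium")
    dri: DRIThresholds | None = None
    ai_nutrients: tuple[str, ...] = ("potassium",)
    recommendations: RecommendationTable = field(default_factory=RecommendationTable)
    composite: NutrientVector = DAIRY_COMPOSITE
    age_groups: tuple[str, ...] = tuple(g for g, _, _ in AGE_GROUPS)
    sexes: tuple[str, ...] = ("all",)
    sources: tuple[str, ...] = ("food", "food+supplements")
    m: int = 100  # pseudo-persons per participant
    B: int = 60  # bootstrap replicates
    seed: int = 0
    per_day_gap: bool = True

    def config_hash(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def requested_nutrients(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.nutrients + self.ai_nutrients))


@dataclass
class PipelineResult:
    dairy_intake: pd.DataFrame
    mean_intakes: pd.DataFrame
    adequacy: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        from pathlib import Path

        from .io import write_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"config {self.manifest['config_hash']} seed {self.manifest['seed']}"
        write_table(self.dairy_intake, out / "dairy_intake.csv", stamp)
        write_table(self.mean_intakes, out / "mean_intakes.csv", stamp)
        write_table(self.adequacy, out / "adequacy.csv", stamp)
        write_table(_round_for_display(self.adequacy), out / "adequacy_display.csv", stamp)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _round_for_display(adequacy: pd.DataFrame) -> pd.DataFrame:
    disp = adequacy.copy()
    for col in ("percent", "se", "ci_lower", "ci_upper"):
        if col in disp:
            disp[col] = disp[col].round(1)
    return disp


# ---------------------------------------------------------------------------
# Estimation helpers (the usual-intake stage wired to domain objects)
# ---------------------------------------------------------------------------

def _day_arrays(participants: Sequence[Participant], days: Sequence[RecallDay]):
    by_id = {p.id: p for p in participants}
    rows = [d for d in days if d.participant_id in by_id]
    ids = np.array([d.participant_id for d in rows])
    seq2 = np.array([float(d.sequence == 2) for d in rows])
    wkend = np.array([float(d.weekend) for d in rows])
    w = np.array([by_id[d.participant_id].sample_weight for d in rows])
    return rows, ids, seq2, wkend, w


def fit_nutrient_distribution(
    participants: Sequence[Participant],
    days: Sequence[RecallDay],
    nutrient: str,
    m: int = 100,
    seed: int = 0,
    lam_grid=None,
) -> tuple[UsualIntakeDistribution, object]:
    """Amount-only usual-intake estimation for a (near-daily) nutrient."""
    rows, ids, seq2, wkend, w = _day_arrays(participants, days)
    values = np.array([d.food[nutrient] for d in rows])
    kw = {} if lam_grid is None else {"lam_grid": lam_grid}
    params = fit_amount_model(values, ids, seq2, wkend, w, **kw)
    keep = [p for p in participants if p.id in set(ids)]
    dist = simulate_usual_distribution(params, None, keep, m=m, seed=seed, nutrient=nutrient)
    return dist, params


def fit_dairy_distribution(
    participants: Sequence[Participant],
    days: Sequence[RecallDay],
    m: int = 100,
    seed: int = 0,
    lam_grid=None,
) -> tuple[UsualIntakeDistribution, object, object]:
    """Two-part (episodic) usual-intake estimation for total dairy."""
    rows, ids, seq2, wkend, w = _day_arrays(participants, days)
    values = np.array([d.dairy_total for d in rows])
    consumed = values > 0
    prob = fit_consumption_model(consumed, ids, seq2, wkend, w)
    kw = {} if lam_grid is None else {"lam_grid": lam_grid}
    amount = fit_amount_model(
        values[consumed], ids[consumed], seq2[consumed], wkend[consumed], w[consumed], **kw
    )
    keep = [p for p in participants if p.id in set(ids)]
    dist = simulate_usual_distribution(amount, prob, keep, m=m, seed=seed, nutrient="dairy")
    return dist, amount, prob


def percent_below_recommendation(
    dist: UsualIntakeDistribution,
    recommendation,
    **meta,
) -> PrevalenceEstimate:
    """Weighted % of usual dairy intake strictly below the recommendation.

    ``recommendation`` is a single cup-eq value or a mapping from source
    participant id to that participant's age-specific recommendation.
    """
    if len(dist) == 0:
        raise ValueError(f"empty usual-intake distribution for stratum {meta.get('stratum')!r}")
    if np.isscalar(recommendation):
        thr = np.full(len(dist), float(recommendation))
    else:
        thr = np.array([float(recommendation[s]) for s in dist.source_ids])
    mask = dist.values < thr
    pct = 100.0 * float(np.sum(dist.weights[mask]) / np.sum(dist.weights))
    return PrevalenceEstimate(
        percent=pct,
        nutrient="dairy",
        n_participants=len(np.unique(dist.source_ids)),
        **meta,
    )


# ---------------------------------------------------------------------------
# The end-to-end run
# ---------------------------------------------------------------------------

def _stratum_members(participants, age_group: str, sex: str):
    out = []
    for p in participants:
        s = assign_stratum(p.age_years, p.sex)
        if s.age_group == age_group and sex in ("all", p.sex):
            out.append(p)
    return out


def _weighted_day_mean(participants, days, getter) -> float:
    by_id = {p.id: p for p in participants}
    num = den = 0.0
    for d in days:
        p = by_id.get(d.participant_id)
        if p is None:
            continue
        num += p.sample_weight * getter(d)
        den += p.sample_weight
    return num / den


def _all_prevalences(
    cfg: RunConfig,
    members: Sequence[Participant],
    days_cur: Sequence[RecallDay],
    days_mod: Sequence[RecallDay],
    seed: int,
    lam_grids: dict | None = None,
) -> tuple[dict[tuple[str, str, str], float], dict[tuple[str, str], tuple[float]]]:
    """Point estimates of every requested prevalence for one stratum.

    Keys are (nutrient, scenario, source).  Reused inside the bootstrap so
    that each replicate reruns the full estimation pipeline; replicates pass
    ``lam_grids`` to hold the Box-Cox exponent at the point estimate.
    """
    out: dict[tuple[str, str, str], float] = {}
    lams: dict[tuple[str, str], tuple[float]] = {}
    for scen, days in (("current", days_cur), ("modeled", days_mod)):
        for nutrient in cfg.requested_nutrients():
            grid = (lam_grids or {}).get((nutrient, scen))
            dist, params = fit_nutrient_distribution(
                members, days, nutrient, m=cfg.m, seed=seed, lam_grid=grid
            )
            lams[(nutrient, scen)] = (params.lam,)
            for source in cfg.sources:
                d = dist
                if source == "food+supplements":
                    d = add_supplements(dist, members)
                thr = _dri_thresholds(cfg, nutrient, members)
                if thr is None:
                    out[(nutrient, scen, source)] = np.nan
                elif nutrient in cfg.ai_nutrients:
                    out[(nutrient, scen, source)] = prevalence_at_or_above(d, thr).percent
                else:
                    out[(nutrient, scen, source)] = prevalence_below(d, thr).percent
    return out, lams


def _dri_thresholds(
    cfg: RunConfig, nutrient: str, members: Sequence[Participant]
) -> dict[str, float] | None:
    """Per-participant sex/age-specific threshold map; None when the DRI
    table has no entry for anyone in the stratum."""
    if cfg.dri is None:
        return None
    out: dict[str, float] = {}
    for p in members:
        e = cfg.dri.lookup(nutrient, p.sex, p.age_years)
        if e is not None:
            out[p.id] = e.value
    if not out:
        return None
    if len(out) < len(members):
        # a draw without a threshold cannot be classified; fall back to the
        # stratum's weighted-majority value for the few uncovered persons
        values = list(out.values())
        fallback = max(set(values), key=values.count)
        for p in members:
            out.setdefault(p.id, fallback)
    return out


def run_analysis(cfg: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full diet-modeling analysis on a (synthetic) cohort."""
    participants, days = generate_cohort(cfg.cohort)
    kept, removed = apply_exclusions(participants)
    kept_ids = {p.id for p in kept}
    days = [d for d in days if d.participant_id in kept_ids]

    modeling = augment_cohort(kept, days, cfg.composite, cfg.recommendations, per_day=cfg.per_day_gap)
    days_mod = modeling.days

    dairy_rows, mean_rows, adeq_rows = [], [], []
    rng = np.random.default_rng(cfg.seed)

    for age_group in cfg.age_groups:
        for sex in cfg.sexes:
            members = _stratum_members(kept, age_group, sex)
            if len(members) < 10:
                continue
            ids = {p.id for p in members}
            sdays = [d for d in days if d.participant_id in ids]
            sdays_mod = [d for d in days_mod if d.participant_id in ids]
            label = f"{age_group}/{sex}"
            seed_s = int(rng.integers(0, 2**31 - 1))

            # --- dairy servings and % below recommendation ----------------
            dist_dairy, am, pm = fit_dairy_distribution(members, sdays, m=cfg.m, seed=seed_s)
            rec_by_id = {
                p.id: cfg.recommendations.recommended_cups(p.age_years) for p in members
            }
            pct_below = percent_below_recommendation(
                dist_dairy, rec_by_id, stratum=label, scenario="current"
            )
            dairy_rows.append(
                {
                    "stratum": label,
                    "n": len(members),
                    "milk": _weighted_day_mean(members, sdays, lambda d: d.milk),
                    "cheese": _weighted_day_mean(members, sdays, lambda d: d.cheese),
                    "yogurt": _weighted_day_mean(members, sdays, lambda d: d.yogurt),
                    "total_dairy": _weighted_day_mean(members, sdays, lambda d: d.dairy_total),
                    "usual_dairy_mean": dist_dairy.weighted_mean(),
                    "pct_below_recommendation": pct_below.percent,
                }
            )

            # --- current vs modeled mean intakes (identity holds exactly) -
            for nutrient in dict.fromkeys(
                cfg.requested_nutrients() + cfg.report_only
            ):
                mean_rows.append(
                    {
                        "stratum": label,
                        "quantity": nutrient,
                        "current": _weighted_day_mean(members, sdays, lambda d: d.food[nutrient]),
                        "modeled": _weighted_day_mean(
                            members, sdays_mod, lambda d: d.food[nutrient]
                        ),
                    }
                )
            mean_rows.append(
                {
                    "stratum": label,
                    "quantity": "dairy",
                    "current": _weighted_day_mean(members, sdays, lambda d: d.dairy_total),
                    "modeled": _weighted_day_mean(members, sdays_mod, lambda d: d.dairy_total),
                }
            )

            # --- adequacy with bootstrap uncertainty ----------------------
            point, lam_grids = _all_prevalences(cfg, members, sdays, sdays_mod, seed_s, None)

            day_map: dict[str, list[RecallDay]] = {}
            for d in sdays:
                day_map.setdefault(d.participant_id, []).append(d)
            day_map_mod: dict[str, list[RecallDay]] = {}
            for d in sdays_mod:
                day_map_mod.setdefault(d.participant_id, []).append(d)

            keys = list(point)
            reps: dict[tuple, list[float]] = {k: [] for k in keys}

            def replicate(resampled, rep_seed):
                rdays_cur, rdays_mod = [], []
                for p in resampled:
                    src = p.id.split("#", 1)[0]
                    for d in day_map.get(src, []):
                        rdays_cur.append(_reown(d, p.id))
                    for d in day_map_mod.get(src, []):
                        rdays_mod.append(_reown(d, p.id))
                vals, _ = _all_prevalences(
                    cfg, resampled, rdays_cur, rdays_mod, rep_seed, lam_grids
                )
                for k in keys:
                    reps[k].append(vals[k])
                return 0.0

            if cfg.B:
                bootstrap_se(replicate, members, B=cfg.B, seed=seed_s)

            for (nutrient, scen, source), pct in point.items():
                if np.isnan(pct):
                    continue
                arr = np.array(reps[(nutrient, scen, source)]) if cfg.B else np.array([])
                se = float(np.std(arr, ddof=1)) if len(arr) > 1 else np.nan
                lo, hi = (
                    (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
                    if len(arr) > 1
                    else (np.nan, np.nan)
                )
                adeq_rows.append(
                    {
                        "stratum": label,
                        "nutrient": nutrient,
                        "scenario": scen,
                        "source": source,
                        "measure": "at_or_above_AI" if nutrient in cfg.ai_nutrients else "below_EAR",
                        "percent": pct,
                        "se": se,
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "n": len(members),
                    }
                )

    adequacy = pd.DataFrame(adeq_rows)
    if len(adequacy):
        adequacy["significant_vs_current"] = _mark_significance(adequacy)

    manifest = {
        "seed": cfg.seed,
        "cohort_seed": cfg.cohort.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_participants": cfg.cohort.n_participants,
        "n_retained": len(kept),
        "exclusions": removed,
        "m": cfg.m,
        "B": cfg.B,
    }
    result = PipelineResult(
        dairy_intake=pd.DataFrame(dairy_rows),
        mean_intakes=pd.DataFrame(mean_rows),
        adequacy=adequacy,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def _reown(day: RecallDay, new_id: str) -> RecallDay:
    import dataclasses

    return dataclasses.replace(day, participant_id=new_id)


def _mark_significance(adequacy: pd.DataFrame) -> list[bool | None]:
    """Non-overlap of 95% CIs between current and modeled, per row's
    (stratum, nutrient, source); None when CIs are unavailable."""
    marks: list[bool | None] = []
    idx = adequacy.set_index(["stratum", "nutrient", "source", "scenario"])
    for _, row in adequacy.iterrows():
        other_scen = "modeled" if row["scenario"] == "current" else "current"
        try:
            other = idx.loc[(row["stratum"], row["nutrient"], row["source"], other_scen)]
        except KeyError:
            marks.append(None)
            continue
        if np.isnan(row["ci_lower"]) or np.isnan(float(other["ci_lower"])):
            marks.append(None)
            continue
        a = PrevalenceEstimate(
            percent=row["percent"], ci_lower=row["ci_lower"], ci_upper=row["ci_upper"]
        )
        b = PrevalenceEstimate(
            percent=float(other["percent"]),
            ci_lower=float(other["ci_lower"]),
            ci_upper=float(other["ci_upper"]),
        )
        marks.append(ci_nonoverlap(a, b))
    return marks
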