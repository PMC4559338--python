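"""Survey-weighted prevalence of inadequacy and its uncertainty.

Prevalence of inadequate intake uses the EAR cut-point method: the weighted
fraction of the usual-intake distribution strictly below the EAR.  For
nutrients with only an AI (potassium), adequacy is reported as the weighted
fraction at or above the AI (boundary inclusive).

Standard errors come from a stratified person-level bootstrap: participants
are resampled with replacement within their variance strata, the whole
estimation pipeline is rerun per replicate, and the SE is the standard
deviation of replicate estimates with a 2.5/97.5 percentile confidence
interval.  Significance between scenarios follows the non-overlapping-95%-CI
rule.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Callable, Sequence
from dataclasses import dataclass, replace

import numpy as np

from .data_model import Participant
from .usual_intake import UsualIntakeDistribution

__all__ = [
    "PrevalenceEstimate",
    "prevalence_below",
    "prevalence_at_or_above",
    "bootstrap_se",
    "ci_nonoverlap",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    percent: float
    nutrient: str = ""
    stratum: str = ""
    scenario: str = "current"  # "current" | "modeled"
    source: str = "food"  # "food" | "food+supplements"
    se: float = float("nan")
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")
    n_participants: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"percent must be in [0, 100], got {self.percent}")
        if np.isfinite(self.ci_lower) and np.isfinite(self.ci_upper):
            if not self.ci_lower <= self.ci_upper:
                raise ValueError("CI bounds out of order")

    def with_uncertainty(self, se: float, lo: float, hi: float) -> "PrevalenceEstimate":
        return replace(self, se=se, ci_lower=lo, ci_upper=hi)


def _weighted_fraction(dist: UsualIntakeDistribution, mask: np.ndarray) -> float:
    return 100.0 * float(np.sum(dist.weights[mask]) / np.sum(dist.weights))


def _threshold_array(dist: UsualIntakeDistribution, threshold) -> np.ndarray:
    """Threshold per draw: a scalar EAR/AI, or a mapping from source
    participant id to that person's (sex/age-specific) threshold."""
    if np.isscalar(threshold):
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        return np.full(len(dist), float(threshold))
    thr = np.array([float(threshold[s]) for s in dist.source_ids])
    if np.any(thr <= 0):
        raise ValueError("thresholds must be > 0")
    return thr


def prevalence_below(
    dist: UsualIntakeDistribution, threshold, **meta
) -> PrevalenceEstimate:
    """Weighted % of usual-intake draws strictly below the threshold (EAR
    cut-point prevalence of inadequacy).  ``threshold`` may be a scalar or a
    per-source-participant mapping (sex/age-specific EARs)."""
    if len(dist) == 0:
        raise ValueError(f"empty usual-intake distribution for stratum {meta.get('stratum')!r}")
    pct = _weighted_fraction(dist, dist.values < _threshold_array(dist, threshold))
    return PrevalenceEstimate(
        percent=pct, nutrient=dist.nutrient, n_participants=len(np.unique(dist.source_ids)), **meta
    )


def prevalence_at_or_above(
    dist: UsualIntakeDistribution, threshold, **meta
) -> PrevalenceEstimate:
    """Weighted % of usual-intake draws at or above the threshold (AI
    adequacy; the boundary counts as meeting the AI)."""
    if len(dist) == 0:
        raise ValueError(f"empty usual-intake distribution for stratum {meta.get('stratum')!r}")
    pct = _weighted_fraction(dist, dist.values >= _threshold_array(dist, threshold))
    return PrevalenceEstimate(
        percent=pct, nutrient=dist.nutrient, n_participants=len(np.unique(dist.source_ids)), **meta
    )


def bootstrap_se(
    statistic: Callable[[Sequence[Participant], int], float],
    participants: Sequence[Participant],
    B: int = 200,
    seed: int = 0,
    max_failure_fraction: float = 0.10,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Stratified person-level bootstrap of an arbitrary pipeline statistic.

    ``statistic(resampled_participants, replicate_seed)`` must rerun whatever
    estimation the caller needs (refit + prevalence, say) and return a float.
    Participants are resampled with replacement within their variance strata.
    Replicates that raise are dropped and counted; more than 10 % failures is
    an error.  Returns (SE, (ci_lower, ci_upper), replicate values);
    deterministic given the seed.
    """
    if B < 50:
        raise ValueError("B must be >= 50 for stable percentile intervals")
    rng = np.random.default_rng(seed)
    by_stratum: dict[str, list[Participant]] = defaultdict(list)
    for p in participants:
        by_stratum[p.variance_stratum].append(p)

    values: list[float] = []
    failures = 0
    for b in range(B):
        resampled: list[Participant] = []
        for members in by_stratum.values():
            idx = rng.integers(0, len(members), size=len(members))
            # resampled participants get fresh ids so repeated picks stay distinct
            for k, i in enumerate(idx):
                resampled.append(replace(members[i], id=f"{members[i].id}#b{k}"))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            values.append(float(statistic(resampled, rep_seed)))
        except Exception:
            failures += 1
    if failures > max_failure_fraction * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed; estimation is unstable"
        )
    arr = np.asarray(values)
    se = float(np.std(arr, ddof=1))
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return se, (float(lo), float(hi)), arr


def ci_nonoverlap(a: PrevalenceEstimate, b: PrevalenceEstimate) -> bool:
    """True iff the two 95% confidence intervals are disjoint (the
    significance marker used between current and modeled scenarios).
    Touching bounds count as overlapping (closed intervals)."""
    for est in (a, b):
        if not (np.isfinite(est.ci_lower) and np.isfinite(est.ci_upper)):
            raise ValueError("both estimates must carry confidence intervals")
    return a.ci_upper < b.ci_lower or b.ci_upper < a.ci_lower
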