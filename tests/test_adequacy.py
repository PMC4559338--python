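import numpy as np
import pytest

from dairyshift.adequacy import (
    PrevalenceEstimate,
    bootstrap_se,
    ci_nonoverlap,
    prevalence_at_or_above,
    prevalence_below,
)
from dairyshift.data_model import Participant
from dairyshift.usual_intake import UsualIntakeDistribution


def make_dist(values, weights=None, ids=None):
    values = np.asarray(values, float)
    n = len(values)
    return UsualIntakeDistribution(
        values=values,
        source_ids=np.asarray(ids) if ids is not None else np.array([f"s{i}" for i in range(n)]),
        weights=np.asarray(weights, float) if weights is not None else np.ones(n),
        nutrient="calcium",
        seed=0,
    )


class TestPrevalence:
    def test_all_below_gives_hundred(self):
        assert prevalence_below(make_dist([1, 2, 3]), 10.0).percent == 100.0

    def test_equal_weights_half_below(self):
        assert prevalence_below(make_dist([1, 1, 9, 9]), 5.0).percent == 50.0

    def test_weighted_ecdf_oracle_equivalence(self, rng):
        # independent oracle: direct weight summation over the ECDF
        values = rng.lognormal(0, 1, 1000)
        weights = rng.uniform(0.1, 5.0, 1000)
        dist = make_dist(values, weights)
        for thr in np.percentile(values, [5, 30, 50, 80, 95]):
            oracle = 100.0 * weights[values < thr].sum() / weights.sum()
            assert abs(prevalence_below(dist, thr).percent - oracle) <= 1e-12
            oracle_above = 100.0 * weights[values >= thr].sum() / weights.sum()
            assert abs(prevalence_at_or_above(dist, thr).percent - oracle_above) <= 1e-12

    def test_ai_boundary_inclusive(self):
        assert prevalence_at_or_above(make_dist([700.0] * 5), 700.0).percent == 100.0

    def test_complementarity_without_boundary_ties(self, rng):
        values = rng.lognormal(0, 1, 500)
        dist = make_dist(values)
        thr = 1.0
        assert not np.any(values == thr)
        total = prevalence_below(dist, thr).percent + prevalence_at_or_above(dist, thr).percent
        assert total == pytest.approx(100.0, abs=1e-12)

    def test_per_person_thresholds(self):
        dist = make_dist([10.0, 10.0], ids=["a", "b"])
        est = prevalence_below(dist, {"a": 20.0, "b": 5.0})
        assert est.percent == 50.0

    def test_empty_distribution_names_stratum(self):
        empty = UsualIntakeDistribution(
            np.array([]), np.array([]), np.array([]), "calcium", seed=0
        )
        with pytest.raises(ValueError, match="19-50"):
            prevalence_below(empty, 100.0, stratum="19-50")

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            prevalence_below(make_dist([1.0]), 0.0)

    def test_percent_bounds_enforced(self):
        with pytest.raises(ValueError):
            PrevalenceEstimate(percent=101.0)


class TestBootstrap:
    @staticmethod
    def participants(n, values, stratum="0"):
        return [
            Participant(id=f"p{i}", age_years=30, sex="male", sample_weight=1.0,
                        variance_stratum=stratum)
            for i in range(n)
        ], dict(zip([f"p{i}" for i in range(n)], values))

    def test_degenerate_cohort_gives_zero_se(self):
        parts, vals = self.participants(40, [1.0] * 40)

        def stat(resampled, seed):
            return float(np.mean([vals[p.id.split("#")[0]] for p in resampled]))

        se, (lo, hi), _ = bootstrap_se(stat, parts, B=100, seed=1)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert lo == hi == 1.0

    def test_bernoulli_toy_matches_binomial_closed_form(self, rng):
        n, p = 100, 0.5
        parts, vals = self.participants(n, (rng.random(n) < p).astype(float))

        def stat(resampled, seed):
            return float(np.mean([vals[p.id.split("#")[0]] for p in resampled]))

        se, _, reps = bootstrap_se(stat, parts, B=500, seed=2)
        closed = np.sqrt(p * (1 - p) / n)
        assert se == pytest.approx(closed, rel=0.20)
        assert len(reps) == 500

    def test_deterministic_given_seed(self, rng):
        parts, vals = self.participants(30, rng.normal(size=30))

        def stat(resampled, seed):
            return float(np.mean([vals[p.id.split("#")[0]] for p in resampled]))

        a = bootstrap_se(stat, parts, B=60, seed=9)
        b = bootstrap_se(stat, parts, B=60, seed=9)
        assert a[0] == b[0] and np.array_equal(a[2], b[2])

    def test_resampling_respects_variance_strata(self, rng):
        # values differ by stratum; within-stratum resampling keeps the
        # stratum composition fixed so replicate means stay in range
        parts_a, _ = self.participants(20, [0.0] * 20, stratum="A")
        parts_b = [
            Participant(id=f"q{i}", age_years=30, sex="male", sample_weight=1.0,
                        variance_stratum="B")
            for i in range(20)
        ]
        vals = {p.id: 0.0 for p in parts_a}
        vals.update({p.id: 1.0 for p in parts_b})

        def stat(resampled, seed):
            return float(np.mean([vals[p.id.split("#")[0]] for p in resampled]))

        se, (lo, hi), reps = bootstrap_se(stat, parts_a + parts_b, B=100, seed=3)
        assert np.allclose(reps, 0.5)  # composition exactly preserved
        assert se == 0.0

    def test_excess_failures_raise(self):
        parts, _ = self.participants(10, [1.0] * 10)

        def bad_stat(resampled, seed):
            raise RuntimeError("no convergence")

        with pytest.raises(RuntimeError, match="replicates failed"):
            bootstrap_se(bad_stat, parts, B=50, seed=4)

    def test_small_B_rejected(self):
        parts, _ = self.participants(10, [1.0] * 10)
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_se(lambda r, s: 0.0, parts, B=10, seed=0)


class TestCINonOverlap:
    def make(self, pct, lo, hi):
        return PrevalenceEstimate(percent=pct, ci_lower=lo, ci_upper=hi)

    def test_disjoint_intervals_significant(self):
        assert ci_nonoverlap(self.make(10, 9, 11), self.make(20, 19, 21))

    def test_overlapping_intervals_not_significant(self):
        assert not ci_nonoverlap(self.make(10, 9, 11), self.make(11, 10.5, 12))

    def test_touching_bounds_count_as_overlap(self):
        assert not ci_nonoverlap(self.make(10, 9, 11), self.make(12, 11, 13))

    def test_symmetry(self):
        a, b = self.make(10, 9, 11), self.make(20, 19, 21)
        assert ci_nonoverlap(a, b) == ci_nonoverlap(b, a)

    def test_missing_ci_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            ci_nonoverlap(PrevalenceEstimate(percent=10.0), self.make(1, 0, 2))
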