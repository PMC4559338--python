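import numpy as np
import pytest

from dairyshift.adequacy import prevalence_below
from dairyshift.data_model import RecallDay, RecommendationTable
from dairyshift.diet_model import add_supplements, augment_cohort, augment_recall_day, dairy_gap
from dairyshift.nutrients import DAIRY_COMPOSITE, NutrientVector
from dairyshift.synthetic import CohortConfig, generate_cohort
from dairyshift.usual_intake import UsualIntakeDistribution


def make_day(dairy, calcium=500.0, pid="p", seq=1):
    return RecallDay(
        pid, seq, False, dairy, subgroups_known=False,
        food=NutrientVector(calcium=calcium, vitamin_d=3.0),
    )


class TestDairyGap:
    @pytest.mark.parametrize(
        "age,servings,expected",
        [
            (5, 2.5, 0.0),  # at the 4-8 y recommendation
            (30, 3.4, 0.0),  # above recommendation: never reduced
            (12, 1.0, 2.0),  # 3.0 recommended from age 9 up
            (2, 0.0, 2.0),
            (8, 1.0, 1.5),
            (71, 2.9, pytest.approx(0.1)),
        ],
    )
    def test_gap_examples(self, age, servings, expected):
        assert dairy_gap(age, servings) == expected

    def test_age_below_range_is_domain_error(self):
        with pytest.raises(ValueError, match="below the study range"):
            dairy_gap(1, 0.0)

    def test_custom_recommendation_table(self):
        rec = RecommendationTable([(2, 200, 4.0)])
        assert dairy_gap(30, 1.0, rec) == 3.0


class TestAugmentRecallDay:
    def test_gap_times_composite_added(self):
        # 1.38 cup-eq short of the adult recommendation
        day = make_day(dairy=3.0 - 1.38, calcium=1025.0)
        out = augment_recall_day(day, 30, DAIRY_COMPOSITE)
        assert out.dairy_total == pytest.approx(3.0, abs=1e-12)
        assert out.food["calcium"] - day.food["calcium"] == pytest.approx(1.38 * 298, abs=1e-9)
        assert out.food["vitamin_d"] - day.food["vitamin_d"] == pytest.approx(
            1.38 * 1.55, abs=1e-9
        )

    def test_zero_gap_returns_identical_day(self):
        day = make_day(dairy=3.5)
        assert augment_recall_day(day, 30, DAIRY_COMPOSITE) is day

    def test_gap_zero_iff_unmodified(self):
        below = make_day(dairy=1.0)
        out = augment_recall_day(below, 30, DAIRY_COMPOSITE)
        assert out.dairy_total > below.dairy_total
        assert not out.food.isclose(below.food)


class TestAugmentCohort:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        participants, days = generate_cohort(CohortConfig(n_participants=200, seed=7))
        return participants, days

    def test_composite_delta_identity_exact(self, cohort):
        # mean(modified) - mean(original) = delta-dairy x composite, exactly
        participants, days = cohort
        result = augment_cohort(participants, days, DAIRY_COMPOSITE)
        w = {p.id: p.sample_weight for p in participants}
        den = sum(w[d.participant_id] for d in days)
        d_dairy = (
            sum(w[d.participant_id] * (m.dairy_total - d.dairy_total)
                for d, m in zip(days, result.days)) / den
        )
        for nutrient in ("calcium", "magnesium", "vitamin_d", "energy", "sodium"):
            d_nut = (
                sum(w[d.participant_id] * (m.food[nutrient] - d.food[nutrient])
                    for d, m in zip(days, result.days)) / den
            )
            assert d_nut == pytest.approx(d_dairy * DAIRY_COMPOSITE[nutrient], abs=1e-9)

    def test_no_day_below_recommendation_after_modeling(self, cohort):
        participants, days = cohort
        rec = RecommendationTable()
        ages = {p.id: p.age_years for p in participants}
        result = augment_cohort(participants, days, DAIRY_COMPOSITE)
        for d in result.days:
            assert d.dairy_total >= rec.recommended_cups(ages[d.participant_id]) - 1e-12

    def test_gaps_are_nonnegative(self, cohort):
        participants, days = cohort
        result = augment_cohort(participants, days, DAIRY_COMPOSITE)
        assert all(g >= 0 for g in result.gaps.values())
        assert result.total_gap > 0

    def test_per_participant_mean_variant(self, cohort):
        participants, days = cohort
        result = augment_cohort(participants, days, DAIRY_COMPOSITE, per_day=False)
        # both days of a participant receive the same added amount
        by_person = {}
        for (pid, seq), g in result.gaps.items():
            by_person.setdefault(pid, []).append(g)
        assert all(len(set(v)) == 1 for v in by_person.values())
        # total added servings match the per-day variant (mean preserved)
        per_day = augment_cohort(participants, days, DAIRY_COMPOSITE, per_day=True)
        assert result.total_gap == pytest.approx(per_day.total_gap, rel=1e-9)


class TestAddSupplements:
    def make_dist(self, values, ids):
        return UsualIntakeDistribution(
            values=np.asarray(values, float),
            source_ids=np.asarray(ids),
            weights=np.ones(len(values)),
            nutrient="calcium",
            seed=0,
        )

    def make_participants(self, supplements):
        from dairyshift.data_model import Participant

        return [
            Participant(id=k, age_years=30, sex="male", sample_weight=1.0, supplement=v)
            for k, v in supplements.items()
        ]

    def test_all_zero_supplements_is_identity(self):
        dist = self.make_dist([10.0, 20.0], ["a", "b"])
        parts = self.make_participants({"a": NutrientVector(), "b": NutrientVector()})
        out = add_supplements(dist, parts)
        assert np.array_equal(out.values, dist.values)

    def test_single_user_shifts_only_their_draws(self):
        dist = self.make_dist([10.0, 10.0, 20.0, 20.0], ["a", "a", "b", "b"])
        parts = self.make_participants(
            {"a": NutrientVector(calcium=200.0), "b": NutrientVector()}
        )
        out = add_supplements(dist, parts)
        assert list(out.values) == [210.0, 210.0, 20.0, 20.0]
        assert np.array_equal(out.weights, dist.weights)

    def test_missing_nutrient_logged_once_and_zero(self):
        dist = self.make_dist([10.0], ["a"])
        parts = self.make_participants({"a": NutrientVector(vitamin_d=5.0)})
        log = []
        out = add_supplements(dist, parts, log=log)
        assert out.values[0] == 10.0
        assert len(log) == 1 and "calcium" in log[0]

    def test_prevalence_never_increases_with_supplements(self):
        # brute-force monotonicity on a 50-person cohort
        participants, days = generate_cohort(CohortConfig(n_participants=50, seed=13))
        rng = np.random.default_rng(0)
        values = rng.lognormal(6.3, 0.5, size=50 * 20)
        ids = np.repeat([p.id for p in participants], 20)
        weights = np.repeat([p.sample_weight for p in participants], 20)
        dist = UsualIntakeDistribution(values, ids, weights, "calcium", seed=0)
        shifted = add_supplements(dist, participants)
        for thr in np.percentile(values, [10, 25, 50, 75, 90]):
            assert (
                prevalence_below(shifted, thr).percent
                <= prevalence_below(dist, thr).percent + 1e-12
            )
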