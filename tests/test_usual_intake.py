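import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special

from dairyshift.data_model import Participant
from dairyshift.synthetic import CohortConfig, NutrientGenParams, generate_cohort
from dairyshift.usual_intake import (
    LAMBDA_GRID,
    AmountModelParams,
    ProbabilityModelParams,
    UsualIntakeDistribution,
    back_transform_mean,
    boxcox_inverse,
    boxcox_transform,
    fit_amount_model,
    fit_consumption_model,
    simulate_usual_distribution,
)


def make_participants(n, weight=1.0):
    return [
        Participant(id=f"p{i}", age_years=30, sex="male", sample_weight=weight)
        for i in range(n)
    ]


class TestBoxCox:
    @given(
        st.floats(1e-3, 1e4, allow_nan=False),
        st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
    )
    def test_roundtrip(self, x, lam):
        assert boxcox_inverse(boxcox_transform(x, lam), lam) == pytest.approx(
            x, rel=1e-10, abs=1e-10
        )

    @given(st.sampled_from([0.0, 0.3, 0.7, 1.0]))
    def test_monotone_increasing(self, lam):
        xs = np.linspace(0.01, 50, 200)
        assert np.all(np.diff(boxcox_transform(xs, lam)) > 0)

    @pytest.mark.parametrize(
        "x,lam,expected",
        [(1.0, 0.37, 0.0), (5.0, 1.0, 4.0), (np.e, 0.0, 1.0)],
    )
    def test_known_values(self, x, lam, expected):
        assert boxcox_transform(x, lam) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_transform(0.0, 0.5)
        with pytest.raises(ValueError):
            boxcox_transform(-1.0, 0.0)


class TestBackTransformMean:
    def test_linear_case_ignores_noise(self):
        for s2 in (0.0, 0.5, 4.0):
            assert back_transform_mean(3.0, s2, 1.0) == 4.0

    def test_log_case_is_lognormal_mean(self):
        # E[e^{z+e}] = e^{z + s2/2} exactly
        assert back_transform_mean(0.0, 0.25, 0.0) == pytest.approx(np.exp(0.125), abs=1e-10)
        assert back_transform_mean(1.3, 0.8, 0.0) == pytest.approx(np.exp(1.7), rel=1e-12)

    def test_zero_noise_is_plain_inverse(self):
        for lam in (0.2, 0.45, 0.8):
            assert back_transform_mean(2.0, 0.0, lam) == pytest.approx(
                boxcox_inverse(2.0, lam), rel=1e-12
            )

    def test_taylor_close_to_quadrature_for_small_noise(self):
        z, s2, lam = 5.0, 0.04, 0.4
        taylor = back_transform_mean(z, s2, lam, method="taylor")
        quad = back_transform_mean(z, s2, lam, method="quadrature", n_nodes=21)
        assert taylor == pytest.approx(quad, rel=1e-4)

    def test_invalid_neighbourhood_raises_without_clip(self):
        # z close to the domain boundary -1/lam with large noise
        with pytest.raises(ValueError, match="invalid"):
            back_transform_mean(-1.9, 4.0, 0.5)
        assert back_transform_mean(-1.9, 4.0, 0.5, clip=True) >= 0.0


class TestAmountModelFit:
    def simulate(self, rng, n=2000, lam=0.4, mu=8.0, s_u=1.0, s_e=1.5, d_wk=0.5, d_seq=-0.1):
        u = rng.normal(0, s_u, n)
        ids = np.repeat(np.arange(n), 2)
        seq2 = np.tile([0.0, 1.0], n)
        wk = (rng.random(2 * n) < 2 / 7).astype(float)
        z = mu + u[ids] + d_wk * wk + d_seq * seq2 + rng.normal(0, s_e, 2 * n)
        y = boxcox_inverse(np.maximum(z, -1 / lam + 1e-9), lam)
        w = np.repeat(rng.lognormal(0, 0.5, n), 2)
        return y, ids, seq2, wk, w

    def test_lambda_recovery(self, rng):
        lams = []
        for _ in range(3):
            y, ids, seq2, wk, w = self.simulate(rng)
            fit = fit_amount_model(y, ids, seq2, wk, w)
            lams.append(fit.lam)
        assert abs(np.median(lams) - 0.4) <= 0.1

    def test_effects_and_variances_recovered_at_true_lambda(self, rng):
        # fixed effects and variance components live on the transform scale,
        # so recovery is judged at the generative exponent
        su2, se2, wks = [], [], []
        for _ in range(3):
            y, ids, seq2, wk, w = self.simulate(rng)
            fit = fit_amount_model(y, ids, seq2, wk, w, lam_grid=(0.4,))
            su2.append(fit.sigma2_u)
            se2.append(fit.sigma2_e)
            wks.append(fit.weekend_effect)
        assert abs(np.median(wks) - 0.5) <= 0.1
        assert abs(np.median(su2) - 1.0) <= 0.10 * 1.0
        assert abs(np.median(se2) - 2.25) <= 0.10 * 2.25

    def test_identical_days_give_zero_within_variance(self, rng):
        n = 200
        u = rng.normal(5.0, 1.0, n)
        ids = np.repeat(np.arange(n), 2)
        y = np.exp(0.3 * u)[ids]  # two identical days per person
        seq2 = np.tile([0.0, 1.0], n)
        fit = fit_amount_model(y, ids, seq2, np.zeros(2 * n), np.ones(2 * n))
        assert fit.sigma2_e < 1e-6

    def test_zero_amounts_shifted_and_recorded(self, rng):
        n = 100
        ids = np.repeat(np.arange(n), 2)
        y = rng.lognormal(1.0, 0.5, 2 * n)
        y[:5] = 0.0
        fit = fit_amount_model(y, ids, np.tile([0.0, 1.0], n), np.zeros(2 * n), np.ones(2 * n))
        assert fit.shift == pytest.approx(0.5 * y[y > 0].min())

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="2 participants"):
            fit_amount_model([1.0, 2.0], ["a", "a"], [0, 1], [0, 0], [1.0, 1.0])


class TestConsumptionModelFit:
    def test_homogeneous_probability_recovery(self, rng):
        target = special.logit(0.7)
        b0s = []
        for _ in range(3):
            n = 2000
            y = rng.random((n, 2)) < 0.7
            ids = np.repeat(np.arange(n), 2)
            fit = fit_consumption_model(
                y.ravel(), ids, np.tile([0.0, 1.0], n), np.zeros(2 * n), np.ones(2 * n)
            )
            b0s.append(fit.beta[0])
        assert abs(np.median(b0s) - target) <= 0.1

    def test_random_intercept_variance_recovery(self, rng):
        su2 = []
        for _ in range(3):
            n = 2000
            v = rng.normal(0, 1.0, n)
            eta = special.logit(0.7) + v
            y = rng.random((n, 2)) < special.expit(eta)[:, None]
            ids = np.repeat(np.arange(n), 2)
            fit = fit_consumption_model(
                y.ravel(), ids, np.tile([0.0, 1.0], n), np.zeros(2 * n), np.ones(2 * n)
            )
            su2.append(fit.sigma2_u)
        assert abs(np.median(su2) - 1.0) <= 0.25

    def test_all_consumers_degenerate_fallback(self):
        fit = fit_consumption_model(
            [True] * 6, ["a", "a", "b", "b", "c", "c"], [0, 1] * 3, [0] * 6, [1.0] * 6
        )
        assert fit.degenerate
        assert fit.usual_probability(0.0) == pytest.approx(1.0)

    def test_no_consumers_rejected(self):
        with pytest.raises(ValueError, match="no consumption"):
            fit_consumption_model([False] * 4, ["a", "a", "b", "b"], [0, 1] * 2, [0] * 4, [1.0] * 4)


class TestSimulateUsualDistribution:
    def test_degenerate_model_gives_constant_draws(self):
        params = AmountModelParams(lam=1.0, beta=(9.0, 0.0, 0.0), sigma2_u=0.0, sigma2_e=0.0,
                                   loglik=0.0)
        dist = simulate_usual_distribution(params, None, make_participants(5), m=10, seed=1)
        assert np.allclose(dist.values, 10.0)  # back-transformed linear predictor

    def test_gaussian_monte_carlo_mean_matches_closed_form(self):
        params = AmountModelParams(lam=1.0, beta=(99.0, 0.0, 0.0), sigma2_u=100.0,
                                   sigma2_e=25.0, loglik=0.0)
        dist = simulate_usual_distribution(params, None, make_participants(2000), m=100, seed=3)
        assert dist.weighted_mean() == pytest.approx(100.0, rel=0.005)

    def test_certain_consumption_equals_amount_only(self):
        params = AmountModelParams(lam=0.5, beta=(1.0, 0.0, 0.1), sigma2_u=0.2,
                                   sigma2_e=0.3, loglik=0.0)
        prob = ProbabilityModelParams(beta=(np.inf, 0.0, 0.0), sigma2_u=0.0, degenerate=True)
        parts = make_participants(50)
        a = simulate_usual_distribution(params, prob, parts, m=20, seed=5)
        b = simulate_usual_distribution(params, None, parts, m=20, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_reproducible_given_seed(self):
        params = AmountModelParams(lam=0.5, beta=(1.0, -0.05, 0.1), sigma2_u=0.2,
                                   sigma2_e=0.3, loglik=0.0)
        parts = make_participants(30)
        a = simulate_usual_distribution(params, None, parts, m=50, seed=7)
        b = simulate_usual_distribution(params, None, parts, m=50, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_refuses_oversized_request(self):
        params = AmountModelParams(lam=1.0, beta=(1.0, 0.0, 0.0), sigma2_u=0.0,
                                   sigma2_e=0.0, loglik=0.0)
        with pytest.raises(ValueError, match="lower m"):
            simulate_usual_distribution(params, None, make_participants(101), m=100_000, seed=0)

    def test_percentiles_monotone(self, calcium_fit):
        dist, _ = calcium_fit
        qs = np.arange(1, 100)
        vals = dist.percentile(qs)
        assert np.all(np.diff(vals) >= 0)


class TestPipelineStatisticalProperties:
    def test_usual_mean_matches_observed_day_mean(self, cohort_2000, calcium_fit):
        _, kept, days = cohort_2000
        dist, _ = calcium_fit
        w = {p.id: p.sample_weight for p in kept}
        num = sum(w[d.participant_id] * d.food["calcium"] for d in days)
        den = sum(w[d.participant_id] for d in days)
        assert dist.weighted_mean() == pytest.approx(num / den, rel=0.02)

    def test_usual_intake_shrinks_relative_to_single_days(self, cohort_2000, calcium_fit):
        _, kept, days = cohort_2000
        dist, params = calcium_fit
        day_values = np.array([d.food["calcium"] for d in days])
        assert params.sigma2_e > 0
        assert np.var(dist.values) < np.var(day_values)

    def test_lambda_grid_spans_unit_interval(self):
        assert LAMBDA_GRID[0] == 0.0 and LAMBDA_GRID[-1] == 1.0
        assert len(LAMBDA_GRID) == 21
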