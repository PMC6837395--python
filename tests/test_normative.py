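"""Cumulative-logit normative model: probabilities, likelihood, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logit

from randotkit.normative import (
    Covariates,
    OrdinalParams,
    age_covariate,
    cumulative_prob,
    fit_ordinal,
    ordinal_loglik,
    sample_score,
    sample_scores,
    score_pmf,
)
from randotkit.scores import LEVELS, NIL, ScoreError


def _monotone_alphas(draw_values):
    base = draw_values[0]
    gaps = np.abs(draw_values[1:])
    return tuple(base + np.concatenate(([0.0], np.cumsum(gaps + 1e-3))))


alphas_strategy = st.lists(
    st.floats(-4.0, 4.0), min_size=6, max_size=6
).map(_monotone_alphas)


class TestProbabilities:
    def test_reference_female_age10(self, reference_params):
        cov = Covariates(A=math.log10(120), x_male=0)
        assert cumulative_prob(reference_params, cov, 40) == pytest.approx(
            0.7086, abs=1e-3
        )

    def test_reference_male_scores_worse(self, reference_params):
        cov = Covariates(A=math.log10(120), x_male=1)
        p_male = cumulative_prob(reference_params, cov, 40)
        assert p_male == pytest.approx(0.6162, abs=1e-3)
        assert p_male < 0.7086

    def test_logistic_at_zero(self):
        params = OrdinalParams(alphas=(0, 1, 2, 3, 4, 5), beta=0.0, gamma=0.0)
        assert cumulative_prob(params, Covariates(A=0.0), 40) == pytest.approx(0.5)

    def test_nil_rejected_as_cumulative_level(self, reference_params):
        with pytest.raises(ScoreError):
            cumulative_prob(reference_params, Covariates(A=2.0), NIL)

    def test_pmf_is_difference_of_adjacent_cumulatives(self, reference_params):
        cov = Covariates(A=math.log10(120), x_male=0)
        pmf = score_pmf(reference_params, cov)
        assert pmf[1] == pytest.approx(0.1469, abs=1e-3)  # P(R = 60)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pmf_symmetric_for_symmetric_cuts(self):
        params = OrdinalParams(
            alphas=(-2.5, -1.5, -0.5, 0.5, 1.5, 2.5), beta=0.0, gamma=0.0
        )
        pmf = score_pmf(params, Covariates(A=0.0))
        assert pmf == pytest.approx(pmf[::-1], abs=1e-12)

    def test_nonmonotone_alphas_rejected(self):
        with pytest.raises(ValueError):
            OrdinalParams(alphas=(0, -1, 2, 3, 4, 5), beta=0.0, gamma=0.0)

    @given(alphas=alphas_strategy, A=st.floats(-2, 2), male=st.sampled_from([0, 1]))
    def test_cumulative_monotone_and_pmf_normalized(self, alphas, A, male):
        params = OrdinalParams(alphas=alphas, beta=-1.0, gamma=0.3)
        cov = Covariates(A=A, x_male=male)
        cum = [cumulative_prob(params, cov, lvl) for lvl in LEVELS]
        assert all(a <= b + 1e-15 for a, b in zip(cum, cum[1:]))
        pmf = score_pmf(params, cov)
        assert np.all(pmf >= 0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestLoglik:
    def test_single_record(self):
        params = OrdinalParams(alphas=(0, 1, 2, 3, 4, 5), beta=0.0, gamma=0.0)
        ll = ordinal_loglik(params, [40])  # P(R=40) = expit(0) = 0.5
        assert ll == pytest.approx(math.log(0.5))

    def test_additivity_under_duplication(self, reference_params, rng):
        age = rng.uniform(2, 11, 30)
        male = rng.integers(0, 2, 30).astype(float)
        scores = sample_scores(reference_params, age, male, rng)
        X = np.column_stack([age_covariate(age), male])
        ll1 = ordinal_loglik(reference_params, scores, X)
        ll3 = ordinal_loglik(reference_params, scores * 3, np.vstack([X] * 3))
        assert ll3 == pytest.approx(3 * ll1, rel=1e-12)

    def test_matches_per_record_pmf_product(self, reference_params, rng):
        age = rng.uniform(2, 11, 25)
        male = rng.integers(0, 2, 25).astype(float)
        scores = sample_scores(reference_params, age, male, rng)
        X = np.column_stack([age_covariate(age), male])
        categories = list(LEVELS) + [NIL]
        expected = 0.0
        for s, (A, m) in zip(scores, X):
            pmf = score_pmf(reference_params, Covariates(A=A, x_male=int(m)))
            expected += math.log(pmf[categories.index(s)])
        assert ordinal_loglik(reference_params, scores, X) == pytest.approx(expected)

    def test_impossible_category_gives_minus_inf(self):
        # with the last cut this saturated, P(nil) underflows to exactly zero
        params = OrdinalParams(alphas=(40, 41, 42, 43, 44, 45), beta=0.0, gamma=0.0)
        assert ordinal_loglik(params, [NIL]) == -math.inf


class TestFit:
    def test_intercept_only_equals_empirical_cumulative_logits(self, rng):
        pool = list(LEVELS) + [NIL]
        counts = np.array([30, 25, 20, 15, 10, 8, 6])
        scores = [s for s, c in zip(pool, counts) for _ in range(c)]
        fit = fit_ordinal(scores)
        cum = np.cumsum(counts)[:6] / counts.sum()
        assert fit.estimates[:6] == pytest.approx(logit(cum), abs=1e-5)
        assert fit.converged

    def test_cross_check_against_statsmodels_ordered_model(
        self, reference_params, rng
    ):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        n = 1500
        age = rng.uniform(2, 143 / 12, n)
        male = rng.integers(0, 2, n).astype(float)
        scores = sample_scores(reference_params, age, male, rng)
        A = age_covariate(age)
        X = np.column_stack([A, male])
        fit = fit_ordinal(scores, X, feature_names=("beta", "gamma"))

        from randotkit.scores import score_rank

        y = np.array([score_rank(s) for s in scores])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # the oracle's own gtol chatter
            sm_res = OrderedModel(y, X, distr="logit").fit(
                method="bfgs", disp=False, gtol=1e-8, maxiter=500
            )
        sm_thresh = sm_res.model.transform_threshold_params(sm_res.params)[1:-1]
        assert fit.params.alphas == pytest.approx(sm_thresh, abs=2e-3)
        assert fit.params.beta == pytest.approx(sm_res.params[0], abs=2e-3)
        assert fit.params.gamma == pytest.approx(sm_res.params[1], abs=2e-3)
        assert fit.loglik == pytest.approx(sm_res.llf, abs=1e-4)

    def test_analytic_gradient_matches_numeric(self, reference_params, rng):
        from scipy.optimize import approx_fprime

        from randotkit.normative import _neg_loglik_and_grad, _prepare_data

        age = rng.uniform(2, 11, 200)
        male = rng.integers(0, 2, 200).astype(float)
        scores = sample_scores(reference_params, age, male, rng)
        cats, X = _prepare_data(scores, np.column_stack([age_covariate(age), male]))
        theta = np.array([-5.0, 0.0, 0.0, 0.0, -0.5, 0.3, -3.0, 0.4])
        _, grad = _neg_loglik_and_grad(theta, cats, X)
        numeric = approx_fprime(
            theta, lambda t: _neg_loglik_and_grad(t, cats, X)[0], 1e-6
        )
        assert grad == pytest.approx(numeric, rel=1e-4, abs=1e-3)

    def test_covariates_never_increase_deviance(self, reference_params, rng):
        age = rng.uniform(2, 11, 600)
        male = rng.integers(0, 2, 600).astype(float)
        scores = sample_scores(reference_params, age, male, rng)
        X = np.column_stack([age_covariate(age), male])
        full = fit_ordinal(scores, X)
        null = fit_ordinal(scores)
        assert full.deviance <= null.deviance + 1e-6

    def test_too_few_categories_rejected(self):
        with pytest.raises(Exception):
            fit_ordinal([40] * 50)

    def test_beta_estimator_bias_small(self, reference_params):
        """Mean beta-hat over repeated cohorts is within 5% of the truth."""
        rng = np.random.default_rng(5)
        betas = []
        for _ in range(120):
            age = rng.uniform(2, 143 / 12, 1000)
            male = rng.integers(0, 2, 1000).astype(float)
            scores = sample_scores(reference_params, age, male, rng)
            X = np.column_stack([age_covariate(age), male])
            betas.append(fit_ordinal(scores, X, n_starts=1).params.beta)
        bias = np.mean(betas) - reference_params.beta
        assert abs(bias) < 0.05 * abs(reference_params.beta)

    def test_sex_effect_direction_across_ages(self, reference_params):
        for months in np.linspace(24, 143, 12):
            A = math.log10(months)
            p_f = cumulative_prob(reference_params, Covariates(A=A, x_male=0), 40)
            p_m = cumulative_prob(reference_params, Covariates(A=A, x_male=1), 40)
            assert p_m < p_f


class TestSampling:
    def test_same_seed_same_sequence(self, reference_params):
        cov = Covariates(A=math.log10(60), x_male=1)
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        seq1 = [sample_score(reference_params, cov, rng1) for _ in range(50)]
        seq2 = [sample_score(reference_params, cov, rng2) for _ in range(50)]
        assert seq1 == seq2

    def test_frequencies_converge_to_pmf(self, reference_params):
        rng = np.random.default_rng(17)
        n = 100_000
        cov = Covariates(A=math.log10(120), x_male=0)
        draws = sample_scores(
            reference_params, np.full(n, 10.0), np.zeros(n), rng
        )
        frac_40 = sum(1 for s in draws if s == 40) / n
        assert frac_40 == pytest.approx(0.7086, abs=0.01)

    def test_degenerate_params_saturate(self):
        # equal cut-points empty every intermediate category: all mass on
        # the extremes {40, nil}
        params = OrdinalParams(alphas=(0.0,) * 6, beta=0.0, gamma=0.0)
        rng = np.random.default_rng(1)
        draws = {sample_score(params, Covariates(A=0.0), rng) for _ in range(200)}
        assert draws == {40, NIL}
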