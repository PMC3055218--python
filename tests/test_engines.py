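"""Imputation engines: logistic fits, posterior draws, ABB, the normal
data-augmentation chain and the adaptive-quadrature random-intercept model."""

import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from crtmi import engines
from crtmi._errors import (
    ConvergenceError,
    EmptyStratumError,
    SeparationError,
    ValidationError,
)
from crtmi.cohort import COVARIATES, CohortConfig, generate_cohort
from crtmi.missingness import MissingnessSpec, apply_cd, apply_mcar
from crtmi.strategies import _design


def _newton_logistic_oracle(X, y, iters=100):
    """Independent brute-force Newton iteration for the logistic MLE."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = np.diag(mu * (1 - mu))
        beta = beta + np.linalg.solve(X.T @ W @ X, X.T @ (y - mu))
    return beta


class TestFitLogistic:
    def test_null_association_gives_zero_coefficient(self):
        # perfectly balanced 2x2: outcome independent of the covariate
        X = np.column_stack([np.ones(8), [0, 0, 1, 1, 0, 0, 1, 1]])
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        fit = engines.fit_logistic(X, y)
        assert abs(fit.params[1]) < 1e-8

    def test_one_class_raises_separation_with_stratum(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SeparationError, match="one-class") as exc:
            engines.fit_logistic(X, np.zeros(10), stratum="cluster=3")
        assert exc.value.stratum == "cluster=3"

    def test_matches_independent_newton_oracle(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=20), rng.integers(0, 2, 20)])
        y = (rng.random(20) < 0.5).astype(float)
        if len(np.unique(y)) < 2:  # pragma: no cover
            y[0] = 1 - y[0]
        fit = engines.fit_logistic(X, y)
        oracle = _newton_logistic_oracle(X, y)
        assert np.allclose(fit.params, oracle, atol=1e-8)
        sm_fit = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.params, sm_fit.params, atol=1e-6)
        assert np.allclose(fit.cov, sm_fit.cov_params(), atol=1e-5)

    def test_quasi_separation_flagged(self):
        # covariate perfectly splits the outcome
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        y[0], y[-1] = 0, 1  # keep both classes overall
        fit = engines.fit_logistic(np.column_stack([np.ones(20), x]), y)
        assert fit.separated


class TestPosteriorDraws:
    def test_zero_covariance_returns_point_estimate(self):
        fit = engines.LogisticFit(
            params=np.array([0.3, -1.2]), cov=np.zeros((2, 2)), converged=True, separated=False
        )
        draw = engines.draw_posterior_params(fit, np.random.default_rng(0))
        assert np.array_equal(draw, fit.params)

    def test_large_sample_moments_match_fit(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit = engines.LogisticFit(
            params=np.array([0.5, -0.2]), cov=cov, converged=True, separated=False
        )
        rng = np.random.default_rng(1)
        draws = np.array([engines.draw_posterior_params(fit, rng) for _ in range(20_000)])
        assert np.allclose(draws.mean(axis=0), fit.params, atol=0.01)
        assert np.allclose(np.cov(draws.T), cov, atol=0.01)

    def test_deterministic_given_seed(self):
        fit = engines.LogisticFit(
            params=np.array([0.5]), cov=np.array([[0.2]]), converged=True, separated=False
        )
        a = engines.draw_posterior_params(fit, np.random.default_rng(9))
        b = engines.draw_posterior_params(fit, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_unconverged_fit_rejected(self):
        fit = engines.LogisticFit(
            params=np.array([0.5]), cov=np.array([[0.2]]), converged=False, separated=False
        )
        with pytest.raises(ConvergenceError):
            engines.draw_posterior_params(fit, np.random.default_rng(0))


class TestImputeFromLogistic:
    def test_infinite_linear_predictor_caps(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0]])
        out = engines.impute_from_logistic(np.array([0.0, 1000.0]), X, np.random.default_rng(0))
        assert list(out) == [1, 0]

    def test_null_coefficients_give_half(self):
        X = np.ones((100_000, 1))
        out = engines.impute_from_logistic(np.zeros(1), X, np.random.default_rng(2))
        assert abs(out.mean() - 0.5) < 0.01

    def test_mean_matches_expit_of_known_model(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(100_000), rng.normal(size=100_000)])
        beta = np.array([-0.3, 0.8])
        out = engines.impute_from_logistic(beta, X, rng)
        expected = float(np.mean(1 / (1 + np.exp(-(X @ beta)))))
        assert abs(out.mean() - expected) < 0.01


@pytest.fixture(scope="module")
def cohort_df():
    return generate_cohort(CohortConfig(), seed=21).data


class TestPropensity:

    def test_mcar_gives_constant_propensity(self, cohort_df):
        mask = apply_mcar(cohort_df, 0.3, seed=1)
        X, _ = _design(cohort_df, COVARIATES, float(cohort_df["age"].mean()))
        prop = engines.compute_propensity(X, mask.astype(float))
        assert abs(prop.mean() - 0.3) < 0.03
        assert prop.std() < 0.03

    def test_cd_mask_raises_male_propensity(self, cohort_df):
        mask = apply_cd(cohort_df, MissingnessSpec("CD", 0.3), seed=2)
        X, _ = _design(cohort_df, COVARIATES, float(cohort_df["age"].mean()))
        prop = engines.compute_propensity(X, mask.astype(float))
        male = cohort_df["sex"].to_numpy() == 1
        assert prop[male].mean() > prop[~male].mean()

    def test_cluster_covariate_increases_co_stratification(self, cohort_df):
        """With cluster indicators in the propensity model, same-cluster rows
        land in the same stratum more often."""
        mask = apply_cd(cohort_df, MissingnessSpec("CD", 0.3), seed=3).astype(float)
        age_c = float(cohort_df["age"].mean())
        levels = sorted(cohort_df["cluster_id"].unique())
        X_plain, _ = _design(cohort_df, COVARIATES, age_c)
        X_clust, _ = _design(cohort_df, COVARIATES, age_c, cluster_levels=levels)

        def co_strat_rate(X):
            labels = engines.stratify_propensity(engines.compute_propensity(X, mask), 5)
            cid = cohort_df["cluster_id"].to_numpy()
            same = 0
            total = 0
            for c in np.unique(cid):
                sub = labels[cid == c]
                n = len(sub)
                total += n * (n - 1) / 2
                for s in np.unique(sub):
                    k = np.sum(sub == s)
                    same += k * (k - 1) / 2
            return same / total

        assert co_strat_rate(X_clust) > co_strat_rate(X_plain)


class TestStratify:
    def test_constant_propensities_collapse_to_one_stratum(self):
        with pytest.warns(UserWarning, match="collapsing"):
            labels = engines.stratify_propensity(np.full(30, 0.2), 5)
        assert len(np.unique(labels)) == 1

    def test_uniform_hundred_into_five_equal_strata(self):
        labels = engines.stratify_propensity(np.linspace(0, 1, 100), 5)
        assert np.array_equal(np.bincount(labels), [20, 20, 20, 20, 20])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=8, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_order_isomorphic_to_sorted_propensities(self, values):
        p = np.array(values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = engines.stratify_propensity(p, 4)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(labels[order]) >= 0)


class TestAbb:
    def test_constant_pool_imputes_constant(self):
        out = engines.abb_draw(np.ones(10), 7, np.random.default_rng(0))
        assert np.all(out == 1)

    def test_mean_preserved(self):
        pool = np.r_[np.ones(10), np.zeros(10)]
        rng = np.random.default_rng(1)
        means = [engines.abb_draw(pool, 20, rng).mean() for _ in range(3000)]
        assert abs(np.mean(means) - 0.5) < 0.01

    def test_two_stage_inflates_variance_over_single_stage(self):
        """ABB's extra bootstrap stage propagates parameter uncertainty: the
        imputed-proportion variance exceeds single-stage resampling."""
        pool = np.r_[np.ones(10), np.zeros(10)]
        rng = np.random.default_rng(2)
        abb = [engines.abb_draw(pool, 20, rng).mean() for _ in range(4000)]
        single = [pool[rng.integers(0, 20, 20)].mean() for _ in range(4000)]
        assert np.var(abb) > np.var(single) * 1.3

    def test_empty_pool_raises(self):
        with pytest.raises(EmptyStratumError):
            engines.abb_draw(np.array([]), 3, np.random.default_rng(0), stratum=("arm=1", 2))


class TestEmMvn:
    def test_complete_data_returns_sample_moments(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(50, 3))
        state = engines.em_mvn(data)
        assert state.em_converged and state.em_iterations == 0
        assert np.allclose(state.mean, data.mean(axis=0))
        assert np.allclose(state.cov, np.cov(data, rowvar=False, bias=True))

    def test_univariate_mcar_mean_is_observed_mean(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        data = x.copy()
        data[:50] = np.nan
        state = engines.em_mvn(data[:, None], tol=1e-10)
        assert state.mean[0] == pytest.approx(x[50:].mean(), abs=1e-8)

    def test_bivariate_monotone_matches_closed_form(self):
        """Monotone bivariate MLE has a closed form via the factored
        likelihood (regression of y on x from complete pairs)."""
        rng = np.random.default_rng(6)
        n, r = 120, 70  # y observed only for the first r rows
        x = rng.normal(1.0, 2.0, size=n)
        y = 0.5 + 0.8 * x + rng.normal(0, 1.0, size=n)
        data = np.column_stack([y, x])
        data[r:, 0] = np.nan

        mu_x, s_xx = x.mean(), x.var()
        xc, yc = x[:r], y[:r]
        b1 = np.cov(xc, yc, bias=True)[0, 1] / xc.var()
        b0 = yc.mean() - b1 * xc.mean()
        resid_var = np.mean((yc - b0 - b1 * xc) ** 2)
        mu_y = b0 + b1 * mu_x
        s_xy = b1 * s_xx
        s_yy = resid_var + b1**2 * s_xx

        state = engines.em_mvn(data, tol=1e-12, max_iter=5000)
        assert state.mean[0] == pytest.approx(mu_y, abs=1e-6)
        assert state.mean[1] == pytest.approx(mu_x, abs=1e-6)
        assert state.cov[0, 0] == pytest.approx(s_yy, abs=1e-6)
        assert state.cov[0, 1] == pytest.approx(s_xy, abs=1e-6)
        assert state.cov[1, 1] == pytest.approx(s_xx, abs=1e-6)

    def test_nonconvergence_raises_with_delta(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(60, 2))
        data[:30, 0] = np.nan
        with pytest.raises(ConvergenceError, match="delta"):
            engines.em_mvn(data, tol=1e-14, max_iter=1)


class TestMcmcImpute:
    def test_rounding_contract(self):
        assert list(engines.round_binary([0.4999, 0.5, -0.3, 1.7])) == [0.0, 1.0, 0.0, 1.0]

    def test_no_missing_returns_data_unchanged(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(40, 2))
        state = engines.em_mvn(data)
        out = engines.mcmc_impute(state, 10, rng)
        assert np.array_equal(out, data[:, 0])

    def test_perfectly_correlated_covariate_determines_imputation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.5, 0.3, size=300)
        data = np.column_stack([x.copy(), x])
        mis = rng.random(300) < 0.3
        data[mis, 0] = np.nan
        state = engines.em_mvn(data, tol=1e-8)
        out = engines.mcmc_impute(state, 50, rng)
        agree = np.mean(out[mis] == engines.round_binary(x[mis]))
        assert agree > 0.9

    def test_batched_chain_matches_scalar_chain_distribution(self):
        """The batched multi-group chain is statistically the same sampler as
        the scalar per-group chain."""
        rng = np.random.default_rng(10)
        base = rng.normal(size=(45, 3))
        base[:, 0] = (base[:, 0] + 0.5 * base[:, 1] > 0).astype(float)
        data = base.copy()
        mis = rng.random(45) < 0.3
        data[mis, 0] = np.nan

        def scalar_mean():
            state = engines.em_mvn(data.copy(), tol=1e-6)
            r = np.random.default_rng(11)
            vals = [engines.mcmc_impute(state, 20, r)[mis].mean() for _ in range(60)]
            return np.mean(vals)

        def batched_mean():
            states = [engines.em_mvn(data.copy(), tol=1e-6) for _ in range(2)]
            chain = engines.BatchedMVNChain([data, data], states)
            r = np.random.default_rng(12)
            vals = []
            for _ in range(60):
                chain.advance(20, r)
                vals.append(chain.outcomes()[:, mis].mean())
            return np.mean(vals)

        assert abs(scalar_mean() - batched_mean()) < 0.08


class TestReLogistic:
    """Oracle values frozen from lme4::glmer (binomial, nAGQ=11) on the same
    generated fixtures."""

    def test_boundary_fixture_matches_glmer(self):
        df = generate_cohort(CohortConfig(n_clusters_per_arm=5, cluster_size=30), seed=42).data
        X, names = _design(df, COVARIATES, float(df["age"].mean()), add_arm=True)
        fit = engines.fit_re_logistic(X, df["outcome"].to_numpy(float), df["cluster_id"].to_numpy(), names=names)
        expected = {
            "intercept": -1.327522427,
            "arm": 1.127649472,
            "age": 0.034335035,
            "sex": 0.594823788,
            "diabetes": 0.179262659,
            "heart_disease": 0.292274625,
            "bp_controlled_baseline": 0.787533562,
        }
        for name, value in expected.items():
            assert fit.params[names.index(name)] == pytest.approx(value, abs=2e-4)
        assert fit.boundary and fit.sigma_b2 < 1e-4
        assert fit.loglik == pytest.approx(-188.6265, abs=1e-3)
        i = names.index("arm")
        assert np.sqrt(fit.cov[i, i]) == pytest.approx(0.250362580, abs=2e-4)

    def test_interior_fixture_matches_glmer(self):
        df = generate_cohort(CohortConfig(n_clusters_per_arm=6, cluster_size=40, sigma_b2=1.0), seed=7).data
        X, names = _design(df, COVARIATES, float(df["age"].mean()), add_arm=True)
        fit = engines.fit_re_logistic(X, df["outcome"].to_numpy(float), df["cluster_id"].to_numpy(), names=names)
        assert fit.params[names.index("arm")] == pytest.approx(1.4956320484, abs=5e-4)
        assert fit.sigma_b2 == pytest.approx(1.6043343, abs=5e-3)
        assert fit.loglik == pytest.approx(-258.1392, abs=1e-3)
        assert not fit.boundary
        i = names.index("arm")
        assert np.sqrt(fit.cov[i, i]) == pytest.approx(0.77005690, abs=5e-3)

    def test_zero_variance_data_reduces_to_plain_logistic(self):
        df = generate_cohort(CohortConfig(n_clusters_per_arm=10, cluster_size=50, sigma_b2=0.0), seed=13).data
        X, names = _design(df, COVARIATES, float(df["age"].mean()), add_arm=True)
        y = df["outcome"].to_numpy(float)
        fit = engines.fit_re_logistic(X, y, df["cluster_id"].to_numpy(), names=names)
        plain = engines.fit_logistic(X, y)
        assert fit.sigma_b2 < 0.02
        assert np.allclose(fit.params, plain.params, atol=0.05)

    def test_quadrature_refinement_shrinks_toward_converged_value(self):
        df = generate_cohort(CohortConfig(n_clusters_per_arm=6, cluster_size=40, sigma_b2=1.0), seed=7).data
        X, _ = _design(df, COVARIATES, float(df["age"].mean()), add_arm=True)
        y = df["outcome"].to_numpy(float)
        cid = df["cluster_id"].to_numpy()
        lls = {
            n: engines.fit_re_logistic(X, y, cid, n_nodes=n).loglik for n in (5, 11, 21, 51)
        }
        gaps = [abs(lls[n] - lls[51]) for n in (5, 11, 21)]
        assert gaps[0] >= gaps[1] >= gaps[2]

    def test_requires_two_clusters(self):
        X = np.ones((10, 1))
        with pytest.raises(ValidationError):
            engines.fit_re_logistic(X, np.r_[np.zeros(5), np.ones(5)], np.zeros(10))


class TestImputeFromReModel:
    def test_zero_variance_reduces_to_logistic_imputation(self):
        rng = np.random.default_rng(14)
        X = np.column_stack([np.ones(20_000), rng.normal(size=20_000)])
        beta = np.array([0.2, 0.5])
        cid = np.repeat(np.arange(200), 100)
        re_out = engines.impute_from_re_model(beta, 0.0, X, cid, np.random.default_rng(1))
        log_out = engines.impute_from_logistic(beta, X, np.random.default_rng(2))
        assert abs(re_out.mean() - log_out.mean()) < 0.02

    def test_per_cluster_mode_correlates_within_cluster(self):
        X = np.ones((20, 1))
        cid = np.repeat([0, 1], 10)
        beta = np.zeros(1)

        def pair_cov(mode, seed):
            rng = np.random.default_rng(seed)
            draws = np.array(
                [engines.impute_from_re_model(beta, 4.0, X, cid, rng, mode=mode) for _ in range(3000)]
            )
            a, b = draws[:, 0], draws[:, 1]  # same cluster
            return np.mean(a * b) - a.mean() * b.mean()

        assert pair_cov("per_cluster", 3) > 0.05
        assert abs(pair_cov("per_record", 4)) < 0.02

    def test_reproducible_given_seed(self):
        X = np.ones((50, 1))
        cid = np.repeat([0, 1], 25)
        a = engines.impute_from_re_model(np.zeros(1), 0.5, X, cid, np.random.default_rng(8))
        b = engines.impute_from_re_model(np.zeros(1), 0.5, X, cid, np.random.default_rng(8))
        assert np.array_equal(a, b)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            engines.impute_from_re_model(np.zeros(1), 0.5, np.ones((2, 1)), np.zeros(2), np.random.default_rng(0), mode="shared")


def test_modified_abb_is_explicitly_unimplemented():
    with pytest.raises(NotImplementedError):
        engines.modified_abb()
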