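"""Estimator checks: brute-force oracles, statsmodels cross-validation,
score identities, and weighting invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ippwlab.datagen import CohortSample, GenerativeParams, ScenarioSpec, \
    generate_cohort, get_scenario
from ippwlab.estimators import (
    ASSOCIATION_TERMS,
    RESPONSE_MODELS,
    DegenerateResponseError,
    ResponseModelSpec,
    compute_weights,
    fit_association_cca,
    fit_association_ippw,
    fit_cca_frame,
    fit_ippw_frame,
    fit_logistic,
    fit_response_model,
    parse_formula,
    response_model,
    wald_ci,
)


def brute_force_wls(X, y, w):
    """Independent weighted normal-equations oracle, accumulated by loops."""
    k = X.shape[1]
    A = np.zeros((k, k))
    b = np.zeros(k)
    for i in range(X.shape[0]):
        xi = X[i]
        A += w[i] * np.outer(xi, xi)
        b += w[i] * xi * y[i]
    return np.linalg.solve(A, b)


def make_sample(z, x, y, r, p=None):
    n = len(x)
    scen = ScenarioSpec("test", 0.0, 0.0, gamma_0=0.0)
    if p is None:
        p = np.full(n, 0.5)
    return CohortSample(z=np.asarray(z, float), x=np.asarray(x, float),
                       y=np.asarray(y, float), p=p,
                       r=np.asarray(r, np.int8), scenario=scen)


class TestResponseModelGrid:
    def test_eighteen_models_pairing(self):
        assert sorted(RESPONSE_MODELS) == list(range(1, 19))
        for k in range(1, 10):
            with_x = RESPONSE_MODELS[k]
            without = RESPONSE_MODELS[k + 9]
            assert with_x.includes_exposure and not without.includes_exposure
            assert without.variables == tuple(
                v for v in with_x.variables if v != "x"
            )
        assert RESPONSE_MODELS[1].variables == ("x", "z1", "z2", "z3", "z4")
        assert RESPONSE_MODELS[2].variables == (
            "x", "z1", "z2", "z3", "z4", "z5", "z6", "z7")
        assert RESPONSE_MODELS[7].variables == ("x", "z1", "z5")

    def test_outcome_never_admissible(self):
        with pytest.raises(ValueError, match="unobserved"):
            ResponseModelSpec(0, ("y", "z1"))

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            response_model(19)


class TestResponseFit:
    def test_intercept_only_mle_is_observed_rate(self):
        n = 100
        r = np.array([1] * 60 + [0] * 40, dtype=np.int8)
        sample = make_sample(np.zeros((n, 7)), np.zeros(n), np.zeros(n), r)
        fit = fit_response_model(sample, ResponseModelSpec(0, ()))
        np.testing.assert_allclose(fit.p_hat, 0.6, atol=1e-9)

    def test_score_identity(self, small_cohort):
        for k in (1, 2, 14):
            fit = fit_response_model(small_cohort, response_model(k))
            assert abs(fit.p_hat.sum() - small_cohort.r.sum()) < 1e-8

    def test_matches_statsmodels_logit(self, small_cohort):
        spec = response_model(1)
        fit = fit_response_model(small_cohort, spec)
        X = np.column_stack(
            [np.ones(small_cohort.n)]
            + [small_cohort.column(v) for v in spec.variables]
        )
        ref = sm.Logit(small_cohort.r, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)

    def test_degenerate_response_rejected(self):
        n = 20
        sample = make_sample(np.zeros((n, 7)), np.zeros(n), np.zeros(n),
                             np.ones(n, dtype=np.int8))
        with pytest.raises(DegenerateResponseError):
            fit_response_model(sample, response_model(14))

    def test_parameter_recovery_at_scale(self):
        # Under MNAR 6 the response model is misspecified (it cannot see y),
        # but its fitted coefficients define a stable pseudo-true value: two
        # independent large cohorts must agree within joint sampling error.
        params = GenerativeParams(n=100_000)
        scen = get_scenario("MNAR 6", params)
        fits = [
            fit_response_model(generate_cohort(scen, params, seed=s),
                               response_model(1))
            for s in (1, 2)
        ]
        assert np.max(np.abs(fits[0].coef - fits[1].coef)) < 0.05


class TestWeights:
    @pytest.mark.parametrize("p,expected", [(0.5, 2.0), (0.25, 4.0)])
    def test_inverse_probability(self, p, expected):
        w = compute_weights(np.array([p]), np.array([1]))
        assert w[0] == pytest.approx(expected)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([1.0]), np.array([1]))

    def test_horvitz_thompson_sum(self):
        # With a correctly specified response model the weights of the
        # respondents add up to (an estimate of) the full cohort size.
        params = GenerativeParams(n=200_000)
        scen = get_scenario("MAR 2", params)
        sample = generate_cohort(scen, params, seed=3)
        fit = fit_response_model(sample, response_model(1))
        w = compute_weights(fit.p_hat, sample.r)
        assert w.sum() / sample.n == pytest.approx(1.0, abs=0.02)


class TestAssociationFits:
    def test_exact_fit_recovers_coefficients(self):
        # Outcome built exactly from the association regressors: any
        # response pattern must return beta = 0.5 to machine precision.
        rng = np.random.default_rng(1)
        n = 60
        z = rng.standard_normal((n, 7))
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + 0.17 * z[:, 0] + 0.17 * z[:, 4]
        r = (rng.random(n) < 0.7).astype(np.int8)
        sample = make_sample(z, x, y, r)
        rec = fit_association_cca(sample)
        assert rec.beta_hat == pytest.approx(0.5, abs=1e-12)

    def test_five_point_hand_dataset_matches_oracle(self):
        z = np.zeros((5, 7))
        z[:, 0] = [0.5, -1.0, 0.2, 1.5, -0.3]
        z[:, 4] = [1.0, 0.0, -0.5, 0.3, 0.8]
        x = np.array([0.0, 1.0, 2.0, -1.0, 0.5])
        y = np.array([1.2, 2.5, 2.9, 0.1, 1.8])
        r = np.ones(5, dtype=np.int8)
        sample = make_sample(z, x, y, r)
        rec = fit_association_cca(sample)
        X = np.column_stack([np.ones(5), x, z[:, 0], z[:, 4]])
        expect = brute_force_wls(X, y, np.ones(5))
        assert rec.beta_hat == pytest.approx(expect[1], abs=1e-10)

    def test_cca_se_matches_statsmodels_ols(self, small_cohort):
        rec = fit_association_cca(small_cohort)
        m = small_cohort.respondent_mask
        X = np.column_stack(
            [np.ones(small_cohort.n)]
            + [small_cohort.column(v) for v in ASSOCIATION_TERMS]
        )[m]
        ref = sm.OLS(small_cohort.y[m], X).fit()
        assert rec.beta_hat == pytest.approx(ref.params[1], abs=1e-10)
        assert rec.se == pytest.approx(ref.bse[1], abs=1e-10)

    def test_ippw_matches_statsmodels_wls_hc0(self, small_cohort):
        spec = response_model(1)
        rec = fit_association_ippw(small_cohort, spec)
        fit = fit_response_model(small_cohort, spec)
        w = compute_weights(fit.p_hat, small_cohort.r)
        m = small_cohort.respondent_mask
        X = np.column_stack(
            [np.ones(small_cohort.n)]
            + [small_cohort.column(v) for v in ASSOCIATION_TERMS]
        )[m]
        ref = sm.WLS(small_cohort.y[m], X, weights=w).fit(cov_type="HC0")
        assert rec.beta_hat == pytest.approx(ref.params[1], abs=1e-10)
        assert rec.se == pytest.approx(ref.bse[1], abs=1e-10)

    def test_constant_weights_equal_cca(self, small_cohort):
        # An intercept-only response model gives every respondent the same
        # weight, which must cancel exactly.
        rec_w = fit_association_ippw(small_cohort, ResponseModelSpec(0, ()))
        rec_c = fit_association_cca(small_cohort)
        assert rec_w.beta_hat == pytest.approx(rec_c.beta_hat, abs=1e-12)
        lo, hi, mean = rec_w.weight_summary
        assert lo == pytest.approx(hi)

    def test_weight_rescaling_invariance(self, small_cohort):
        rec = fit_association_ippw(small_cohort, response_model(7))
        capped = fit_association_ippw(small_cohort, response_model(7),
                                      weight_cap=np.inf)
        assert rec.beta_hat == capped.beta_hat
        # direct invariance check on the WLS solver
        from ippwlab.estimators import _wls_beta
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        w = rng.random(12) + 0.1
        b1, *_ = _wls_beta(X, y, w)
        b2, *_ = _wls_beta(X, y, 7.3 * w)
        np.testing.assert_allclose(b1, b2, atol=1e-12)

    def test_se_method_hook(self, small_cohort):
        rec_m = fit_association_ippw(small_cohort, response_model(1),
                                     se_method="model")
        assert rec_m.se > 0
        with pytest.raises(ValueError, match="se_method"):
            fit_association_ippw(small_cohort, response_model(1),
                                 se_method="linearized")


class TestWaldCI:
    def test_standard_normal_quantile(self):
        lo, hi = wald_ci(0.0, 1.0)
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    n=st.integers(min_value=5, max_value=10),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_weighted_ols_equals_brute_force_oracle(n, seed):
    """WLS solution equals the explicit (X'WX)^-1 X'Wy on random datasets."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    y = rng.standard_normal(n)
    w = rng.random(n) + 0.05
    from ippwlab.estimators import _wls_beta

    beta, *_ = _wls_beta(X, y, w)
    np.testing.assert_allclose(beta, brute_force_wls(X, y, w), atol=1e-10)


class TestLogisticSolver:
    def test_converges_on_separable_ish_small_data(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.standard_normal(200)])
        r = (expit(X[:, 1]) > rng.random(200)).astype(float)
        coef, converged, _ = fit_logistic(X, r)
        assert converged
        ref = sm.Logit(r, X).fit(disp=0)
        np.testing.assert_allclose(coef, ref.params, atol=1e-7)


class TestAppliedMode:
    def test_parse_formula(self):
        assert parse_formula("r ~ x + z1") == ("r", ["x", "z1"])
        assert parse_formula("r ~ 1") == ("r", [])
        with pytest.raises(ValueError):
            parse_formula("no tilde")

    def test_constant_response_probability_matches_cca(self, small_cohort):
        df = small_cohort.to_frame(observed=True)
        cca = fit_cca_frame(df, "y ~ x + z1 + z5", response_col="r")
        ippw = fit_ippw_frame(df, "r ~ 1", "y ~ x + z1 + z5")
        assert ippw.beta_hat == pytest.approx(cca.beta_hat, abs=1e-12)

    def test_parameter_recovery_within_two_se(self):
        params = GenerativeParams(n=4000)
        sample = generate_cohort(get_scenario("MAR 2", params), params, seed=5)
        df = sample.to_frame(observed=True)
        rec = fit_ippw_frame(df, "r ~ x + z1 + z2 + z3 + z4",
                             "y ~ x + z1 + z5")
        assert abs(rec.beta_hat - 0.5) < 2 * rec.se

    def test_outcome_banned_from_response_formula(self, small_cohort):
        df = small_cohort.to_frame(observed=True)
        with pytest.raises(ValueError, match="unobserved"):
            fit_ippw_frame(df, "r ~ y + z1", "y ~ x + z1 + z5")

    def test_missing_covariates_rejected_not_imputed(self, small_cohort):
        df = small_cohort.to_frame(observed=True)
        df.loc[3, "z1"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit_ippw_frame(df, "r ~ z1", "y ~ x + z1 + z5")
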