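"""Tests of the L1 covariate model: solver, path, selection, CV, predict."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from livernorm.lasso import (FrozenLassoModel, LassoPath, LiverSuvLasso,
                             lambda_max, lasso_fit, select_lambda_by_support,
                             standardize)
from livernorm.synthetic import (CohortConfig, DEFAULT_MEAN_COEFFICIENTS,
                                 generate_cohort)

from _oracles import lasso_bruteforce


def random_instance(rng, n, p, snr=1.0):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * (rng.random(p) < 0.6)
    y = 1.0 + X @ beta + snr * rng.standard_normal(n)
    return X, y


class TestStandardize:
    def test_definitional(self):
        Xs, par = standardize(np.array([[1.0], [2.0], [3.0]]), ["a"])
        assert abs(Xs.mean()) < 1e-12
        assert abs(Xs.std() - 1.0) < 1e-12

    def test_idempotent_on_standardized(self, rng):
        X = rng.standard_normal((50, 3))
        Xs, _ = standardize(X)
        Xss, _ = standardize(Xs)
        np.testing.assert_allclose(Xss, Xs, atol=1e-12)

    def test_inverse_identity(self, rng):
        X = rng.standard_normal((30, 4)) * 5 + 2
        Xs, par = standardize(X)
        np.testing.assert_allclose(par.inverse(Xs), X, atol=1e-12)

    def test_zero_variance_named(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(X)


class TestLambdaMax:
    def test_single_column_definition(self):
        x = np.array([1.0, -1.0]) / np.array([1.0, -1.0]).std()
        y = np.array([0.5, -0.5])
        assert lambda_max(x[:, None], y) == pytest.approx(0.5)

    def test_orthogonal_response(self, rng):
        Xs, _ = standardize(rng.standard_normal((10, 3)))
        y = np.zeros(10)
        assert lambda_max(Xs, y) == 0.0

    def test_fit_above_lambda_max_is_empty(self, rng):
        X, y = random_instance(rng, 10, 3)
        m = LiverSuvLasso(y, X)
        res = m.fit(1.001 * m.lambda_max)
        assert res.df_model == 0
        # independent brute-force check of the same claim
        Xs, _ = standardize(X)
        b = lasso_bruteforce(Xs, y - y.mean(), 1.001 * m.lambda_max)
        assert (b == 0).all()

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            lambda_max(rng.standard_normal((5, 2)), np.zeros(4))


class TestLassoFit:
    def test_all_zero_at_lambda_max(self, rng):
        X, y = random_instance(rng, 20, 4)
        m = LiverSuvLasso(y, X)
        res = m.fit(m.lambda_max)
        assert res.support == []
        assert res.intercept == pytest.approx(y.mean(), abs=1e-12)

    def test_single_predictor_soft_threshold(self):
        # standardized predictor with OLS slope 0.5; lambda 0.2 -> slope 0.3
        n = 40
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = 0.5 * x
        res = lasso_fit(x[:, None], y, 0.2, var_names=["x"])
        assert res.params_std[0] == pytest.approx(0.3, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 31))
            p = int(rng.integers(2, 7))
            X, y = random_instance(rng, n, p)
            m = LiverSuvLasso(y, X)
            lam = float(rng.choice([0.01, 0.1, 0.5])) * m.lambda_max
            res = m.fit(lam)
            oracle = lasso_bruteforce(m.exog_std, m.endog - m.endog.mean(), lam)
            np.testing.assert_allclose(res.params_std, oracle, atol=1e-6)

    def test_lambda_zero_matches_ols(self, rng):
        X, y = random_instance(rng, 50, 4)
        res = LiverSuvLasso(y, X).fit(0.0)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None)
        assert res.intercept == pytest.approx(coef[0], abs=1e-8)
        np.testing.assert_allclose(res.params.to_numpy(), coef[1:], atol=1e-8)

    def test_kkt_certificate(self, rng):
        for lam_frac in (0.02, 0.2, 0.8):
            X, y = random_instance(rng, 25, 5)
            m = LiverSuvLasso(y, X)
            res = m.fit(lam_frac * m.lambda_max)
            assert res.kkt_violation() < 1e-6

    def test_nan_rejected(self):
        X = np.ones((4, 1)) * np.arange(4)[:, None]
        with pytest.raises(ValueError):
            LiverSuvLasso([1.0, np.nan, 2.0, 3.0], X)
        with pytest.raises(ValueError, match="NaN"):
            Xn = X.copy(); Xn[0, 0] = np.nan
            LiverSuvLasso([1.0, 2.0, 3.0, 4.0], Xn)

    def test_sd_kind_requires_positive(self):
        with pytest.raises(ValueError, match="> 0"):
            LiverSuvLasso([0.4, -0.1, 0.3], np.arange(3.0)[:, None], kind="sd")

    def test_standardization_equivariance(self, rng):
        """Rescaling a covariate column leaves predictions unchanged and
        divides its original-scale coefficient by the same factor."""
        X, y = random_instance(rng, 40, 3)
        m = LiverSuvLasso(y, X)
        lam = 0.1 * m.lambda_max
        base = m.fit(lam)
        c = 37.5
        X2 = X.copy()
        X2[:, 1] *= c
        scaled = LiverSuvLasso(y, X2).fit(lam)
        np.testing.assert_allclose(scaled.predict(X2), base.predict(X),
                                   atol=1e-10)
        assert scaled.params.iloc[1] == pytest.approx(base.params.iloc[1] / c)

    def test_original_vs_standardized_prediction_identity(self, rng):
        X, y = random_instance(rng, 30, 4)
        m = LiverSuvLasso(y, X)
        res = m.fit(0.05 * m.lambda_max)
        via_std = m.endog.mean() + m.exog_std @ res.params_std
        np.testing.assert_allclose(res.predict(X), via_std, atol=1e-10)


class TestPath:
    def test_first_entry_empty_support_and_descent(self, rng):
        X, y = random_instance(rng, 30, 5)
        m = LiverSuvLasso(y, X)
        path = m.fit_path(n_lambdas=20)
        assert path.results[0].df_model == 0
        yc = y - y.mean()
        for res in path.results:
            zero_obj = yc @ yc / (2 * len(y))
            assert res.objective() <= zero_obj + 1e-12

    def test_lambdas_strictly_decreasing(self, rng):
        X, y = random_instance(rng, 30, 5)
        path = LiverSuvLasso(y, X).fit_path(n_lambdas=15)
        assert (np.diff(path.lambdas) < 0).all()

    def test_path_contains_true_support(self):
        """On low-noise synthetic cohorts, some penalty on the path selects a
        support containing all 12 generative variables (5 seeds).

        Exact support equality is not attainable: the blood-glucose and
        gamma-GTP slopes contribute less than the residual noise floor at
        this n, so null covariates can enter before them.
        """
        true = set(DEFAULT_MEAN_COEFFICIENTS)
        for seed in range(5):
            cfg = CohortConfig(n_subjects=1000, abnormal_fraction=0.0,
                               residual_sd_mean=0.05, seed=seed)
            cov, tgt, _ = generate_cohort(cfg)
            path = LiverSuvLasso(tgt["suv_mean"], cov).fit_path()
            assert any(true <= set(r.support) for r in path.results), seed


class TestSelectLambdaBySupport:
    @staticmethod
    def _fake_path(sizes):
        class R:
            def __init__(self, k):
                self.df_model = k
        lambdas = np.geomspace(1.0, 0.01, len(sizes))
        return LassoPath(lambdas=lambdas, results=[R(k) for k in sizes])

    def test_exact_match(self):
        path = self._fake_path([0, 3, 10, 15])
        assert select_lambda_by_support(path, 10).df_model == 10

    def test_closest_available(self):
        path = self._fake_path([0, 2, 4])
        assert select_lambda_by_support(path, 10).df_model == 4

    def test_target_zero_picks_lambda_max(self):
        path = self._fake_path([0, 3, 10])
        assert select_lambda_by_support(path, 0) is path.results[0]

    def test_empty_path_errors(self):
        with pytest.raises(ValueError):
            select_lambda_by_support(LassoPath(np.array([]), []), 5)


class TestCrossValidate:
    def test_noiseless_recovery(self, rng):
        X = rng.standard_normal((60, 3))
        y = 1.0 + X @ np.array([1.0, -0.5, 0.2])
        m = LiverSuvLasso(y, X)
        cv = m.cross_validate([1e-6 * m.lambda_max], k=2, seed=0)
        assert cv["cv_mse"].iloc[0] < 1e-6

    def test_intercept_only_error_is_response_variance(self, rng):
        X, y = random_instance(rng, 200, 3, snr=2.0)
        m = LiverSuvLasso(y, X)
        cv = m.cross_validate([2.0 * m.lambda_max], k=2, seed=1)
        assert cv["cv_mse"].iloc[0] == pytest.approx(np.var(y), rel=0.25)

    def test_determinism(self, rng):
        X, y = random_instance(rng, 40, 3)
        m = LiverSuvLasso(y, X)
        alphas = [0.1 * m.lambda_max, 0.01 * m.lambda_max]
        a = m.cross_validate(alphas, k=2, seed=3)
        b = m.cross_validate(alphas, k=2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_subjects(self, rng):
        X, y = random_instance(rng, 5, 2)
        with pytest.raises(ValueError):
            LiverSuvLasso(y, X).cross_validate([0.1], k=3)


class TestPredictAndSerialize:
    def test_zero_covariates_give_intercept(self, rng):
        X, y = random_instance(rng, 30, 3)
        res = LiverSuvLasso(y, X).fit(0.1)
        assert res.predict(np.zeros((1, 3)))[0] == pytest.approx(res.intercept)

    def test_published_sd_model_arithmetic(self):
        """A weight-only SUV-SD model (intercept 0.228, slope 0.0029)
        predicts 0.417 at the cohort-mean weight 65.18 kg."""
        model = FrozenLassoModel(kind="sd", intercept=0.228,
                                 coefficients=pd.Series({"weight": 0.0029}),
                                 lambda_internal=0.0, n_train=0)
        pred = model.predict(pd.DataFrame({"weight": [65.18]}))[0]
        assert pred == pytest.approx(0.417, abs=5e-4)

    def test_training_residual_mean_is_zero(self, rng):
        X, y = random_instance(rng, 50, 4)
        m = LiverSuvLasso(y, X)
        res = m.fit(0.2 * m.lambda_max)
        assert abs(res.resid.mean()) < 1e-10

    def test_missing_support_variable_named(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        y = X["a"] * 2 + rng.standard_normal(30) * 0.1
        m = LiverSuvLasso(y, X)
        res = m.fit(0.05 * m.lambda_max)
        assert "a" in res.support
        with pytest.raises(KeyError, match="a"):
            res.predict(pd.DataFrame({"b": [1.0]}))

    def test_json_round_trip(self, rng, tmp_path):
        X = pd.DataFrame(rng.standard_normal((30, 3)),
                         columns=["u", "v", "w"])
        y = 1 + X["u"] - 0.5 * X["w"] + 0.05 * rng.standard_normal(30)
        m = LiverSuvLasso(y, X)
        res = m.fit(0.05 * m.lambda_max)
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = FrozenLassoModel.from_json(path)
        np.testing.assert_allclose(loaded.predict(X), res.predict(X),
                                   atol=1e-12)
        raw = json.loads(path.read_text())
        assert raw["lambda_rss_scale"] == pytest.approx(
            2 * res.nobs * res.alpha)

    def test_summary_mentions_support(self, rng):
        X, y = random_instance(rng, 30, 3)
        res = LiverSuvLasso(y, X).fit(0.01)
        text = res.summary()
        assert "lambda" in text and "intercept" in text


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_kkt_holds_on_random_instances(seed):
    """Property: every fitted model carries a valid KKT certificate."""
    rng = np.random.default_rng(seed)
    X, y = random_instance(rng, int(rng.integers(10, 40)),
                           int(rng.integers(1, 7)))
    m = LiverSuvLasso(y, X)
    lam = float(rng.random()) * m.lambda_max
    res = m.fit(lam)
    assert res.kkt_violation() < 1e-6
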