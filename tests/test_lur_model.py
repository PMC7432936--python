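"""OLS core, VIF, supervised forward selection and LOOCV."""

import numpy as np
import pandas as pd
import pytest

import airlur as al
from airlur.errors import SingularDesignError
from airlur.geo_predictors import PredictorMatrix, PredictorSpec


def normal_equations(y, X):
    """Independent oracle: beta = (Z'Z)^-1 Z'y via explicit inversion."""
    Z = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Z.T @ Z, Z.T @ y)


def toy_matrix(X, priors=None, names=None):
    n, k = X.shape
    names = names or [f"v{j:02d}" for j in range(k)]
    priors = priors or ["0"] * k
    specs = [PredictorSpec(nm, "elevation", None, None, p) for nm, p in zip(names, priors)]
    data = pd.DataFrame(X, columns=names, index=[f"s{i}" for i in range(n)])
    return PredictorMatrix(data, specs)


class TestFitOls:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = al.fit_ols(2 * x, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_is_mean(self):
        y = np.array([3.0, 5.0, 4.0, 8.0])
        fit = al.fit_ols(y, None)
        assert fit.params["const"] == pytest.approx(y.mean())
        assert fit.r2 == 0.0

    def test_four_point_hand_fit(self):
        # normal equations by hand: slope 0.9, intercept 0.9
        fit = al.fit_ols([1, 2, 2, 4], pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}))
        assert fit.params["x"] == pytest.approx(0.9)
        assert fit.params["const"] == pytest.approx(0.9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = rng.integers(8, 21)
            k = rng.integers(1, 6)
            X = rng.standard_normal((n, k))
            y = rng.standard_normal(n)
            fit = al.fit_ols(y, pd.DataFrame(X, columns=[f"c{j}" for j in range(k)]))
            expect = normal_equations(y, X)
            got = fit.params.to_numpy()
            np.testing.assert_allclose(got, expect, rtol=1e-8)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(SingularDesignError) as err:
            al.fit_ols(np.arange(5.0), X)
        assert "b" in err.value.columns

    def test_rmse_definition(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.standard_normal(12)})
        y = rng.standard_normal(12)
        fit = al.fit_ols(y, X)
        sse = float(np.sum(fit.resid**2))
        assert fit.rmse == pytest.approx(np.sqrt(sse / 12))


class TestVif:
    def test_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1, 1, -1, 1, -1.0], "b": [1, 1, -1, -1, 1, 1, -1, -1.0]})
        got = al.vif(X)
        assert got["a"] == pytest.approx(1.0)
        assert got["b"] == pytest.approx(1.0)

    def test_duplicated_column_infinite(self):
        x = np.arange(6.0)
        got = al.vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(got).all()

    def test_correlation_09_closed_form(self):
        n = 40
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        x = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = z - z.mean() - (z - z.mean()) @ x * x
        z = z / np.linalg.norm(z)
        y = 0.9 * x + np.sqrt(1 - 0.81) * z  # sample corr exactly 0.9
        got = al.vif(pd.DataFrame({"a": x, "b": y}))
        assert got["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)


class TestUnivariateScreen:
    def test_exact_generator_ranked_first(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        M = toy_matrix(X, priors=["+"] * 5)
        y = 3.0 * X[:, 2]
        screen = al.univariate_screen(y, M)
        assert screen.iloc[0]["name"] == "v02"
        assert screen.iloc[0]["r2"] == pytest.approx(1.0)

    def test_prior_violation_excluded_from_ranking(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        M = toy_matrix(x[:, None], priors=["+"])
        screen = al.univariate_screen(-2.0 * x, M)  # fitted slope negative
        assert not screen.iloc[0]["sign_ok"]

    def test_null_predictors_near_zero_adj_r2(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 8))
        M = toy_matrix(X)
        screen = al.univariate_screen(rng.standard_normal(200), M)
        assert screen["adj_r2"].abs().max() < 0.1


class TestForwardSelection:
    def test_recovers_true_predictors_low_noise(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 10))
        M = toy_matrix(X, priors=["+"] * 8 + ["-"] * 2)
        y = 2 * X[:, 0] + 1.5 * X[:, 3] - 2 * X[:, 8] + rng.normal(0, 0.05, 40)
        m = al.supervised_forward_select(y, M)
        assert set(m.predictor_names) == {"v00", "v03", "v08"}
        assert m.fit.r2 > 0.99

    def test_single_violating_candidate_gives_intercept_only(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        M = toy_matrix(x[:, None], priors=["+"])
        m = al.supervised_forward_select(-3.0 * x + rng.normal(0, 0.1, 20), M)
        assert m.intercept_only
        assert any(e.get("action") == "final" for e in m.selection_log)

    def test_duplicated_informative_column_keeps_one(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        noise = rng.standard_normal((30, 2))
        X = np.column_stack([x, x, noise])
        M = toy_matrix(X, priors=["+", "+", "0", "0"])
        m = al.supervised_forward_select(4 * x + rng.normal(0, 0.2, 30), M)
        assert sum(n in ("v00", "v01") for n in m.predictor_names) == 1

    def test_emitted_model_invariants(self, study):
        for m in study.models.values():
            priors = {s.name: s.sign_prior for s in m.specs}
            for name in m.predictor_names:
                beta = float(m.fit.params[name])
                p = float(m.fit.pvalues[name])
                assert p < m.p_max
                if priors[name] == "+":
                    assert beta > 0
                elif priors[name] == "-":
                    assert beta < 0
            if len(m.predictor_names) >= 2:
                assert m.vifs.max() < m.vif_max

    def test_adjusted_r2_nondecreasing_in_log(self, study):
        for m in study.models.values():
            adds = [e["adj_r2"] for e in m.selection_log if e.get("action") == "add"]
            assert all(b > a for a, b in zip(adds, adds[1:])) or len(adds) <= 1

    def test_column_permutation_invariant(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((35, 12))
        M = toy_matrix(X, priors=["+"] * 12)
        y = 2 * X[:, 1] + 2 * X[:, 5] + rng.normal(0, 0.3, 35)
        m1 = al.supervised_forward_select(y, M)
        rev = toy_matrix(X[:, ::-1], priors=["+"] * 12,
                         names=[f"v{j:02d}" for j in range(11, -1, -1)])
        m2 = al.supervised_forward_select(y, rev)
        assert set(m1.predictor_names) == set(m2.predictor_names)

    def test_too_few_sites_rejected(self):
        M = toy_matrix(np.random.default_rng(0).standard_normal((5, 2)))
        with pytest.raises(ValueError):
            al.supervised_forward_select(np.zeros(5), M)


class TestLoocv:
    def test_perfect_relation(self):
        x = np.arange(10.0)
        r2, preds = al.loocv(3 * x + 1, pd.DataFrame({"x": x}))
        assert r2 == pytest.approx(1.0)
        np.testing.assert_allclose(preds, 3 * x + 1)

    def test_intercept_only_hand_check(self):
        r2, preds = al.loocv([1.0, 2.0, 3.0], None)
        np.testing.assert_allclose(preds, [2.5, 2.0, 1.5])
        assert r2 == pytest.approx(-1.25)

    def test_loocv_not_above_insample_on_study_models(self, study):
        worse = 0
        for m in study.models.values():
            if np.isfinite(m.loocv_r2) and np.isfinite(m.fit.r2):
                worse += m.loocv_r2 <= m.fit.r2 + 1e-9
        assert worse == len(study.models)
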