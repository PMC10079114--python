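"""OLS/GLM/ANOVA against direct normal-equation and Newton oracles."""

import numpy as np
import pandas as pd
import pytest

from threatdyn.errors import CollinearityError, ConfigurationError, SchemaError
from threatdyn.inference import (
    anova_oneway,
    binned_trend,
    correlation_matrix,
    glm_binary,
    ols_regression,
    tukey_hsd,
)


class TestOLS:
    def test_noiseless_fit_exact(self):
        x = np.linspace(0, 1, 30)
        table = pd.DataFrame({"x": x, "y": 2.0 * x})
        res = ols_regression(table, "y", ["x"])
        assert res.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n, p = 200, 4
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.standard_normal(n)
        table = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
        table["y"] = y
        res = ols_regression(table, "y", [f"x{j}" for j in range(p)])
        Xd = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)
        # residual SE oracle
        resid = y - Xd @ beta
        se2 = resid @ resid / (n - p - 1)
        assert res.resid_se == pytest.approx(np.sqrt(se2), abs=1e-8)

    def test_listwise_deletion_count(self, rng):
        table = pd.DataFrame({"x": rng.standard_normal(50)})
        table["y"] = table["x"] * 2
        table.loc[0, "x"] = np.nan
        assert ols_regression(table, "y", ["x"]).n_obs == 49

    def test_collinear_design_names_terms(self, rng):
        x = rng.standard_normal(40)
        table = pd.DataFrame({"a": x, "b": 2 * x, "y": x + 1})
        with pytest.raises(CollinearityError) as err:
            ols_regression(table, "y", ["a", "b"])
        assert err.value.terms

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            ols_regression(pd.DataFrame({"y": [1.0, 2.0]}), "y", ["nope"])


class TestGLM:
    @staticmethod
    def _newton_logit(X, y, iters=50):
        """Textbook Newton-Raphson IRLS on the logit log-likelihood."""
        beta = np.zeros(X.shape[1])
        for _ in range(iters):
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            W = mu * (1 - mu)
            H = X.T @ (W[:, None] * X)
            g = X.T @ (y - mu)
            beta = beta + np.linalg.solve(H, g)
        return beta

    def test_logistic_matches_newton_oracle(self, rng):
        n = 500
        X = rng.standard_normal((n, 3))
        eta = 0.3 + X @ np.array([1.0, -1.5, 0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        table["y"] = y
        res = glm_binary(table, "y", ["a", "b", "c"])
        Xd = np.column_stack([np.ones(n), X])
        beta = self._newton_logit(Xd, y)
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-6)

    def test_recovery_within_wald_cis(self, rng):
        n = 4000
        X = rng.standard_normal((n, 3))
        truth = np.array([0.2, 1.0, -1.5, 0.5])
        eta = truth[0] + X @ truth[1:]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        table["y"] = y
        res = glm_binary(table, "y", ["a", "b", "c"])
        lo = res.params - 1.96 * res.bse
        hi = res.params + 1.96 * res.bse
        inside = (truth >= lo.to_numpy() - 1e-9) & (truth <= hi.to_numpy() + 1e-9)
        assert inside.sum() >= 3  # allow one marginal miss

    def test_constant_outcome_intercept_only(self):
        table = pd.DataFrame({"x": [0.1, 0.2, 0.3, 0.4], "y": [0.0] * 4})
        res = glm_binary(table, "y", ["x"])
        assert "intercept-only" in res.note
        assert list(res.terms) == ["const"]

    def test_linear_probability_option(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (rng.random(n) < np.clip(0.4 + 0.2 * x, 0.01, 0.99)).astype(float)
        table = pd.DataFrame({"x": x, "y": y})
        res = glm_binary(table, "y", ["x"], family="linear")
        assert res.family == "linear-probability"
        assert res.params["x"] == pytest.approx(0.2, abs=0.1)

    def test_non_binary_outcome_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [0.0, 0.5, 1.0]})
        with pytest.raises(ConfigurationError):
            glm_binary(table, "y", ["x"])

    def test_complete_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        table = pd.DataFrame({"x": x, "y": (x > 0).astype(float)})
        res = glm_binary(table, "y", ["x"])
        assert "separation" in res.note or np.isfinite(res.params["x"])


class TestAnova:
    def test_equal_groups_zero_noise_f_zero(self):
        table = pd.DataFrame({"y": [1.0] * 6, "g": list("aabbcc")})
        res = anova_oneway(table, "y", "g")
        assert res.f_statistic == 0.0

    def test_two_groups_equals_squared_t(self, rng):
        a = rng.standard_normal(40) + 0.5
        b = rng.standard_normal(35)
        table = pd.DataFrame({"y": np.r_[a, b],
                              "g": ["a"] * 40 + ["b"] * 35})
        res = anova_oneway(table, "y", "g")
        from scipy import stats

        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_affine_invariance_of_f(self, rng):
        y = rng.standard_normal(60)
        g = rng.choice(list("abc"), 60)
        t1 = pd.DataFrame({"y": y, "g": g})
        t2 = pd.DataFrame({"y": 5 * y + 3, "g": g})
        assert anova_oneway(t1, "y", "g").f_statistic == pytest.approx(
            anova_oneway(t2, "y", "g").f_statistic, rel=1e-10
        )

    def test_small_group_excluded_with_warning(self, rng):
        table = pd.DataFrame({
            "y": np.r_[rng.standard_normal(20), [9.9]],
            "g": ["a"] * 10 + ["b"] * 10 + ["tiny"],
        })
        with pytest.warns(UserWarning, match="tiny"):
            res = anova_oneway(table, "y", "g")
        assert "tiny" in res.excluded_groups
        assert res.df_between == 1

    def test_tukey_pairwise_rows(self, rng):
        table = pd.DataFrame({
            "y": rng.standard_normal(90) + np.repeat([0, 1, 3], 30),
            "g": np.repeat(list("abc"), 30),
        })
        tk = tukey_hsd(table, "y", "g")
        assert len(tk) == 3  # three pairwise comparisons
        ab = tk[(tk.group1 == "a") & (tk.group2 == "c")]
        assert bool(ab.reject.iloc[0])


class TestCorrelationAndTrend:
    def test_self_correlation_unit_diagonal(self, rng):
        table = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        corr = correlation_matrix(table)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.standard_normal((10000, 2)), columns=["a", "b"])
        assert abs(correlation_matrix(table).loc["a", "b"]) < 0.03

    def test_zero_variance_column_flagged(self, rng):
        table = pd.DataFrame({"a": rng.standard_normal(30), "b": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(table)
        assert np.isnan(corr.loc["a", "b"])

    def test_trend_identity_is_monotone(self):
        table = pd.DataFrame({"x": np.repeat(np.arange(5), 10)})
        table["y"] = table["x"].astype(float)
        trend = binned_trend(table, "x", "y")
        assert trend["spearman_rho"] == pytest.approx(1.0)

    def test_trend_constant_outcome_flagged_zero(self):
        table = pd.DataFrame({"x": np.repeat(np.arange(4), 5), "y": 1.0})
        trend = binned_trend(table, "x", "y")
        assert trend["spearman_rho"] == 0.0
        assert trend["flag"]
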