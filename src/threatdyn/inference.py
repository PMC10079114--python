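"""Regression, ANOVA and correlation battery shared by the survey and sweep analyses.

Thin, contract-enforcing wrappers around statsmodels: OLS with listwise
deletion and collinearity diagnosis, binomial GLM (logistic by default, with
a linear-probability option), classical one-way ANOVA with Tukey HSD
post-hocs, pairwise Pearson correlation matrices, and ordinal binned trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import CollinearityError, ConfigurationError, SchemaError

__all__ = [
    "RegressionTable",
    "AnovaResult",
    "ols_regression",
    "glm_binary",
    "anova_oneway",
    "tukey_hsd",
    "correlation_matrix",
    "binned_trend",
]


@dataclass
class RegressionTable:
    """A fitted regression in the package's common table form."""

    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_obs: int
    r_squared: float | None = None
    r_squared_adj: float | None = None
    f_statistic: float | None = None
    df_model: int | None = None
    df_resid: int | None = None
    resid_se: float | None = None
    log_likelihood: float | None = None
    aic: float | None = None
    family: str = "gaussian"
    note: str = ""

    @classmethod
    def from_statsmodels(cls, res, family: str = "gaussian", note: str = ""):
        is_ols = hasattr(res, "rsquared")
        return cls(
            terms=list(res.params.index),
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            n_obs=int(res.nobs),
            r_squared=float(res.rsquared) if is_ols else None,
            r_squared_adj=float(res.rsquared_adj) if is_ols else None,
            f_statistic=float(res.fvalue) if is_ols else None,
            df_model=int(res.df_model) if is_ols else None,
            df_resid=int(res.df_resid),
            resid_se=float(np.sqrt(res.mse_resid)) if is_ols else None,
            log_likelihood=float(res.llf),
            aic=float(res.aic),
            family=family,
            note=note,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )

    def summary(self) -> str:
        lines = [f"{self.family} regression, n = {self.n_obs}"]
        if self.r_squared is not None:
            lines.append(
                f"  R2 = {self.r_squared:.3f} (adj {self.r_squared_adj:.3f}), "
                f"F({self.df_model}, {self.df_resid}) = {self.f_statistic:.3f}, "
                f"residual SE = {self.resid_se:.3f}"
            )
        if self.log_likelihood is not None:
            lines.append(f"  logLik = {self.log_likelihood:.2f}, AIC = {self.aic:.2f}")
        if self.note:
            lines.append(f"  note: {self.note}")
        lines.append(self.to_frame().to_string(float_format="%.4f"))
        return "\n".join(lines)


def _design(table: pd.DataFrame, outcome: str, covariates: list[str]):
    missing = [c for c in [outcome, *covariates] if c not in table.columns]
    if missing:
        raise SchemaError(missing)
    data = table.loc[:, [outcome, *covariates]].astype(float).dropna(axis=0, how="any")
    y = data[outcome]
    X = sm.add_constant(data[list(covariates)])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via the QR diagonal
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise CollinearityError(bad or list(X.columns))
    return y, X


def ols_regression(table: pd.DataFrame, outcome: str,
                   covariates: list[str]) -> RegressionTable:
    """OLS with intercept and listwise deletion.

    Raises :class:`CollinearityError` naming the collinear terms when the
    design matrix is rank deficient.
    """
    y, X = _design(table, outcome, covariates)
    res = sm.OLS(y, X).fit()
    return RegressionTable.from_statsmodels(res, family="gaussian")


def glm_binary(table: pd.DataFrame, outcome: str, covariates: list[str],
               family: str = "logistic") -> RegressionTable:
    """Binary-outcome GLM: binomial-logistic (default) or linear probability.

    On complete separation the logistic fit falls back to an L2-penalised
    fit; the fallback is flagged in the result's ``note``.
    """
    y, X = _design(table, outcome, covariates)
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0}:
        raise ConfigurationError("glm_binary outcome must be coded 0/1")
    if family == "linear":
        res = sm.OLS(y, X).fit()
        return RegressionTable.from_statsmodels(res, family="linear-probability")
    if family != "logistic":
        raise ConfigurationError(f"unknown GLM family '{family}'")
    if len(vals) == 1:
        # degenerate outcome: intercept-only fit carries the information
        resc = sm.GLM(y, X.iloc[:, :1],
                      family=sm.families.Binomial()).fit()
        out = RegressionTable.from_statsmodels(
            resc, family="binomial-logit", note="constant outcome: intercept-only fit"
        )
        return out
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return RegressionTable.from_statsmodels(res, family="binomial-logit")
    except Exception:
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=False)
        rt = RegressionTable(
            terms=list(res.params.index), params=res.params,
            bse=pd.Series(np.nan, index=res.params.index),
            pvalues=pd.Series(np.nan, index=res.params.index),
            n_obs=int(res.nobs), family="binomial-logit",
            note="complete separation: L2-penalised fallback (no Wald SEs)",
        )
        return rt


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.Series
    group_sizes: pd.Series
    excluded_groups: list[str] = field(default_factory=list)

    def summary(self) -> str:
        s = (f"one-way ANOVA: F({self.df_between}, {self.df_within}) = "
             f"{self.f_statistic:.2f}, p = {self.p_value:.3g}")
        if self.excluded_groups:
            s += f" (excluded groups with <2 cases: {self.excluded_groups})"
        return s


def anova_oneway(table: pd.DataFrame, outcome: str, group: str) -> AnovaResult:
    """Classical one-way ANOVA.

    Groups with fewer than two complete cases are excluded with a warning.
    Zero between-group sum of squares reports F = 0 (covers the degenerate
    equal-means zero-noise case).
    """
    missing = [c for c in (outcome, group) if c not in table.columns]
    if missing:
        raise SchemaError(missing)
    data = table.loc[:, [outcome, group]].dropna(axis=0, how="any")
    sizes = data.groupby(group, observed=True)[outcome].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with <2 cases: {small}", UserWarning,
                      stacklevel=2)
        data = data[~data[group].isin(small)]
    groups = {k: v[outcome].to_numpy(dtype=float)
              for k, v in data.groupby(group, observed=True)}
    if len(groups) < 2:
        raise ConfigurationError("anova_oneway needs >=2 non-empty groups")
    grand = data[outcome].astype(float).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(data) - len(groups)
    if ss_between <= 0:
        f_stat, p = 0.0, 1.0
    elif ss_within <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    means = data.groupby(group, observed=True)[outcome].mean()
    return AnovaResult(float(f_stat), df_b, df_w, p, means,
                       sizes.drop(small, errors="ignore"), small)


def tukey_hsd(table: pd.DataFrame, outcome: str, group: str,
              alpha: float = 0.05) -> pd.DataFrame:
    """Tukey honest-significant-difference pairwise comparisons."""
    data = table.loc[:, [outcome, group]].dropna(axis=0, how="any")
    res = pairwise_tukeyhsd(data[outcome].astype(float), data[group], alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame


def correlation_matrix(table: pd.DataFrame,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations (unit diagonal, symmetric).

    Zero-variance columns yield NaN rows/columns and raise a warning.
    """
    cols = columns or [c for c in table.columns
                       if pd.api.types.is_numeric_dtype(table[c])]
    if len(cols) < 2 or len(table) < 3:
        raise ConfigurationError("correlation_matrix needs >=2 columns and >=3 rows")
    sub = table.loc[:, cols].astype(float)
    flat = sub.std(ddof=1)
    dead = flat[flat == 0].index.tolist()
    if dead:
        warnings.warn(f"zero-variance columns (undefined correlations): {dead}",
                      UserWarning, stacklevel=2)
    return sub.corr(method="pearson")


def binned_trend(table: pd.DataFrame, x: str, y: str) -> dict:
    """Per-level summary of y across an ordinal x, with a monotonicity statistic.

    Returns the per-bin mean/median/quartiles and the Spearman correlation of
    level vs. bin mean (0, flagged, when y is constant).
    """
    missing = [c for c in (x, y) if c not in table.columns]
    if missing:
        raise SchemaError(missing)
    data = table.loc[:, [x, y]].dropna(axis=0, how="any")
    if data[x].nunique() < 2:
        raise ConfigurationError("binned_trend needs >=2 levels of x")
    g = data.groupby(x)[y]
    summary = g.agg(["mean", "median", "count"])
    summary["q25"] = g.quantile(0.25)
    summary["q75"] = g.quantile(0.75)
    if data[y].nunique() < 2:
        rho, p, flag = 0.0, 1.0, "constant outcome: monotonicity undefined"
    else:
        rho, p = stats.spearmanr(summary.index.to_numpy(dtype=float),
                                 summary["mean"].to_numpy())
        flag = ""
    return {"summary": summary, "spearman_rho": float(rho),
            "p_value": float(p), "flag": flag}
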