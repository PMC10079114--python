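"""Structural equation modelling by maximum likelihood on the covariance matrix.

A small general linear SEM engine in the RAM parametrisation: variables are
the union of observed and latent; one matrix ``A`` holds directed paths
(factor loadings and regression slopes), one symmetric matrix ``S`` holds
variances and two-way covariances, and the model-implied covariance of the
observed variables is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

with ``F`` the observed-variable selection matrix.  The discrepancy minimised
is the normal-theory ML fit function

    F_ML = log|Sigma| + tr(S_xx Sigma^-1) - log|S_xx| - p

and chi-square = (n - 1) * F_ML at the optimum.  CFI/TLI are computed against
the independence baseline, RMSEA from chi-square/df, and the reported AIC is
the chi-square-based criterion chi2 + 2*k (comparison-consistent across
models fitted to the same data).

The default model shipped here is the two-cluster threat model used
throughout the package: social and predation threat subscales load on one
latent cluster, financial, contagion and natural threats on a second
(correlated) cluster; the clusters drive nationalism with opposite signs;
nationalism, both clusters, religious identification and supernatural belief
drive the two political-conservativism sliders; and the sliders drive the
binary "immigrants as undesirable neighbours" item.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .errors import ConfigurationError, ConvergenceError

__all__ = [
    "SemModel",
    "SemResults",
    "threat_cluster_spec",
    "reference_estimates",
    "simulate_from_estimates",
    "DEFAULT_MEANS",
]

_OPS = ("=~", "~", "~~")


@dataclass
class _Param:
    op: str  # "=~" loading, "~" regression, "~~" (co)variance
    lhs: str
    rhs: str
    value: float | None  # None => free
    free: bool
    index: int = -1  # position in theta if free

    @property
    def label(self) -> str:
        return f"{self.lhs} {self.op} {self.rhs}"


def threat_cluster_spec() -> dict:
    """Model description for the two-cluster threat model (JSON-serialisable).

    ``None`` marks a free parameter; a number fixes it.  The first indicator
    of each latent is fixed to 1 for identification.  The religious
    identification and supernatural-belief scores are exogenous observed
    predictors whose variances/covariance are held at their sample values
    ("saturated") and do not enter the degrees of freedom.
    """
    return {
        "latents": {
            "threat_sp": {"threat_social": 1.0, "threat_predation": None},
            "threat_cfn": {
                "threat_financial": 1.0,
                "threat_contagion": None,
                "threat_natural": None,
            },
        },
        "regressions": {
            "nationalism_full": {"threat_sp": None, "threat_cfn": None},
            "politics_social": {
                "threat_sp": None,
                "threat_cfn": None,
                "nationalism_full": None,
                "sid_religious": None,
                "sbs_extended": None,
            },
            "politics_economic": {
                "threat_sp": None,
                "threat_cfn": None,
                "nationalism_full": None,
                "sid_religious": None,
                "sbs_extended": None,
            },
            "wvs_undesirable_immigrants": {
                "politics_social": None,
                "politics_economic": None,
            },
        },
        "covariances": [["sid_religious", "sbs_extended"]],
        "saturated_exogenous": ["sid_religious", "sbs_extended"],
    }


def reference_estimates() -> pd.DataFrame:
    """Default generating values for the two-cluster model.

    These are the package's canonical parameter set for the synthetic-data
    generator and for parameter-recovery experiments; they reproduce the
    reported survey solution of the model (unit loadings on the anchor
    indicators, a strong positive social/predation path and strong negative
    contagion/financial/natural path into nationalism, weak paths into the
    political sliders, and a small positive social-conservativism path into
    anti-immigrant sentiment).
    """
    rows = [
        ("=~", "threat_sp", "threat_social", 1.00),
        ("=~", "threat_sp", "threat_predation", 0.81),
        ("=~", "threat_cfn", "threat_financial", 1.00),
        ("=~", "threat_cfn", "threat_contagion", 0.86),
        ("=~", "threat_cfn", "threat_natural", 0.56),
        ("~", "nationalism_full", "threat_sp", 2.75),
        ("~", "nationalism_full", "threat_cfn", -3.62),
        ("~", "politics_social", "threat_sp", 17.52),
        ("~", "politics_social", "threat_cfn", -23.23),
        ("~", "politics_social", "nationalism_full", -5.18),
        ("~", "politics_social", "sid_religious", -0.04),
        ("~", "politics_social", "sbs_extended", 0.48),
        ("~", "politics_economic", "threat_sp", 20.82),
        ("~", "politics_economic", "threat_cfn", -28.20),
        ("~", "politics_economic", "nationalism_full", -6.51),
        ("~", "politics_economic", "sid_religious", -0.08),
        ("~", "politics_economic", "sbs_extended", 0.26),
        ("~", "wvs_undesirable_immigrants", "politics_social", 0.06),
        ("~", "wvs_undesirable_immigrants", "politics_economic", 0.02),
        ("~~", "threat_social", "threat_social", 0.38),
        ("~~", "threat_predation", "threat_predation", 0.67),
        ("~~", "threat_financial", "threat_financial", 0.87),
        ("~~", "threat_contagion", "threat_contagion", 0.68),
        ("~~", "threat_natural", "threat_natural", 0.71),
        ("~~", "nationalism_full", "nationalism_full", 0.08),
        ("~~", "politics_social", "politics_social", 2.06),
        ("~~", "politics_economic", "politics_economic", 1.29),
        ("~~", "wvs_undesirable_immigrants", "wvs_undesirable_immigrants", 1.24),
        ("~~", "sid_religious", "sid_religious", 2.76),
        ("~~", "sbs_extended", "sbs_extended", 3.87),
        ("~~", "sid_religious", "sbs_extended", 1.23),
        ("~~", "threat_sp", "threat_sp", 0.30),
        ("~~", "threat_cfn", "threat_cfn", 0.19),
        ("~~", "threat_sp", "threat_cfn", 0.13),
    ]
    return pd.DataFrame(rows, columns=["op", "lhs", "rhs", "estimate"])


#: Observed-variable means used when simulating survey-scaled data.
DEFAULT_MEANS = {
    "threat_social": 2.6,
    "threat_predation": 2.4,
    "threat_financial": 3.0,
    "threat_contagion": 3.0,
    "threat_natural": 2.5,
    "nationalism_full": 3.6,
    "politics_social": 3.8,
    "politics_economic": 4.4,
    "wvs_undesirable_immigrants": 0.33,
    "sid_religious": 4.2,
    "sbs_extended": 5.0,
}


class SemModel:
    """Linear structural equation model.

    Parameters
    ----------
    spec : dict
        Model description as produced by :func:`threat_cluster_spec`.
    data : pandas.DataFrame, optional
        Raw observed data; listwise-deleted and centred internally.
    cov, n_obs : optional
        A sample covariance matrix (DataFrame) plus case count may be given
        instead of raw data.
    """

    def __init__(self, spec: dict, data: pd.DataFrame | None = None,
                 cov: pd.DataFrame | None = None, n_obs: int | None = None):
        self.spec = spec
        self._build_structure()
        if data is not None:
            use = data.loc[:, self.observed].astype(float).dropna(axis=0, how="any")
            if len(use) <= len(self.observed):
                raise ConfigurationError("not enough complete cases for SEM")
            self.sample_cov = use.cov()
            self.n_obs = len(use)
        elif cov is not None and n_obs is not None:
            self.sample_cov = cov.loc[self.observed, self.observed].astype(float)
            self.n_obs = int(n_obs)
        else:
            raise ConfigurationError("provide either data or (cov, n_obs)")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: dict | None = None) -> "SemModel":
        return cls(spec or threat_cluster_spec(), data=data)

    # -- structure -----------------------------------------------------------

    def _build_structure(self):
        spec = self.spec
        self.latents = list(spec.get("latents", {}))
        observed: list[str] = []

        def _add(v):
            if v not in observed and v not in self.latents:
                observed.append(v)

        for lat, inds in spec.get("latents", {}).items():
            for ind in inds:
                _add(ind)
        for dep, preds in spec.get("regressions", {}).items():
            _add(dep)
            for pr in preds:
                _add(pr)
        self.observed = observed
        self.variables = observed + self.latents
        self._idx = {v: i for i, v in enumerate(self.variables)}

        endogenous = set()
        params: list[_Param] = []
        for lat, inds in spec.get("latents", {}).items():
            for ind, val in inds.items():
                params.append(_Param("=~", lat, ind, val, val is None))
                endogenous.add(ind)
        for dep, preds in spec.get("regressions", {}).items():
            for pr, val in preds.items():
                params.append(_Param("~", dep, pr, val, val is None))
            endogenous.add(dep)

        saturated = list(spec.get("saturated_exogenous", []))
        self.saturated = saturated
        # residual variances: free for endogenous observed; saturated-fixed for
        # declared exogenous; latent variances/covariances free.
        for v in self.observed:
            if v in saturated:
                params.append(_Param("~~", v, v, "sample", False))
            elif v in endogenous:
                params.append(_Param("~~", v, v, None, True))
            else:
                params.append(_Param("~~", v, v, None, True))
        for i, a in enumerate(self.latents):
            params.append(_Param("~~", a, a, None, True))
        for i, a in enumerate(self.latents):
            for b in self.latents[i + 1:]:
                params.append(_Param("~~", a, b, None, True))
        for pair in spec.get("covariances", []):
            a, b = pair[0], pair[1]
            if a in saturated and b in saturated:
                params.append(_Param("~~", a, b, "sample", False))
            else:
                params.append(_Param("~~", a, b, None, True))

        j = 0
        for p in params:
            if p.free:
                p.index = j
                j += 1
        self.params = params
        self.n_free = j
        # saturated sample moments do not contribute degrees of freedom
        n_sat = len(saturated) * (len(saturated) + 1) // 2 if saturated else 0
        p_obs = len(self.observed)
        self.df = p_obs * (p_obs + 1) // 2 - self.n_free - n_sat

    # -- matrices ------------------------------------------------------------

    def _matrices(self, theta: np.ndarray, values: dict | None = None):
        m = len(self.variables)
        A = np.zeros((m, m))
        S = np.zeros((m, m))
        scov = self.sample_cov
        for p in self.params:
            if p.free:
                val = theta[p.index]
            elif p.value == "sample":
                val = float(scov.loc[p.lhs, p.rhs])
            else:
                val = float(p.value)
            if values is not None:
                values[p.label] = val
            if p.op == "=~":  # indicator <- latent
                A[self._idx[p.rhs], self._idx[p.lhs]] = val
            elif p.op == "~":  # lhs <- rhs
                A[self._idx[p.lhs], self._idx[p.rhs]] = val
            else:
                i, j = self._idx[p.lhs], self._idx[p.rhs]
                S[i, j] = val
                S[j, i] = val
        return A, S

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        A, S = self._matrices(theta)
        m = len(self.variables)
        B = np.linalg.solve(np.eye(m) - A, S)
        total = np.linalg.solve(np.eye(m) - A, B.T).T
        p = len(self.observed)
        return total[:p, :p]

    # -- fitting -------------------------------------------------------------

    def _objective(self, theta: np.ndarray) -> float:
        sigma = self.implied_cov(theta)
        s = self.sample_cov.to_numpy()
        p = s.shape[0]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            return 1e10
        try:
            inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        _, logdet_s = np.linalg.slogdet(s)
        val = logdet + float(np.sum(inv * s)) - logdet_s - p
        return val if np.isfinite(val) else 1e10

    def _objective_and_grad(self, theta: np.ndarray):
        """F_ML and its analytic gradient.

        With B = (I - A)^-1, Bp its observed rows, Sigma = Bp S Bp', and
        G = Sigma^-1 - Sigma^-1 S_xx Sigma^-1:
          d F / d S_ij = (Bp' G Bp)_ij * (2 - delta_ij)
          d F / d A_ij = 2 (B S Bp' G Bp)_ji
        """
        m = len(self.variables)
        p = len(self.observed)
        A, S = self._matrices(theta)
        s = self.sample_cov.to_numpy()
        try:
            B = np.linalg.inv(np.eye(m) - A)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(self.n_free)
        Bp = B[:p, :]
        sigma = Bp @ S @ Bp.T
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            return 1e10, np.zeros(self.n_free)
        inv = np.linalg.inv(sigma)
        _, logdet_s = np.linalg.slogdet(s)
        f = logdet + float(np.sum(inv * s)) - logdet_s - p
        if not np.isfinite(f):
            return 1e10, np.zeros(self.n_free)
        G = inv - inv @ s @ inv
        GBp = G @ Bp
        Q = Bp.T @ GBp                      # for S-parameters
        R = (B @ S @ Bp.T) @ GBp            # for A-parameters (index [j, i])
        grad = np.zeros(self.n_free)
        for prm in self.params:
            if not prm.free:
                continue
            if prm.op == "=~":
                i, j = self._idx[prm.rhs], self._idx[prm.lhs]
                grad[prm.index] = 2.0 * R[j, i]
            elif prm.op == "~":
                i, j = self._idx[prm.lhs], self._idx[prm.rhs]
                grad[prm.index] = 2.0 * R[j, i]
            else:
                i, j = self._idx[prm.lhs], self._idx[prm.rhs]
                grad[prm.index] = Q[i, j] * (1.0 if i == j else 2.0)
        return f, grad

    def _start_values(self) -> np.ndarray:
        """Heuristic starts: proxy latents = mean of their indicators."""
        scov = self.sample_cov
        proxies = {}
        data_vars = list(scov.columns)
        # proxy covariance matrix via linear combinations of sample cov
        weights = {}
        for lat, inds in self.spec.get("latents", {}).items():
            w = pd.Series(0.0, index=data_vars)
            for ind in inds:
                w[ind] = 1.0 / len(inds)
            weights[lat] = w
        for v in data_vars:
            weights[v] = pd.Series(
                [1.0 if u == v else 0.0 for u in data_vars], index=data_vars
            )

        def _cov(a, b):
            return float(weights[a] @ scov.to_numpy() @ weights[b])

        theta = np.zeros(self.n_free)
        for p in self.params:
            if not p.free:
                continue
            if p.op == "=~":
                vp = _cov(p.lhs, p.lhs)
                theta[p.index] = _cov(p.rhs, p.lhs) / vp if vp > 0 else 1.0
            elif p.op == "~":
                # marginal slope (ignores other predictors; adequate as a start)
                vp = _cov(p.rhs, p.rhs)
                theta[p.index] = _cov(p.lhs, p.rhs) / vp if vp > 0 else 0.0
            else:
                if p.lhs == p.rhs:
                    if p.lhs in self.latents:
                        theta[p.index] = max(0.5 * _cov(p.lhs, p.lhs), 1e-3)
                    else:
                        theta[p.index] = max(0.5 * float(scov.loc[p.lhs, p.lhs]), 1e-3)
                else:
                    theta[p.index] = 0.5 * _cov(p.lhs, p.rhs)
        return theta

    def fit(self, compute_se: bool = True, maxiter: int = 2000) -> "SemResults":
        """Minimise the ML discrepancy; return estimates, SEs and fit indices."""
        bounds = []
        for p in self.params:
            if not p.free:
                continue
            if p.op == "~~" and p.lhs == p.rhs:
                bounds.append((1e-6, None))
            else:
                bounds.append((None, None))
        theta0 = self._start_values()
        res = None
        # a handful of deterministic restarts guards against the rare
        # pathological line search from an unlucky start
        for attempt in range(3):
            start = theta0 if attempt == 0 else theta0 * (
                1.0 + 0.1 * attempt * np.cos(np.arange(self.n_free) + attempt)
            )
            cand = optimize.minimize(
                self._objective_and_grad, start, jac=True, method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                         "ftol": 1e-12, "gtol": 1e-8},
            )
            if res is None or cand.fun < res.fun:
                res = cand
            gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
            if res.success or gnorm <= 1e-2:
                break
        if not res.success and gnorm > 1e-2:
            raise ConvergenceError(
                f"SEM did not converge: {res.message}", n_iter=res.nit,
                gradient_norm=gnorm,
            )
        theta = res.x
        for p in self.params:
            if p.free and p.op == "~~" and p.lhs == p.rhs and theta[p.index] <= 2e-6:
                warnings.warn(
                    f"Heywood case: variance of '{p.lhs}' at its lower bound",
                    RuntimeWarning, stacklevel=2,
                )

        se = np.full(self.n_free, np.nan)
        if compute_se and self.n_free > 0:
            try:
                H = approx_hess1(theta, self._objective)
                cov_theta = 2.0 / (self.n_obs - 1) * np.linalg.pinv(H)
                d = np.diag(cov_theta)
                se = np.sqrt(np.where(d > 0, d, np.nan))
            except Exception:  # pragma: no cover - SE failure is non-fatal
                pass

        values: dict[str, float] = {}
        self._matrices(theta, values)
        rows = []
        for p in self.params:
            est = values[p.label]
            if p.free:
                s = se[p.index]
                z = est / s if s and np.isfinite(s) and s > 0 else np.nan
                pv = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            else:
                s, z, pv = np.nan, np.nan, np.nan
            rows.append((p.op, p.lhs, p.rhs, est, s, z, pv, p.free))
        estimates = pd.DataFrame(
            rows, columns=["op", "lhs", "rhs", "estimate", "se", "z", "p_value", "free"]
        )

        n = self.n_obs
        p_obs = len(self.observed)
        fmin = max(self._objective(theta), 0.0)
        chi2 = (n - 1) * fmin
        df = self.df
        s = self.sample_cov.to_numpy()
        _, logdet_s = np.linalg.slogdet(s)
        f_base = float(np.sum(np.log(np.diag(s))) - logdet_s)
        chi2_b = (n - 1) * max(f_base, 0.0)
        df_b = p_obs * (p_obs - 1) // 2
        if df > 0:
            num = max(chi2 - df, 0.0)
            den = max(chi2_b - df_b, num, 1e-12)
            cfi = 1.0 - num / den
            tli_den = chi2_b / df_b - 1.0
            tli = (chi2_b / df_b - chi2 / df) / tli_den if tli_den > 0 else 1.0
            rmsea = float(np.sqrt(num / (df * (n - 1))))
            p_chi2 = float(stats.chi2.sf(chi2, df))
        else:
            cfi, tli, rmsea, p_chi2 = 1.0, 1.0, 0.0, np.nan
        fit_indices = {
            "chi_square": float(chi2), "df": int(df), "p_value": p_chi2,
            "cfi": float(cfi), "tli": float(tli), "rmsea": rmsea,
            "aic": float(chi2 + 2 * self.n_free), "n_obs": int(n),
            "n_free": int(self.n_free),
        }
        implied = pd.DataFrame(
            self.implied_cov(theta), index=self.observed, columns=self.observed
        )
        return SemResults(self, estimates, fit_indices, implied, converged=res.success)


class SemResults:
    """Fitted SEM: parameter table, fit indices, implied covariance."""

    def __init__(self, model: SemModel, estimates: pd.DataFrame,
                 fit_indices: dict, implied_cov: pd.DataFrame, converged: bool):
        self.model = model
        self.estimates = estimates
        self.fit_indices = fit_indices
        self.implied_cov = implied_cov
        self.converged = converged

    def get(self, op: str, lhs: str, rhs: str) -> float:
        m = self.estimates
        row = m[(m.op == op) & (m.lhs == lhs) & (m.rhs == rhs)]
        if row.empty and op == "~~":
            row = m[(m.op == op) & (m.lhs == rhs) & (m.rhs == lhs)]
        if row.empty:
            raise KeyError(f"no parameter {lhs} {op} {rhs}")
        return float(row.estimate.iloc[0])

    def simulate(self, n: int, rng: np.random.Generator,
                 means: dict | None = None) -> pd.DataFrame:
        """Draw observed data from the fitted model (self-consistency checks)."""
        return simulate_from_estimates(self.estimates, self.model.spec, n, rng, means)

    def summary(self) -> str:
        fi = self.fit_indices
        lines = [
            "Structural equation model (ML on covariance matrix)",
            f"  n = {fi['n_obs']}, free parameters = {fi['n_free']}",
            (
                f"  chi2({fi['df']}) = {fi['chi_square']:.2f}, p = {fi['p_value']:.3g}, "
                f"CFI = {fi['cfi']:.3f}, TLI = {fi['tli']:.3f}, "
                f"RMSEA = {fi['rmsea']:.3f}, AIC = {fi['aic']:.2f}"
            ),
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            lines.append(self.estimates.to_string(index=False, float_format="%.3f"))
        return "\n".join(lines)


def _build_matrices_from_estimates(estimates: pd.DataFrame, spec: dict):
    model_vars: list[str] = []
    latents = list(spec.get("latents", {}))

    observed: list[str] = []
    for lat, inds in spec.get("latents", {}).items():
        for ind in inds:
            if ind not in observed:
                observed.append(ind)
    for dep, preds in spec.get("regressions", {}).items():
        if dep not in observed and dep not in latents:
            observed.append(dep)
        for pr in preds:
            if pr not in observed and pr not in latents:
                observed.append(pr)
    model_vars = observed + latents
    idx = {v: i for i, v in enumerate(model_vars)}
    m = len(model_vars)
    A = np.zeros((m, m))
    S = np.zeros((m, m))
    for _, r in estimates.iterrows():
        if r.op == "=~":
            A[idx[r.rhs], idx[r.lhs]] = r.estimate
        elif r.op == "~":
            A[idx[r.lhs], idx[r.rhs]] = r.estimate
        else:
            S[idx[r.lhs], idx[r.rhs]] = r.estimate
            S[idx[r.rhs], idx[r.lhs]] = r.estimate
    return A, S, observed, model_vars


def simulate_from_estimates(estimates: pd.DataFrame, spec: dict, n: int,
                            rng: np.random.Generator,
                            means: dict | None = None) -> pd.DataFrame:
    """Generate observed data exactly from a parameter table.

    Residuals/latents are drawn jointly normal with covariance ``S``; the
    reduced form is v = (I - A)^-1 e.  Data are continuous and unbounded (the
    survey generator applies its own scaling/clipping downstream).
    """
    A, S, observed, model_vars = _build_matrices_from_estimates(estimates, spec)
    m = len(model_vars)
    # eigen factorisation tolerates the PSD-but-singular S
    evals, evecs = np.linalg.eigh(S)
    evals = np.clip(evals, 0, None)
    L = evecs * np.sqrt(evals)
    e = rng.standard_normal((n, m)) @ L.T
    v = np.linalg.solve(np.eye(m) - A, e.T).T
    out = pd.DataFrame(v[:, : len(observed)], columns=observed)
    if means:
        for k, mu in means.items():
            if k in out.columns:
                out[k] = out[k] + mu
    return out
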