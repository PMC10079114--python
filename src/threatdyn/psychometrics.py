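"""Scale scoring, internal-consistency reliability, and exploratory factor analysis.

Implements the measurement layer of the survey battery: mean scoring of
multi-item Likert scales (with reverse-keying), Cronbach's alpha with the
Feldt F-distribution confidence interval, and principal-axis exploratory
factor analysis with varimax rotation (used for the two-item-per-trait
Big-Five check).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    ConvergenceError,
    SchemaError,
    UndefinedReliabilityError,
)

__all__ = [
    "ScaleDefinition",
    "ReliabilityReport",
    "EFAResult",
    "default_scale_definitions",
    "score_scale",
    "cronbach_alpha",
    "alpha_from_mean_correlation",
    "mean_correlation_for_alpha",
    "efa_varimax",
    "varimax",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A multi-item scale: its items, reverse-keyed subset and response range."""

    name: str
    items: tuple[str, ...]
    response_range: tuple[float, float]
    reverse: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.items) < 2:
            raise ConfigurationError(f"scale '{self.name}' needs >=2 items")
        if not set(self.reverse) <= set(self.items):
            raise ConfigurationError(
                f"scale '{self.name}': reverse-keyed items not a subset of items"
            )


@dataclass(frozen=True)
class ReliabilityReport:
    """Cronbach's alpha with a 95% Feldt confidence interval."""

    alpha: float
    ci_low: float
    ci_high: float
    n_items: int
    n_cases: int

    def __str__(self):  # pragma: no cover - cosmetic
        return (
            f"alpha = {self.alpha:.3f}, 95% CI [{self.ci_low:.3f}; {self.ci_high:.3f}] "
            f"(k = {self.n_items}, n = {self.n_cases})"
        )


def default_scale_definitions() -> dict[str, ScaleDefinition]:
    """Load the scale definitions shipped with the package.

    Every instrument used in the survey battery (nationalism and its
    single-item extension, social identification and verbal fusion for nation
    and religion, the supernatural-belief scale and its two extension items,
    the five three-item threat subscales, and the ten Big-Five markers) has an
    entry in ``data/scale_definitions.json``.
    """
    text = resources.files("threatdyn.data").joinpath("scale_definitions.json").read_text()
    raw = json.loads(text)
    out = {}
    for name, d in raw.items():
        out[name] = ScaleDefinition(
            name=name,
            items=tuple(d["items"]),
            response_range=(float(d["range"][0]), float(d["range"][1])),
            reverse=frozenset(d.get("reverse", [])),
        )
    return out


def score_scale(table: pd.DataFrame, definition: ScaleDefinition) -> pd.Series:
    """Mean-score a scale for every respondent.

    Reverse-keyed items contribute ``min + max - x``. A respondent missing any
    item gets a missing score (casewise).
    """
    missing = [c for c in definition.items if c not in table.columns]
    if missing:
        raise SchemaError(missing, f"scale '{definition.name}': {missing} not in table")
    lo, hi = definition.response_range
    block = table.loc[:, list(definition.items)].astype(float).copy()
    for item in definition.reverse:
        block[item] = lo + hi - block[item]
    return block.mean(axis=1, skipna=False).rename(definition.name)


def cronbach_alpha(items: pd.DataFrame | np.ndarray, ci: float = 0.95) -> ReliabilityReport:
    """Cronbach's alpha with the Feldt 95% confidence interval.

    alpha = k/(k-1) * (1 - sum(var_i)/var_total), computed on listwise-complete
    cases with unbiased (ddof=1) variances. The interval uses the Feldt (1965)
    result that (1 - alpha_pop)/(1 - alpha_hat) follows an F distribution with
    (n-1, (n-1)(k-1)) degrees of freedom.
    """
    X = pd.DataFrame(items).astype(float).dropna(axis=0, how="any")
    n, k = X.shape
    if k < 2:
        raise ConfigurationError("cronbach_alpha needs at least 2 items")
    if n < 3:
        raise ConfigurationError("cronbach_alpha needs at least 3 complete cases")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedReliabilityError("total score has zero variance")
    item_var = X.var(ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    gamma = 1.0 - ci
    df1 = n - 1
    df2 = df1 * (k - 1)
    lo = 1 - (1 - alpha) * stats.f.isf(gamma / 2, df1, df2)
    hi = 1 - (1 - alpha) * stats.f.isf(1 - gamma / 2, df1, df2)
    return ReliabilityReport(float(alpha), float(lo), float(hi), k, n)


def alpha_from_mean_correlation(rbar: float, k: int) -> float:
    """Standardised alpha implied by a compound-symmetric inter-item correlation."""
    return k * rbar / (1.0 + (k - 1) * rbar)


def mean_correlation_for_alpha(alpha: float, k: int) -> float:
    """Invert alpha = k*rbar / (1 + (k-1)*rbar) for the inter-item correlation."""
    if not 0 < alpha < 1:
        raise ConfigurationError("target alpha must lie in (0, 1)")
    rbar = alpha / (k - alpha * (k - 1))
    if rbar >= 1:
        raise ConfigurationError(f"alpha={alpha} unattainable with {k} items")
    return rbar


# ---------------------------------------------------------------------------
# Exploratory factor analysis
# ---------------------------------------------------------------------------


@dataclass
class EFAResult:
    """Principal-axis factor solution after varimax rotation."""

    loadings: pd.DataFrame
    uniquenesses: pd.Series
    rmsr: float
    chi_square: float
    df: int
    p_value: float
    n_iter: int
    n_obs: int

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1).rename("communality")


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser-normalised by default).

    Returns the rotated loading matrix and the orthogonal rotation matrix.
    Rotation is orthogonal, so row communalities are preserved.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    if normalize:
        h_safe = np.where(h > 0, h, 1.0)
        L = L / h_safe[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    L = L @ R
    if normalize:
        L = L * h_safe[:, None]
    return L, R


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations from the inverse correlation matrix."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def efa_varimax(items: pd.DataFrame | np.ndarray, n_factors: int,
                max_iter: int = 500, tol: float = 1e-3) -> EFAResult:
    """Principal-axis EFA with varimax rotation.

    Communalities start from squared multiple correlations and are iterated to
    convergence (the default tolerance of 1e-3 on the communality change is
    the conventional stopping rule for principal-axis refinement; tighter
    tolerances stall on weakly identified two-indicator factors).
    The residual summary is the root-mean-square of off-diagonal
    residual correlations; the chi-square is the maximum-likelihood
    discrepancy of the factor model (with Bartlett's correction) at
    ((p-k)^2 - (p+k))/2 degrees of freedom.
    """
    X = pd.DataFrame(items).astype(float).dropna(axis=0, how="any")
    names = list(X.columns)
    n, p = X.shape
    if n_factors >= p:
        raise ConfigurationError("n_factors must be smaller than the number of items")
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(np.linalg.cond(R, p=None) * np.ones(1))):
        raise ConfigurationError("correlation matrix is singular")

    h2 = np.clip(_smc(R), 1e-4, 0.98)
    L = None
    for it in range(1, max_iter + 1):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        order = np.argsort(evals)[::-1][:n_factors]
        lam = np.clip(evals[order], 0, None)
        L = evecs[:, order] * np.sqrt(lam)
        # damped update with a communality cap guards against the oscillation /
        # Heywood drift typical of two-indicator factors
        h2_new = np.clip(0.5 * h2 + 0.5 * (L**2).sum(axis=1), 0, 0.98)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    else:
        raise ConvergenceError(
            f"principal-axis iteration did not converge in {max_iter} iterations",
            n_iter=max_iter,
        )

    L_rot, _ = varimax(L)
    # orient each factor so its largest-magnitude loading is positive
    for j in range(L_rot.shape[1]):
        if L_rot[np.argmax(np.abs(L_rot[:, j])), j] < 0:
            L_rot[:, j] = -L_rot[:, j]

    resid = R - L_rot @ L_rot.T
    off = resid[np.triu_indices(p, k=1)]
    rmsr = float(np.sqrt(np.mean(off**2)))

    uniq = np.clip(1.0 - (L_rot**2).sum(axis=1), 1e-8, None)
    sigma = L_rot @ L_rot.T + np.diag(uniq)
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_r, logdet_r = np.linalg.slogdet(R)
    discrepancy = logdet_s - logdet_r + np.trace(R @ np.linalg.inv(sigma)) - p
    k = n_factors
    correction = n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
    chi2 = float(max(correction * discrepancy, 0.0))
    df = int(((p - k) ** 2 - (p + k)) / 2)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

    cols = [f"F{j + 1}" for j in range(n_factors)]
    return EFAResult(
        loadings=pd.DataFrame(L_rot, index=names, columns=cols),
        uniquenesses=pd.Series(uniq, index=names, name="uniqueness"),
        rmsr=rmsr,
        chi_square=chi2,
        df=df,
        p_value=pval,
        n_iter=it,
        n_obs=n,
    )
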