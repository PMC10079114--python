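"""Sweep-output analyses: engagement regressions, subset moderation, trends.

These reproduce the structure of the published simulation analyses: an OLS of
anti-immigrant sentiment on the five engagement integrals (the sign-pattern
validation), full-parameter regressions refit inside subsets of the output
space (bottom/top nationalism quartiles, low/high religiosity halves) to test
moderation at alpha = .05, and ordinal binned trends (religious attendance
vs. nationalism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import CHANNELS
from .errors import ConfigurationError
from .inference import RegressionTable, binned_trend, correlation_matrix, ols_regression

__all__ = [
    "SubsetSpec",
    "ModerationReport",
    "ENGAGEMENT_TERMS",
    "DEFAULT_SWEEP_TERMS",
    "FINANCIAL_FOCAL_TERMS",
    "MEDIA_FOCAL_TERMS",
    "sweep_regression",
    "engagement_regression",
    "subset_moderation",
    "nationalism_moderation",
    "religiosity_moderation",
    "binned_trend",
    "correlation_matrix",
]

ENGAGEMENT_TERMS = [f"engagement_{c}" for c in CHANNELS]

#: the full-parameter term list of the subset regressions (output-side
#: nationalism is included as in the published tables; the conservativism and
#: religiosity stocks, printed without coefficients there, are excluded)
DEFAULT_SWEEP_TERMS = [
    "tvMediaUse", "threatPctOfMedia", "socialMediaUse", "rel_frequency",
    "initial_concern_social", "initial_concern_financial",
    "initial_concern_contagion", "initial_concern_predation",
    *[f"hazard_intensity_{c}" for c in CHANNELS],
    "habituationRate", "energyDecay",
    "big_5_openness", "big_5_conscientiousness", "big_5_agreeableness",
    *[f"hazard_event_count_{c}" for c in CHANNELS],
    "nationalism_level",
]

#: the financial-hazard term whose effect the nationalism level moderates
FINANCIAL_FOCAL_TERMS = ["hazard_event_count_financial"]
#: the media terms whose effect religiosity moderates
MEDIA_FOCAL_TERMS = ["threatPctOfMedia", "socialMediaUse"]


@dataclass(frozen=True)
class SubsetSpec:
    """A subset of a sweep table defined on one output variable."""

    variable: str
    mode: str  # bottom_quartile | top_quartile | below_value | above_value
    threshold: float | None = None

    def select(self, table: pd.DataFrame) -> pd.DataFrame:
        x = table[self.variable]
        if self.mode == "bottom_quartile":
            return table[x <= x.quantile(0.25)]
        if self.mode == "top_quartile":
            return table[x >= x.quantile(0.75)]
        if self.mode == "below_value":
            return table[x < self.threshold]
        if self.mode == "above_value":
            return table[x >= self.threshold]
        raise ConfigurationError(f"unknown subset mode '{self.mode}'")


@dataclass
class ModerationReport:
    """Focal-term significance compared between two subsets at alpha = .05."""

    focal_terms: list[str]
    coef_a: pd.Series
    coef_b: pd.Series
    p_a: pd.Series
    p_b: pd.Series
    alpha: float
    verdict: str  # a_only | b_only | both | neither
    n_a: int
    n_b: int

    @property
    def significant_a(self) -> pd.Series:
        return self.p_a < self.alpha

    @property
    def significant_b(self) -> pd.Series:
        return self.p_b < self.alpha

    def summary(self) -> str:
        rows = pd.DataFrame({
            "coef_A": self.coef_a, "p_A": self.p_a,
            "coef_B": self.coef_b, "p_B": self.p_b,
        })
        return (
            f"moderation verdict: {self.verdict} "
            f"(alpha = {self.alpha}, nA = {self.n_a}, nB = {self.n_b})\n"
            + rows.to_string(float_format="%.4g")
        )


def sweep_regression(table: pd.DataFrame, outcome: str,
                     terms: list[str]) -> RegressionTable:
    """OLS over sweep outputs — the same engine as the survey regressions."""
    return ols_regression(table, outcome, terms)


def engagement_regression(table: pd.DataFrame,
                          outcome: str = "anti_immigrant_sentiment") -> RegressionTable:
    """Sentiment on the five per-channel engagement integrals."""
    return sweep_regression(table, outcome, ENGAGEMENT_TERMS)


def subset_moderation(table: pd.DataFrame, outcome: str, terms: list[str],
                      subset_a: SubsetSpec, subset_b: SubsetSpec,
                      focal_terms: list[str], alpha: float = 0.05,
                      min_rows: int = 30) -> ModerationReport:
    """Refit the sweep regression inside two disjoint subsets and compare
    focal-term significance at ``alpha``."""
    sub_a = subset_a.select(table)
    sub_b = subset_b.select(table)
    if len(sub_a) < min_rows or len(sub_b) < min_rows:
        raise ConfigurationError(
            f"subset too small for a stable fit (<{min_rows} rows)"
        )
    common = set(sub_a.index) & set(sub_b.index)
    if common:
        raise ConfigurationError("subsets A and B must be disjoint")
    fit_a = sweep_regression(sub_a, outcome, terms)
    fit_b = sweep_regression(sub_b, outcome, terms)
    p_a = fit_a.pvalues[focal_terms]
    p_b = fit_b.pvalues[focal_terms]
    sig_a = bool((p_a < alpha).all())
    sig_b = bool((p_b < alpha).all())
    any_a = bool((p_a < alpha).any())
    any_b = bool((p_b < alpha).any())
    if sig_a and not any_b:
        verdict = "a_only"
    elif sig_b and not any_a:
        verdict = "b_only"
    elif any_a and any_b:
        verdict = "both"
    else:
        verdict = "neither"
    return ModerationReport(
        focal_terms=list(focal_terms),
        coef_a=fit_a.params[focal_terms], coef_b=fit_b.params[focal_terms],
        p_a=p_a, p_b=p_b, alpha=alpha, verdict=verdict,
        n_a=fit_a.n_obs, n_b=fit_b.n_obs,
    )


def nationalism_moderation(table: pd.DataFrame,
                           alpha: float = 0.05) -> ModerationReport:
    """Financial-hazard moderation by simulated nationalism (quartile split)."""
    return subset_moderation(
        table, "anti_immigrant_sentiment", DEFAULT_SWEEP_TERMS,
        SubsetSpec("nationalism_level", "bottom_quartile"),
        SubsetSpec("nationalism_level", "top_quartile"),
        FINANCIAL_FOCAL_TERMS, alpha=alpha,
    )


def religiosity_moderation(table: pd.DataFrame,
                           alpha: float = 0.05) -> ModerationReport:
    """Media-effect moderation by religious attendance (low/high halves)."""
    return subset_moderation(
        table, "anti_immigrant_sentiment", DEFAULT_SWEEP_TERMS,
        SubsetSpec("rel_frequency", "below_value", threshold=4.5),
        SubsetSpec("rel_frequency", "above_value", threshold=4.5),
        MEDIA_FOCAL_TERMS, alpha=alpha,
    )
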