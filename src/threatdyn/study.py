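"""End-to-end survey battery: the full set of analyses for one survey table.

Reliability for every instrument, the Big-Five EFA check, threat regressions
(nationalism, supernatural belief, identification/fusion, personality), the
binary anti-immigrant GLM, religious-identity and gender ANOVAs with Tukey
post-hocs, the two-cluster SEM, and the permutation feature-importance
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .importance import ImportanceRanking, feature_importance
from .inference import (
    AnovaResult,
    RegressionTable,
    anova_oneway,
    correlation_matrix,
    glm_binary,
    ols_regression,
    tukey_hsd,
)
from .psychometrics import ReliabilityReport, cronbach_alpha, default_scale_definitions, efa_varimax
from .sem import SemModel, SemResults

__all__ = ["SurveyAnalysis", "analyze_survey", "THREAT_SCORES"]

THREAT_SCORES = ["threat_predation", "threat_contagion", "threat_financial",
                 "threat_natural", "threat_social"]

#: outcome -> threat-regression label of the per-outcome OLS battery
_OLS_OUTCOMES = {
    "nationalism_full": "nationalism on threats",
    "sbs_extended": "supernatural belief on threats",
    "sid_religious": "religious identification on threats",
    "fusion_religious": "religious fusion on threats",
    "sid_national": "national identification on threats",
    "fusion_national": "national fusion on threats",
    "big5_openness": "openness on threats",
    "big5_conscientiousness": "conscientiousness on threats",
    "big5_extraversion": "extraversion on threats",
    "big5_agreeableness": "agreeableness on threats",
    "big5_neuroticism": "neuroticism on threats",
}


@dataclass
class SurveyAnalysis:
    """Everything the survey battery computes for one table."""

    n_respondents: int
    n_men: int
    n_women: int
    mean_age: float
    reliability: dict[str, ReliabilityReport]
    big5_efa: object
    regressions: dict[str, RegressionTable]
    glm_immigrants: RegressionTable
    anova_universal_force: AnovaResult
    anova_karma: AnovaResult
    anova_threat_gender: AnovaResult
    tukey_threat_gender: pd.DataFrame
    sem: SemResults
    importance: ImportanceRanking
    correlations: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        lines = [
            f"Survey battery: n = {self.n_respondents} "
            f"({self.n_men} men, {self.n_women} women), mean age {self.mean_age:.2f}",
            "reliability:",
        ]
        for name, rep in self.reliability.items():
            lines.append(f"  {name:<20s} {rep}")
        e = self.big5_efa
        lines.append(
            f"Big-Five EFA (5 factors): RMSR = {e.rmsr:.3f}, "
            f"chi2({e.df}) = {e.chi_square:.2f}"
        )
        lines.append(self.anova_universal_force.summary())
        lines.append(self.anova_karma.summary())
        lines.append(self.anova_threat_gender.summary())
        nat = self.regressions["nationalism on threats"]
        lines.append(
            f"nationalism ~ threats: R2 = {nat.r_squared:.3f}, n = {nat.n_obs}"
        )
        fi = self.sem.fit_indices
        lines.append(
            f"SEM: chi2({fi['df']}) = {fi['chi_square']:.1f}, CFI = {fi['cfi']:.3f}, "
            f"RMSEA = {fi['rmsea']:.3f}; "
            f"predation loading = {self.sem.get('=~', 'threat_sp', 'threat_predation'):.3f}"
        )
        lines.append("feature importance (top 3): "
                     + ", ".join(self.importance.features[:3]))
        return "\n".join(lines)


def analyze_survey(table: pd.DataFrame, seed: int = 0,
                   glm_family: str = "logistic") -> SurveyAnalysis:
    """Run the full battery on a survey table."""
    defs = default_scale_definitions()
    reliability = {}
    for name in ["nationalism", "nationalism_ext", "sid_national", "sid_religious",
                 "fusion_national", "fusion_religious", "sbs_original",
                 "sbs_extended", "threat_social", "threat_predation",
                 "threat_contagion", "threat_financial", "threat_natural"]:
        d = defs[name]
        reliability[name] = cronbach_alpha(table[list(d.items)])

    big5_items = [f"b5_{j}" for j in range(1, 11)]
    efa = efa_varimax(table[big5_items], n_factors=5)

    regressions = {}
    for outcome, label in _OLS_OUTCOMES.items():
        regressions[label] = ols_regression(table, outcome, THREAT_SCORES)
    regressions["nationalism on threats + covid"] = ols_regression(
        table, "nationalism_full", THREAT_SCORES + ["covid_way_of_life"]
    )

    glm = glm_binary(table, "wvs_undesirable_immigrants", THREAT_SCORES,
                     family=glm_family)

    anova_uf = anova_oneway(table, "sbs_universal_force", "religious_identity")
    anova_karma = anova_oneway(table, "sbs_karma", "religious_identity")
    anova_gender = anova_oneway(table, "threat_overall", "gender")
    tukey_gender = tukey_hsd(table, "threat_overall", "gender")

    sem = SemModel.from_dataframe(table).fit()
    imp = feature_importance(table, "wvs_undesirable_immigrants", seed=seed)

    corr_cols = [c for c in table.columns
                 if pd.api.types.is_numeric_dtype(table[c])
                 and not c.startswith(("nat_", "sid_nat_", "sid_rel_", "fus_",
                                       "sbs_", "thr_", "b5_"))
                 and c != "respondent_id"]
    corr = correlation_matrix(table, corr_cols)

    return SurveyAnalysis(
        n_respondents=len(table),
        n_men=int((table["gender"] == "man").sum()),
        n_women=int((table["gender"] == "woman").sum()),
        mean_age=float(table["age"].mean()),
        reliability=reliability,
        big5_efa=efa,
        regressions=regressions,
        glm_immigrants=glm,
        anova_universal_force=anova_uf,
        anova_karma=anova_karma,
        anova_threat_gender=anova_gender,
        tukey_threat_gender=tukey_gender,
        sem=sem,
        importance=imp,
        correlations=corr,
    )
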