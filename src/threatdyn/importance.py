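"""Permutation feature importance for the binary anti-immigrant item.

A random-forest classifier is fit on a train split and permutation importance
is computed on a held-out split (>=10 shuffles), so importances measure
generalisable predictive contribution rather than in-sample fit.  Fixed seed
implies an identical ranking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError

__all__ = ["ImportanceRanking", "feature_importance", "DEFAULT_IMPORTANCE_FEATURES"]

#: default predictor set for the anti-immigrant classification
DEFAULT_IMPORTANCE_FEATURES = [
    "nationalism_full", "fusion_religious", "fusion_national",
    "sid_national", "sid_religious", "sbs_extended", "rel_attendance",
    "threat_social", "threat_predation", "threat_contagion",
    "threat_financial", "threat_natural",
    "politics_social", "politics_economic",
    "big5_openness", "big5_conscientiousness", "big5_extraversion",
    "big5_agreeableness", "big5_neuroticism", "age",
]


@dataclass
class ImportanceRanking:
    """Features ordered by mean permutation importance."""

    features: list[str]          # ordered, most important first
    scores: pd.Series            # importance per feature (same order)
    scores_sd: pd.Series
    settings_digest: str
    seed: int
    n_obs: int

    def summary(self) -> str:
        lines = [f"permutation importance (seed {self.seed}, n = {self.n_obs}, "
                 f"settings {self.settings_digest[:12]})"]
        for f in self.features:
            lines.append(f"  {f:<28s} {self.scores[f]: .4f} "
                         f"(+- {self.scores_sd[f]:.4f})")
        return "\n".join(lines)


def feature_importance(table: pd.DataFrame, outcome: str,
                       features: list[str] | None = None,
                       seed: int = 0, n_repeats: int = 10,
                       n_estimators: int = 300,
                       test_size: float = 0.3) -> ImportanceRanking:
    """Rank predictors of a binary outcome by permutation importance."""
    feats = features or [f for f in DEFAULT_IMPORTANCE_FEATURES
                         if f in table.columns]
    data = table.loc[:, [outcome, *feats]].dropna(axis=0, how="any")
    y = data[outcome].astype(int)
    if y.nunique() < 2:
        raise ConfigurationError("outcome has a single class; importance undefined")
    X = data[feats].astype(float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1,
        min_samples_leaf=5,
    )
    clf.fit(X_tr, y_tr)
    imp = permutation_importance(
        clf, X_te, y_te, n_repeats=n_repeats, random_state=seed,
        scoring="roc_auc", n_jobs=1,
    )
    scores = pd.Series(imp.importances_mean, index=feats)
    sds = pd.Series(imp.importances_std, index=feats)
    order = scores.sort_values(ascending=False).index.tolist()
    settings = {
        "model": "RandomForestClassifier",
        "n_estimators": n_estimators, "min_samples_leaf": 5,
        "n_repeats": n_repeats, "scoring": "roc_auc",
        "test_size": test_size, "features": feats,
    }
    digest = hashlib.sha256(
        json.dumps(settings, sort_keys=True).encode()
    ).hexdigest()
    return ImportanceRanking(
        features=order, scores=scores[order], scores_sd=sds[order],
        settings_digest=digest, seed=seed, n_obs=len(data),
    )
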