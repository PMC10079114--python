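"""Synthetic survey generator emulating the deposited respondent-level table.

The generator draws a two-factor latent threat structure (social/predation
vs. contagion/financial/natural clusters) together with the structural
equations that link the clusters to nationalism, political conservativism,
religious identification, supernatural belief and the binary "immigrants as
undesirable neighbours" item.  Around that core it adds the survey's
demographic mixtures (gender, fourteen religious identities, truncated-normal
age), religiosity-driven group differences, Likert item blocks calibrated to
the published reliability of every instrument, and media/personality columns.

Scores vs. items
----------------
Score columns carry the exact latent-model values (clipped to their response
range) so covariance-structure analyses refit the generating model; item
blocks are Likert discretisations calibrated so that Cronbach's alpha of the
*discretised* items hits the target.  Re-averaging items therefore yields the
discretised approximation of the score, not the score column itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SchemaError
from .psychometrics import mean_correlation_for_alpha
from .sem import (
    DEFAULT_MEANS,
    reference_estimates,
    simulate_from_estimates,
    threat_cluster_spec,
)

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate_survey",
    "write_survey",
    "read_survey",
    "survey_schema",
    "latent_r_for_discretised",
    "DEFAULT_GENDER_COUNTS",
    "DEFAULT_RELIGION_COUNTS",
]

# Default demographic mixtures of the emulated sample (counts out of 2,018).
DEFAULT_GENDER_COUNTS = {"man": 1038, "woman": 970, "other": 10}

DEFAULT_RELIGION_COUNTS = {
    "Agnostic": 169,
    "Atheist": 485,
    "Buddhist": 33,
    "Catholic": 481,
    "Church of England/Anglican": 37,
    "Evangelical/Pentecostal/Charismatic": 40,
    "Hindu": 64,
    "Humanist": 70,
    "Jewish": 26,
    "Muslim": 35,
    "None": 174,
    "Other": 39,
    "Protestant (misc.)": 246,
    "Spiritual but not religious": 119,
}

# Group-level religiosity indices in [0, 1] driving attendance / identification
# (``practice``) and supernatural-belief strength (``spirit``).  Chosen once to
# mirror the qualitative group ordering of the survey (atheists lowest, the
# "spiritual but not religious" high on belief but low on attendance).
RELIGIOSITY_PRACTICE = {
    "Agnostic": 0.15, "Atheist": 0.05, "Buddhist": 0.50, "Catholic": 0.70,
    "Church of England/Anglican": 0.65, "Evangelical/Pentecostal/Charismatic": 0.90,
    "Hindu": 0.70, "Humanist": 0.15, "Jewish": 0.55, "Muslim": 0.85,
    "None": 0.10, "Other": 0.40, "Protestant (misc.)": 0.70,
    "Spiritual but not religious": 0.45,
}
RELIGIOSITY_SPIRIT = {
    "Agnostic": 0.35, "Atheist": 0.12, "Buddhist": 0.70, "Catholic": 0.72,
    "Church of England/Anglican": 0.65, "Evangelical/Pentecostal/Charismatic": 0.90,
    "Hindu": 0.75, "Humanist": 0.30, "Jewish": 0.50, "Muslim": 0.85,
    "None": 0.30, "Other": 0.55, "Protestant (misc.)": 0.72,
    "Spiritual but not religious": 0.80,
}

DEFAULT_TARGET_ALPHAS = {
    "nationalism_ext": 0.90,   # the 7-item subset then lands at ~.88
    "sid_national": 0.92,
    "sid_religious": 0.94,
    "fusion_national": 0.95,
    "fusion_religious": 0.96,
    "sbs_extended": 0.98,      # the 10-item subset stays ~.98
    "threat": 0.80,            # per three-item threat dimension (not reported)
}

DEFAULT_ITEM_COUNTS = {
    "nationalism_ext": 8, "sid_national": 4, "sid_religious": 4,
    "fusion_national": 7, "fusion_religious": 7, "sbs_extended": 12,
    "threat": 3, "big5": 10,
}

#: standardised effects generating the binary anti-immigrant item; the
#: ordering (nationalism strongest, religious fusion second) reflects the
#: feature-importance finding the generator is designed to reproduce.
DEFAULT_WVS_EFFECTS = {
    "nationalism_full": 0.16,
    "fusion_religious": 0.11,
    "politics_social": 0.03,
    "politics_economic": 0.015,
}


@dataclass
class GeneratorConfig:
    """Everything the survey generator needs; see :func:`default_config`."""

    n_respondents: int = 2018
    seed: int = 0
    estimates: pd.DataFrame = field(default_factory=reference_estimates)
    spec: dict = field(default_factory=threat_cluster_spec)
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    item_counts: dict = field(default_factory=lambda: dict(DEFAULT_ITEM_COUNTS))
    target_alphas: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_ALPHAS))
    gender_counts: dict = field(default_factory=lambda: dict(DEFAULT_GENDER_COUNTS))
    religion_counts: dict = field(default_factory=lambda: dict(DEFAULT_RELIGION_COUNTS))
    age_mean: float = 39.06
    age_sd: float = 13.00
    wvs_effects: dict = field(default_factory=lambda: dict(DEFAULT_WVS_EFFECTS))
    wvs_base_rate: float = 0.33
    group_effects: bool = True
    gender_threat_shift: dict = field(
        default_factory=lambda: {"man": -0.06, "woman": 0.065, "other": 0.30}
    )

    def validate(self):
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents must be >= 0")
        lat = self.estimates
        phi = np.array([
            [_get(lat, "~~", "threat_sp", "threat_sp"),
             _get(lat, "~~", "threat_sp", "threat_cfn")],
            [_get(lat, "~~", "threat_sp", "threat_cfn"),
             _get(lat, "~~", "threat_cfn", "threat_cfn")],
        ])
        if np.any(np.linalg.eigvalsh(phi) < -1e-12):
            raise ConfigurationError("latent covariance matrix is not PSD")
        for name, a in self.target_alphas.items():
            if not 0 < a < 1:
                raise ConfigurationError(f"target alpha for '{name}' outside (0,1)")
        for g, c in {**self.gender_counts, **self.religion_counts}.items():
            if c < 0:
                raise ConfigurationError(f"negative frequency for category '{g}'")


def _get(est: pd.DataFrame, op, lhs, rhs):
    m = est[(est.op == op) & (est.lhs == lhs) & (est.rhs == rhs)]
    if m.empty and op == "~~":
        m = est[(est.op == op) & (est.lhs == rhs) & (est.rhs == lhs)]
    return float(m.estimate.iloc[0])


def default_config(n_respondents: int = 2018, seed: int = 0, **kw) -> GeneratorConfig:
    cfg = GeneratorConfig(n_respondents=n_respondents, seed=seed, **kw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Likert discretisation
# ---------------------------------------------------------------------------

_ATTEN_CACHE: dict[tuple[float, int], float] = {}


def _discretised_corr(r: float, levels: int) -> float:
    """Pearson correlation of two standard normals after equal-probability
    discretisation into ``levels`` categories scored 1..levels."""
    qs = np.arange(1, levels) / levels
    t = stats.norm.ppf(qs)
    # joint CDF at every threshold pair
    grid = np.array([[a, b] for a in t for b in t])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    cdf = np.asarray(mvn.cdf(grid)).reshape(levels - 1, levels - 1)
    full = np.zeros((levels + 1, levels + 1))
    full[1:levels, 1:levels] = cdf
    full[levels, 1:levels] = stats.norm.cdf(t)
    full[1:levels, levels] = stats.norm.cdf(t)
    full[levels, levels] = 1.0
    # cell probabilities by inclusion-exclusion on the cumulative grid
    p = (full[1:, 1:] - full[:-1, 1:] - full[1:, :-1] + full[:-1, :-1])
    vals = np.arange(1, levels + 1, dtype=float)
    exy = float(vals @ p @ vals)
    mu = (levels + 1) / 2.0
    var = (levels**2 - 1) / 12.0
    return (exy - mu * mu) / var


def latent_r_for_discretised(r_target: float, levels: int) -> float:
    """Latent inter-item correlation whose discretised correlation is r_target.

    Inverted by bisection on the monotone attenuation map; results cached.
    """
    key = (round(r_target, 6), levels)
    if key in _ATTEN_CACHE:
        return _ATTEN_CACHE[key]
    if _discretised_corr(0.9999, levels) < r_target:
        raise ConfigurationError(
            f"target correlation {r_target:.3f} unattainable with {levels} levels"
        )
    lo, hi = r_target, 0.9999
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _discretised_corr(mid, levels) < r_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    out = 0.5 * (lo + hi)
    _ATTEN_CACHE[key] = out
    return out


def _likert_block(score: np.ndarray, n_items: int, alpha: float, levels: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Likert items whose common factor is the standardised score.

    The latent inter-item correlation is attenuation-corrected so that the
    discretised block's Cronbach alpha matches the target.
    """
    n = score.shape[0]
    if n == 0:
        return np.zeros((0, n_items))
    r_disc = mean_correlation_for_alpha(alpha, n_items)
    r_lat = latent_r_for_discretised(r_disc, levels)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    eps = rng.standard_normal((n, n_items))
    x = np.sqrt(r_lat) * z[:, None] + np.sqrt(1.0 - r_lat) * eps
    thresholds = stats.norm.ppf(np.arange(1, levels) / levels)
    return np.searchsorted(thresholds, x) + 1


def _quota(counts: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder quota allocation of categories, then shuffled."""
    labels = list(counts)
    total = sum(counts.values())
    if total <= 0 or n == 0:
        return np.array([], dtype=object)
    exact = np.array([counts[k] * n / total for k in labels])
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    out = np.repeat(np.array(labels, dtype=object), base)
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_THREATS = ("social", "predation", "contagion", "financial", "natural")


def generate_survey(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic survey table (deterministic given the seed)."""
    config.validate()
    n = config.n_respondents
    rng = np.random.default_rng(config.seed)
    est, spec, means = config.estimates, config.spec, config.means

    if n == 0:
        cols = survey_schema()["columns"]
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    # -- demographics -------------------------------------------------------
    gender = _quota(config.gender_counts, n, rng)
    religion = _quota(config.religion_counts, n, rng)
    # truncated normal at 18 whose *truncated* mean equals age_mean: solve for
    # the location so truncation does not inflate the reported mean age
    loc = _truncnorm_loc(config.age_mean, config.age_sd, lower=18.0)
    a = (18.0 - loc) / config.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=config.age_sd,
                              size=n, random_state=rng)
    age = np.round(age).astype(int)

    practice = np.array([RELIGIOSITY_PRACTICE[r] for r in religion])
    spirit = np.array([RELIGIOSITY_SPIRIT[r] for r in religion])

    # -- latent structural core --------------------------------------------
    # exogenous religiosity scores carry the group structure: their group
    # component explains a fixed share of the published variance, the rest is
    # individual noise with the published mutual covariance.
    var_sid = _get(est, "~~", "sid_religious", "sid_religious")
    var_sbs = _get(est, "~~", "sbs_extended", "sbs_extended")
    cov_ss = _get(est, "~~", "sid_religious", "sbs_extended")
    g_prac = practice - practice.mean()
    g_spir = spirit - spirit.mean()
    share_sid, share_sbs = (0.30, 0.38) if config.group_effects else (0.0, 0.0)
    a_sid = np.sqrt(share_sid * var_sid / max(g_prac.var(), 1e-12)) if share_sid else 0.0
    a_sbs = np.sqrt(share_sbs * var_sbs / max(g_spir.var(), 1e-12)) if share_sbs else 0.0
    resid_cov = np.array([
        [var_sid * (1 - share_sid), cov_ss - a_sid * a_sbs * np.cov(g_prac, g_spir)[0, 1]],
        [0.0, var_sbs * (1 - share_sbs)],
    ])
    resid_cov[1, 0] = resid_cov[0, 1]
    if np.any(np.linalg.eigvalsh(resid_cov) < 0):
        raise ConfigurationError("group effect shares leave a non-PSD residual")
    L = np.linalg.cholesky(resid_cov)
    uu = rng.standard_normal((n, 2)) @ L.T
    sid_rel_dev = a_sid * g_prac + uu[:, 0]
    sbs_dev = a_sbs * g_spir + uu[:, 1]

    core = _simulate_core(est, spec, n, rng, sid_rel_dev, sbs_dev)

    # small religious-group shift on nationalism (between-group differences)
    if config.group_effects:
        var_nat = core["nationalism_full"].var()
        shift = np.sqrt(0.05 * var_nat / max(g_prac.var(), 1e-12)) * g_prac
        core["nationalism_full"] = core["nationalism_full"] + shift
    # gender differences in perceived threat
    if config.group_effects:
        gshift = np.array([config.gender_threat_shift[g] for g in gender])
        for t in _THREATS:
            core[f"threat_{t}"] = core[f"threat_{t}"] + gshift

    table = pd.DataFrame({"respondent_id": np.arange(n)})
    table["gender"] = gender
    table["age"] = age
    table["religious_identity"] = religion
    att = practice * 9 + 1.8 * rng.standard_normal(n)
    table["rel_attendance"] = np.clip(np.round(att), 0, 9).astype(int)

    # -- score columns (clipped latent-exact values) ------------------------
    for t in _THREATS:
        table[f"threat_{t}"] = np.clip(core[f"threat_{t}"] + means[f"threat_{t}"], 1, 5)
    table["threat_overall"] = table[[f"threat_{t}" for t in _THREATS]].mean(axis=1)
    nat = np.clip(core["nationalism_full"] + means["nationalism_full"], 1, 7)
    table["nationalism_full"] = nat
    table["politics_social"] = np.clip(core["politics_social"] + means["politics_social"], 0, 10)
    table["politics_economic"] = np.clip(
        core["politics_economic"] + means["politics_economic"], 0, 10
    )
    sid_rel = np.clip(sid_rel_dev + means["sid_religious"], 1, 7)
    sbs_ext = np.clip(sbs_dev + means["sbs_extended"], 1, 9)
    table["sid_religious"] = sid_rel
    table["sbs_extended"] = sbs_ext

    znat = _z(nat)
    table["sid_national"] = np.clip(4.8 + 0.55 * znat + 1.1 * rng.standard_normal(n), 1, 7)
    table["fusion_national"] = np.clip(3.8 + 0.75 * znat + 1.2 * rng.standard_normal(n), 1, 7)
    fus_rel = np.clip(
        4.0 + 0.55 * _z(sbs_ext) + 0.45 * _z(sid_rel) + 1.0 * rng.standard_normal(n), 1, 7
    )
    table["fusion_religious"] = fus_rel

    # Big-Five trait scores with mild threat links (push-pull realism)
    z_sp = _z(core["threat_social"] + core["threat_predation"])
    z_cfn = _z(core["threat_contagion"] + core["threat_financial"] + core["threat_natural"])
    traits = {
        "big5_openness": 3.4 - 0.12 * z_sp + 0.06 * z_cfn,
        "big5_conscientiousness": 3.9 - 0.10 * z_sp - 0.05 * z_cfn,
        "big5_extraversion": 3.2 - 0.03 * z_sp - 0.04 * z_cfn,
        "big5_agreeableness": 3.8 - 0.12 * z_sp - 0.08 * z_cfn,
        "big5_neuroticism": 3.1 - 0.15 * z_sp - 0.06 * z_cfn,
    }
    for name, base in traits.items():
        traits[name] = np.clip(base + 0.75 * rng.standard_normal(n), 1, 5)
        table[name] = traits[name]

    table["covid_way_of_life"] = np.clip(
        np.round(4 + 1.1 * (0.6 * _z(table["threat_contagion"].to_numpy())
                            + 0.3 * _z(table["threat_financial"].to_numpy()))
                 + 1.0 * rng.standard_normal(n)), 1, 7
    ).astype(int)

    table["social_media_use"] = rng.integers(1, 6, n)
    table["tv_media_use"] = rng.integers(1, 5, n)

    # -- binary anti-immigrant item -----------------------------------------
    pred = np.full(n, config.wvs_base_rate)
    feats = {
        "nationalism_full": nat, "fusion_religious": fus_rel,
        "politics_social": table["politics_social"].to_numpy(),
        "politics_economic": table["politics_economic"].to_numpy(),
    }
    for k, b in config.wvs_effects.items():
        pred = pred + b * _z(feats[k])
    p = np.clip(pred, 0.01, 0.99)
    table["wvs_undesirable_immigrants"] = (rng.random(n) < p).astype(int)

    # -- Likert item blocks --------------------------------------------------
    alphas, counts = config.target_alphas, config.item_counts
    blocks = [
        ("nat", nat, counts["nationalism_ext"], alphas["nationalism_ext"], 7),
        ("sid_nat", table["sid_national"].to_numpy(), counts["sid_national"],
         alphas["sid_national"], 7),
        ("sid_rel", sid_rel, counts["sid_religious"], alphas["sid_religious"], 7),
        ("fus_nat", table["fusion_national"].to_numpy(), counts["fusion_national"],
         alphas["fusion_national"], 7),
        ("fus_rel", fus_rel, counts["fusion_religious"], alphas["fusion_religious"], 7),
    ]
    for prefix, score, k, a, lv in blocks:
        items = _likert_block(score, k, a, lv, rng)
        for j in range(k):
            table[f"{prefix}_{j + 1}"] = items[:, j]
    sbs_items = _likert_block(sbs_ext, counts["sbs_extended"], alphas["sbs_extended"], 9, rng)
    for j in range(10):
        table[f"sbs_{j + 1}"] = sbs_items[:, j]
    table["sbs_karma"] = sbs_items[:, 10]
    table["sbs_universal_force"] = sbs_items[:, 11]
    for t in _THREATS:
        items = _likert_block(table[f"threat_{t}"].to_numpy(), counts["threat"],
                              alphas["threat"], 5, rng)
        for j in range(counts["threat"]):
            table[f"thr_{t}_{j + 1}"] = items[:, j]

    # item-mean versions of the scores that have an "original" sub-scale
    table["nationalism"] = table[[f"nat_{j}" for j in range(1, 8)]].mean(axis=1)
    table["sbs_original"] = table[[f"sbs_{j}" for j in range(1, 11)]].mean(axis=1)

    # Big-Five items: two markers per trait, pairwise latent r = 0.55
    b5_map = {1: "big5_openness", 2: "big5_conscientiousness", 3: "big5_extraversion",
              4: "big5_agreeableness", 5: "big5_neuroticism"}
    for j, trait in b5_map.items():
        pair = _likert_block(traits[trait], 2, 0.55 * 2 / (1 + 0.55), 5, rng)
        table[f"b5_{j}"] = pair[:, 0]
        table[f"b5_{j + 5}"] = pair[:, 1]

    # passthrough fields (not analysed)
    covid_status = _quota(
        {"tested_negative": 35, "symptoms_untested": 12, "currently_positive": 3,
         "recovered": 10, "none": 40}, n, rng,
    )
    table["covid_status"] = covid_status
    voted = rng.random(n) < 0.12
    leave = rng.random(n) < 0.5
    brexit = np.full(n, np.nan, dtype=object)
    brexit[voted & leave] = "leave"
    brexit[voted & ~leave] = "remain"
    table["brexit_vote"] = brexit

    return table


def _simulate_core(est, spec, n, rng, sid_rel_dev, sbs_dev) -> dict[str, np.ndarray]:
    """Structural-core draw with the exogenous religiosity deviations injected."""
    df = simulate_from_estimates(est, spec, n, rng, means=None)
    # replace the exogenous draws: re-solve the two downstream political
    # sliders and the binary item would be circular; instead regenerate via the
    # reduced form with substituted exogenous residuals.
    from .sem import _build_matrices_from_estimates

    A, S, observed, model_vars = _build_matrices_from_estimates(est, spec)
    m = len(model_vars)
    evals, evecs = np.linalg.eigh(S)
    evals = np.clip(evals, 0, None)
    L = evecs * np.sqrt(evals)
    e = rng.standard_normal((n, m)) @ L.T
    idx = {v: i for i, v in enumerate(model_vars)}
    e[:, idx["sid_religious"]] = sid_rel_dev
    e[:, idx["sbs_extended"]] = sbs_dev
    v = np.linalg.solve(np.eye(m) - A, e.T).T
    return {name: v[:, idx[name]] for name in observed}


def _truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location of a lower-truncated normal whose truncated mean is target_mean."""
    from scipy.optimize import brentq

    def f(loc):
        a = (lower - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - target_mean

    return float(brentq(f, target_mean - 5 * sd, target_mean + sd))


def _z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def survey_schema() -> dict:
    """The documented column schema (shipped as JSON with the package)."""
    text = resources.files("threatdyn.data").joinpath("survey_schema.json").read_text()
    return json.loads(text)


def write_survey(table: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a survey table as CSV (RFC-4180, UTF-8, header) or XLSX."""
    path = str(path)
    fmt = fmt or ("xlsx" if path.endswith(".xlsx") else "csv")
    if fmt == "csv":
        # %.17g guarantees float64 round-trip to the exact same bits
        table.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "xlsx":
        table.to_excel(path, index=False)
    else:
        raise ConfigurationError(f"unknown survey format '{fmt}'")


def read_survey(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a survey table, validating required columns and category labels.

    Missing required columns raise :class:`SchemaError` listing the names;
    unknown category labels raise a warning but the rows are retained.
    """
    path = str(path)
    fmt = fmt or ("xlsx" if path.endswith(".xlsx") else "csv")
    if fmt == "csv":
        # keep_default_na=False: the religious-identity label "None" is a
        # real category, not missing data; only empty cells are missing
        table = pd.read_csv(path, keep_default_na=False, na_values=[""],
                            float_precision="round_trip")
    elif fmt == "xlsx":
        table = pd.read_excel(path)
    else:
        raise ConfigurationError(f"unknown survey format '{fmt}'")
    schema = survey_schema()
    missing = [c for c in schema["required"] if c not in table.columns]
    if missing:
        raise SchemaError(missing)
    for col, allowed in schema.get("categories", {}).items():
        if col in table.columns:
            bad = sorted(set(table[col].dropna().astype(str)) - set(allowed) - {""})
            if bad:
                warnings.warn(
                    f"column '{col}' has unknown category labels {bad}; rows retained",
                    UserWarning, stacklevel=2,
                )
    return table
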