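"""Generator contracts: determinism, moment recovery, alphas, demographics, I/O."""

import json

import numpy as np
import pandas as pd
import pytest

from threatdyn.errors import ConfigurationError, SchemaError
from threatdyn.psychometrics import cronbach_alpha, default_scale_definitions
from threatdyn.sem import reference_estimates
from threatdyn.synthetic import (
    DEFAULT_GENDER_COUNTS,
    DEFAULT_RELIGION_COUNTS,
    GeneratorConfig,
    default_config,
    generate_survey,
    latent_r_for_discretised,
    read_survey,
    survey_schema,
    write_survey,
)


class TestGeneration:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = generate_survey(default_config(n_respondents=120, seed=9))
        b = generate_survey(default_config(n_respondents=120, seed=9))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_survey(a, pa)
        write_survey(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a = generate_survey(default_config(n_respondents=60, seed=1))
        b = generate_survey(default_config(n_respondents=60, seed=2))
        assert not a.equals(b)

    def test_empty_table_has_full_header(self):
        t = generate_survey(default_config(n_respondents=0, seed=0))
        assert len(t) == 0
        for col in survey_schema()["columns"]:
            assert col in t.columns

    def test_ranges_and_invariants(self, full_survey):
        t = full_survey
        schema = survey_schema()
        assert (t["age"] >= 18).all()
        assert set(t["wvs_undesirable_immigrants"].unique()) <= {0, 1}
        for col, (lo, hi) in schema["ranges"].items():
            if hi is None:
                continue
            assert t[col].min() >= lo and t[col].max() <= hi, col

    def test_quota_category_counts_exact_at_default_n(self, full_survey):
        gc = full_survey["gender"].value_counts()
        for k, v in DEFAULT_GENDER_COUNTS.items():
            assert gc[k] == v
        rc = full_survey["religious_identity"].value_counts()
        for k, v in DEFAULT_RELIGION_COUNTS.items():
            assert rc[k] == v

    def test_category_proportions_scale_with_n(self):
        t = generate_survey(default_config(n_respondents=1009, seed=4))
        frac = (t["gender"] == "man").mean()
        assert frac == pytest.approx(1038 / 2018, abs=0.001)

    def test_mean_age_matches_target(self, full_survey):
        assert full_survey["age"].mean() == pytest.approx(39.06, abs=1.0)

    def test_non_psd_latent_cov_rejected(self):
        est = reference_estimates()
        bad = est.copy()
        bad.loc[(bad.lhs == "threat_sp") & (bad.rhs == "threat_cfn")
                & (bad.op == "~~"), "estimate"] = 5.0  # |cov| > sqrt(v1*v2)
        with pytest.raises(ConfigurationError):
            default_config(estimates=bad).validate()

    def test_bad_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg = GeneratorConfig(target_alphas={"nationalism_ext": 1.5})
            cfg.validate()


class TestMomentRecovery:
    def test_threat_covariance_matches_lambda_phi_lambda(self):
        """Sample covariance of the five threat scores converges to
        Lambda Phi Lambda' + Theta computed directly from the estimates
        (checked on the unclipped latent generator; the bounded survey table
        attenuates variances slightly at the range edges)."""
        from threatdyn.sem import simulate_from_estimates, threat_cluster_spec

        est = reference_estimates()
        t = simulate_from_estimates(est, threat_cluster_spec(), 60000,
                                    np.random.default_rng(5))

        def g(op, l, r):
            m = est[(est.op == op) & (est.lhs == l) & (est.rhs == r)]
            return float(m.estimate.iloc[0])

        lam = np.array([
            [1.00, 0.0], [g("=~", "threat_sp", "threat_predation"), 0.0],
            [0.0, 1.00], [0.0, g("=~", "threat_cfn", "threat_contagion")],
            [0.0, g("=~", "threat_cfn", "threat_natural")],
        ])
        phi = np.array([[0.30, 0.13], [0.13, 0.19]])
        theta = np.diag([0.38, 0.67, 0.87, 0.68, 0.71])
        expected = lam @ phi @ lam.T + theta
        cols = ["threat_social", "threat_predation", "threat_financial",
                "threat_contagion", "threat_natural"]
        observed = t[cols].cov().to_numpy()
        assert np.allclose(observed, expected, atol=0.03)

    def test_alpha_recovery_within_003(self):
        t = generate_survey(default_config(n_respondents=5000, seed=6))
        defs = default_scale_definitions()
        targets = {
            "nationalism_ext": 0.90, "sid_national": 0.92, "sid_religious": 0.94,
            "fusion_national": 0.95, "fusion_religious": 0.96,
            "sbs_extended": 0.98, "threat_contagion": 0.80,
        }
        for name, target in targets.items():
            rep = cronbach_alpha(t[list(defs[name].items)])
            assert rep.alpha == pytest.approx(target, abs=0.03), name

    def test_seven_item_nationalism_lands_near_088(self):
        t = generate_survey(default_config(n_respondents=5000, seed=6))
        d = default_scale_definitions()["nationalism"]
        assert cronbach_alpha(t[list(d.items)]).alpha == pytest.approx(0.88, abs=0.03)


class TestDiscretisation:
    def test_attenuation_inversion_roundtrip(self):
        """Discretising at the inflated latent r recovers the target r."""
        rng = np.random.default_rng(0)
        r_target = 0.55
        r_lat = latent_r_for_discretised(r_target, 5)
        assert r_lat > r_target
        n = 200_000
        z = rng.standard_normal(n)
        x = np.sqrt(r_lat) * z + np.sqrt(1 - r_lat) * rng.standard_normal(n)
        y = np.sqrt(r_lat) * z + np.sqrt(1 - r_lat) * rng.standard_normal(n)
        from scipy import stats

        t = stats.norm.ppf(np.arange(1, 5) / 5)
        xd = np.searchsorted(t, x) + 1
        yd = np.searchsorted(t, y) + 1
        assert np.corrcoef(xd, yd)[0, 1] == pytest.approx(r_target, abs=0.01)

    def test_unattainable_target_raises(self):
        with pytest.raises(ConfigurationError):
            latent_r_for_discretised(0.999, 2)


class TestIO:
    def test_csv_roundtrip_identity(self, tmp_path):
        t = generate_survey(default_config(n_respondents=10, seed=3))
        p = tmp_path / "t.csv"
        write_survey(t, p)
        back = read_survey(p)
        pd.testing.assert_frame_equal(
            back, t, check_dtype=False, check_exact=True
        )

    def test_xlsx_roundtrip(self, tmp_path):
        t = generate_survey(default_config(n_respondents=10, seed=3))
        p = tmp_path / "t.xlsx"
        write_survey(t, p)
        back = read_survey(p)
        num = t.select_dtypes("number").columns
        assert np.allclose(back[num].fillna(-1), t[num].fillna(-1))

    def test_missing_required_column_raises_with_names(self, tmp_path):
        t = generate_survey(default_config(n_respondents=5, seed=3))
        p = tmp_path / "t.csv"
        write_survey(t.drop(columns=["wvs_undesirable_immigrants"]), p)
        with pytest.raises(SchemaError) as err:
            read_survey(p)
        assert "wvs_undesirable_immigrants" in err.value.missing

    def test_unknown_category_warns_but_keeps_rows(self, tmp_path):
        t = generate_survey(default_config(n_respondents=5, seed=3))
        t.loc[0, "religious_identity"] = "Jedi"
        p = tmp_path / "t.csv"
        write_survey(t, p)
        with pytest.warns(UserWarning, match="Jedi"):
            back = read_survey(p)
        assert len(back) == 5

    def test_schema_file_is_valid_json(self):
        schema = survey_schema()
        assert {"required", "columns", "categories", "ranges"} <= set(schema)
        json.dumps(schema)  # serialisable
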