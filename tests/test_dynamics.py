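"""Simulator oracles: Rescorla-Wagner fixed points, analytic decay, stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threatdyn.dynamics import (
    CHANNELS,
    STOCKS,
    CouplingConstants,
    SDParameters,
    SDState,
    ThreatDynamicsModel,
    apply_hazard_event,
    decay_step,
    run_simulation,
    simulate_batch,
)
from threatdyn.errors import ConfigurationError


def _no_events(**kw):
    base = {f"hazard_event_count_{c}": 0 for c in CHANNELS}
    base.update(kw)
    return SDParameters(**base)


def _param_arrays(p: SDParameters):
    return {k: np.asarray([v], dtype=float) for k, v in p.to_dict().items()}


class TestRescorlaWagner:
    def test_fixed_point_no_change(self):
        p = SDParameters(hazard_intensity_social=2.0, tvMediaUse=0,
                         socialMediaUse=0, threatPctOfMedia=0)
        P = _param_arrays(p)
        state = SDState.initial(P, 1)
        state.concern["social"][:] = 2.0  # C == lambda*
        apply_hazard_event(state, "social", P, CouplingConstants())
        assert state.concern["social"][0] == pytest.approx(2.0, abs=1e-15)

    def test_geometric_convergence_without_habituation(self):
        """With h = 0 repeated events close the gap geometrically at 1-alpha0."""
        p = SDParameters(hazard_intensity_social=3.0, habituationRate=0.0,
                         base_learning_rate=0.4, tvMediaUse=0, socialMediaUse=0,
                         threatPctOfMedia=0)
        P = _param_arrays(p)
        state = SDState.initial(P, 1)
        const = CouplingConstants()
        gaps = [3.0 - state.concern["social"][0]]
        for _ in range(6):
            apply_hazard_event(state, "social", P, const)
            gaps.append(3.0 - state.concern["social"][0])
        ratios = np.diff(np.log(gaps))
        assert np.allclose(np.exp(ratios), 0.6, atol=1e-12)
        assert np.all(np.diff(gaps) < 0)  # monotone approach

    def test_strong_habituation_second_event_negligible(self):
        p = SDParameters(hazard_intensity_social=3.0, habituationRate=50.0,
                         tvMediaUse=0, socialMediaUse=0, threatPctOfMedia=0)
        P = _param_arrays(p)
        state = SDState.initial(P, 1)
        const = CouplingConstants()
        apply_hazard_event(state, "social", P, const)
        first = state.concern["social"][0]
        apply_hazard_event(state, "social", P, const)
        assert state.concern["social"][0] - first < 1e-15

    def test_media_amplifies_stimulus(self):
        const = CouplingConstants()
        p = SDParameters(hazard_intensity_social=2.0, tvMediaUse=1.0,
                         socialMediaUse=1.0, threatPctOfMedia=1.0)
        P = _param_arrays(p)
        state = SDState.initial(P, 1)
        apply_hazard_event(state, "social", P, const)
        lam_star = 2.0 * (1 + const.w_tv + const.w_sm)
        assert state.concern["social"][0] == pytest.approx(
            p.base_learning_rate * lam_star
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(h=st.floats(0, 3), a0=st.floats(0.05, 1.0), lam=st.floats(0.1, 5.0))
    def test_event_increments_non_increasing(self, h, a0, lam):
        """Habituation property: repeated-stimulus increments never grow."""
        p = SDParameters(hazard_intensity_social=lam, habituationRate=h,
                         base_learning_rate=a0, tvMediaUse=0, socialMediaUse=0,
                         threatPctOfMedia=0)
        P = _param_arrays(p)
        state = SDState.initial(P, 1)
        const = CouplingConstants()
        increments = []
        prev = 0.0
        for _ in range(8):
            apply_hazard_event(state, "social", P, const)
            cur = state.concern["social"][0]
            increments.append(cur - prev)
            prev = cur
        assert all(b <= a + 1e-12 for a, b in zip(increments, increments[1:]))


class TestDecay:
    def test_analytic_exponential_decay_everywhere(self):
        p = _no_events(initial_concern_contagion=2.0, energyDecay=0.35)
        model = ThreatDynamicsModel(p)
        res = model.run(record_trajectory=True)
        traj = res.trajectory
        expected = 2.0 * np.exp(-0.35 * traj["t"].to_numpy())
        assert np.max(np.abs(traj["concern_contagion"].to_numpy() - expected)) < 1e-10

    def test_zero_decay_keeps_concern_and_linear_integral(self):
        p = _no_events(initial_concern_social=1.5, energyDecay=0.0)
        r = run_simulation(p)
        assert r["final_concern_social"] == pytest.approx(1.5, abs=1e-12)
        assert r["engagement_social"] == pytest.approx(1.5 * p.horizon, rel=1e-12)

    def test_zero_stimulus_integral_exact(self):
        p = _no_events(initial_concern_predation=1.3, energyDecay=0.3)
        r = run_simulation(p)
        exact = 1.3 * (1 - np.exp(-0.3 * p.horizon)) / 0.3
        assert r["engagement_predation"] == pytest.approx(exact, abs=1e-12)

    def test_decay_step_operator_matches_closed_form(self):
        p = _no_events(initial_concern_social=2.0, energyDecay=0.5)
        P = _param_arrays(p)
        state = SDState.initial(P, 1)
        decay_step(state, P, 0.25)
        assert state.concern["social"][0] == pytest.approx(
            2.0 * np.exp(-0.5 * 0.25), abs=1e-14
        )


class TestRunSimulation:
    def test_null_run_all_zero(self):
        p = _no_events(rel_frequency=0, big_5_openness=0,
                       big_5_conscientiousness=0, big_5_agreeableness=0,
                       tvMediaUse=0, socialMediaUse=0, threatPctOfMedia=0)
        r = run_simulation(p)
        for ch in CHANNELS:
            assert r[f"engagement_{ch}"] == 0.0
        for s in STOCKS:
            assert r[s] == pytest.approx(0.0, abs=1e-12)

    def test_single_event_closed_form(self):
        """One event at t = T: final concern is alpha0 * lambda* (no decay after)."""
        p = _no_events(hazard_event_count_social=1, hazard_intensity_social=2.0,
                       energyDecay=0.25, tvMediaUse=0, socialMediaUse=0,
                       threatPctOfMedia=0)
        r = run_simulation(p)
        assert r["final_concern_social"] == pytest.approx(0.5 * 2.0, abs=1e-12)

    def test_bit_level_determinism(self):
        p = SDParameters(hazard_intensity_contagion=2.2, habituationRate=0.3)
        a = run_simulation(p)
        b = run_simulation(p)
        assert (a == b).all()

    def test_scalar_equals_batch_row(self):
        p = SDParameters(hazard_event_count_social=4, hazard_intensity_social=2.3,
                         energyDecay=0.2, habituationRate=0.4)
        single = run_simulation(p)
        batch = simulate_batch(pd.DataFrame([p.to_dict()])).iloc[0]
        assert (single == batch).all()

    def test_dt_must_divide_horizon(self):
        with pytest.raises(ConfigurationError):
            run_simulation(SDParameters(horizon=1.0, dt=0.3))

    def test_dt_halving_stability_under_one_percent(self):
        rng = np.random.default_rng(11)
        n = 60
        df = pd.DataFrame({
            **{f"hazard_intensity_{c}": rng.uniform(0, 5, n) for c in CHANNELS},
            **{f"hazard_event_count_{c}": rng.integers(0, 21, n) for c in CHANNELS},
            **{f"initial_concern_{c}": rng.uniform(0, 1, n) for c in CHANNELS},
            "tvMediaUse": rng.uniform(0, 1, n),
            "socialMediaUse": rng.uniform(0, 1, n),
            "threatPctOfMedia": rng.uniform(0, 1, n),
            "rel_frequency": rng.integers(0, 10, n),
            "habituationRate": rng.uniform(0, 1, n),
            "energyDecay": rng.uniform(0, 0.3, n),
            "big_5_openness": rng.uniform(0, 1, n),
            "big_5_conscientiousness": rng.uniform(0, 1, n),
            "big_5_agreeableness": rng.uniform(0, 1, n),
        })
        a = simulate_batch(df.assign(dt=0.1))
        b = simulate_batch(df.assign(dt=0.05))
        cols = [c for c in a.columns
                if c.startswith(("engagement_", "final_", "mean_")) or c in STOCKS]
        for c in cols:
            scale = np.abs(a[c]).mean()
            rel = np.abs(a[c] - b[c]) / np.maximum(np.abs(a[c]), scale)
            assert rel.max() < 0.01, c


class TestCouplings:
    def test_sp_engagement_raises_nationalism(self):
        p = _no_events(initial_concern_social=1.0, initial_concern_predation=1.0,
                       energyDecay=0.0, tvMediaUse=0, socialMediaUse=0,
                       threatPctOfMedia=0, big_5_openness=0,
                       big_5_conscientiousness=0, big_5_agreeableness=0)
        model = ThreatDynamicsModel(p)
        res = model.run(record_trajectory=True)
        n_traj = res.trajectory["nationalism_level"].to_numpy()
        assert res.record["nationalism_level"] > 0
        assert np.all(np.diff(n_traj) > -1e-12)  # nondecreasing toward equilibrium

    def test_cfn_engagement_lowers_nationalism(self):
        p = _no_events(initial_concern_contagion=1.0, initial_concern_financial=1.0,
                       initial_concern_natural=1.0, energyDecay=0.0)
        assert run_simulation(p)["nationalism_level"] < 0

    def test_attendance_raises_equilibrium_nationalism(self):
        lo = run_simulation(_no_events(rel_frequency=0))
        hi = run_simulation(_no_events(rel_frequency=9))
        assert hi["nationalism_level"] > lo["nationalism_level"]

    def test_engagement_integrals_nondecreasing_and_k_bounded(self):
        p = SDParameters(hazard_event_count_social=7)
        model = ThreatDynamicsModel(p)
        res = model.run(record_trajectory=True)
        assert res.record["engagement_social"] >= 0
        # delivered events never exceed the configured count
        assert res.record[f"final_concern_social"] >= 0

    def test_openness_suppresses_belief_stock(self):
        low = run_simulation(_no_events(big_5_openness=0.0))
        high = run_simulation(_no_events(big_5_openness=1.0))
        assert high["anthropomorphic_promiscuity"] < low["anthropomorphic_promiscuity"]
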