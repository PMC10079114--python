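"""Deterministic system-dynamics model of five-channel threat perception.

Five concern stocks (social, predation, contagion, financial, natural) are
driven by discrete hazard events through a Rescorla-Wagner update whose
learning rate habituates across repeated events, and decay exponentially
between events.  The channels aggregate into two engagement variables that
mirror the latent clusters of the survey model — social/predation versus
contagion/financial/natural — which drive nationalism, social and economic
conservativism, two religiosity stocks (anthropomorphic promiscuity and
sociographic prudery) and anti-immigrant sentiment.

Event update (channel i, k-th event):
    lambda* = hazard_intensity_i * (1 + threatPctOfMedia * (w_tv*tvMediaUse
                                                           + w_sm*socialMediaUse))
    alpha   = alpha0 * exp(-habituationRate * k)
    C_i    <- C_i + alpha * (lambda* - C_i)

Between events each stock decays exactly: C_i(t+dt) = C_i(t) * exp(-delta*dt),
and the running engagement integral of each channel accrues the analytic
segment integral C_i(t) * (1 - exp(-delta*dt)) / delta.

Coupled stocks follow first-order relaxation dx/dt = input - rho*x, advanced
with the exact exponential-integrator step for piecewise-constant input.
All state is vectorised over runs, so a parameter sweep is a single batched
integration; a single run is the batch of size one, which guarantees
bit-identical results between the two paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrationError

__all__ = [
    "CHANNELS",
    "STOCKS",
    "SDParameters",
    "CouplingConstants",
    "SDState",
    "apply_hazard_event",
    "decay_step",
    "update_couplings",
    "run_simulation",
    "simulate_batch",
    "ThreatDynamicsModel",
    "SimulationResult",
]

CHANNELS = ("social", "predation", "contagion", "financial", "natural")
STOCKS = (
    "nationalism_level",
    "social_conservativism",
    "economic_conservativism",
    "anthropomorphic_promiscuity",
    "sociographic_prudery",
    "anti_immigrant_sentiment",
)


@dataclass
class SDParameters:
    """One parameter set; keys mirror the sweep's published row labels."""

    tvMediaUse: float = 0.5
    socialMediaUse: float = 0.5
    threatPctOfMedia: float = 0.5
    rel_frequency: int = 0  # attendance ordinal 0 (never) .. 9 (daily)
    habituationRate: float = 0.2
    energyDecay: float = 0.2
    base_learning_rate: float = 0.5
    big_5_openness: float = 0.5
    big_5_conscientiousness: float = 0.5
    big_5_agreeableness: float = 0.5
    big_5_extraversion: float = 0.5  # carried but uncoupled
    big_5_neuroticism: float = 0.5   # carried but uncoupled
    initial_concern_social: float = 0.0
    initial_concern_predation: float = 0.0
    initial_concern_contagion: float = 0.0
    initial_concern_financial: float = 0.0
    initial_concern_natural: float = 0.0
    hazard_intensity_social: float = 1.0
    hazard_intensity_predation: float = 1.0
    hazard_intensity_contagion: float = 1.0
    hazard_intensity_financial: float = 1.0
    hazard_intensity_natural: float = 1.0
    hazard_event_count_social: int = 5
    hazard_event_count_predation: int = 5
    hazard_event_count_contagion: int = 5
    hazard_event_count_financial: int = 5
    hazard_event_count_natural: int = 5
    horizon: float = 20.0
    dt: float = 0.1

    def validate(self):
        if self.dt <= 0 or self.horizon <= 0:
            raise ConfigurationError("horizon and dt must be positive")
        n_steps = self.horizon / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigurationError("dt must divide the horizon")
        if not 0 < self.base_learning_rate <= 1:
            raise ConfigurationError("base_learning_rate must be in (0, 1]")
        for name in ("habituationRate", "energyDecay"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for ch in CHANNELS:
            if getattr(self, f"hazard_intensity_{ch}") < 0:
                raise ConfigurationError("hazard intensities must be >= 0")
            if getattr(self, f"initial_concern_{ch}") < 0:
                raise ConfigurationError("initial concerns must be >= 0")
            if getattr(self, f"hazard_event_count_{ch}") < 0:
                raise ConfigurationError("event counts must be >= 0")
        if not 0 <= self.rel_frequency <= 9:
            raise ConfigurationError("rel_frequency must be an ordinal in 0..9")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SDParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulator parameters: {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p


@dataclass(frozen=True)
class CouplingConstants:
    """Gains wiring engagements into the socio-political stocks.

    Signs are structural (they encode the survey model's cluster signs and
    the sweep's published sign patterns); magnitudes are configuration with
    defaults calibrated so a broad uniform sweep reproduces those patterns.
    """

    # media weighting inside the stimulus amplifier
    w_tv: float = 0.25
    w_sm: float = 0.25
    # nationalism
    a_sp: float = 0.5          # + social/predation engagement -> N
    a_cfn: float = 0.5         # - contagion/financial/natural engagement -> N
    k_rel_nat: float = 0.15    # + religiosity -> N
    # anthropomorphic promiscuity (god-hunting religiosity stock)
    k_ap_base: float = 0.0     # optional baseline propensity toward agent
    #                            detection (default 0 so the null run is null)
    k_ap: float = 0.4
    k_ap_open: float = 0.8     # applied negatively: openness suppresses AP
    # sociographic prudery (norm-guarding religiosity stock)
    k_sgp_rel: float = 0.8
    k_sgp_sp: float = 0.4
    # social / economic conservativism
    c_soc_sp: float = 0.5
    c_soc_cfn: float = 0.5
    c_nat_soc: float = 0.25    # applied negatively: nationalism -> social cons.
    b_sbs_soc: float = 0.12    # + belief stock (AP) -> social cons.
    c_eco_sp: float = 0.3
    c_eco_cfn: float = 0.3
    c_nat_eco: float = 0.15
    b_sbs_eco: float = 0.06
    # anti-immigrant sentiment
    b_wvs_polsoc: float = 0.35
    b_wvs_nat: float = 1.6
    b_wvs_rel: float = 0.4
    b_wvs_open: float = 0.8    # positive (outweighs the negative cascade
    #                            openness -> AP -> social conservativism)
    b_wvs_consc: float = 0.1   # applied negatively
    b_wvs_agree: float = 0.3   # applied negatively
    # susceptibility channels: conscientious (order-valuing) societies
    # translate threat-driven politics into exclusionary sentiment more
    # readily (multiplier susc_base + susc_consc*conscientiousness on the
    # engagement-driven input), while openness blunts the gated negative
    # pathways (multiplier susc_open_base - susc_open*openness)
    susc_base: float = 0.5
    susc_consc: float = 1.6
    susc_open_base: float = 1.3
    susc_open: float = 1.0
    # gated pathways
    g_fin_gate: float = 0.8    # financial shock -> AIS, shut off at high N
    m_media: float = 2.0       # media exposure -> AIS, shut off at high religiosity
    w_tv_ais: float = 0.3
    w_sm_ais: float = 0.7
    gate_n_mid: float = 0.3    # nationalism gate midpoint (stock units)
    gate_n_steep: float = 0.05
    gate_rel_mid: float = 0.5  # religiosity gate midpoint (normalised attendance)
    gate_rel_steep: float = 0.01
    # relaxation rates
    rho: float = 0.25          # socio-political stocks
    rho_ais: float = 1.0       # sentiment reacts on a faster timescale
    rho_shock: float = 0.5     # financial shock stock

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingConstants":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown coupling constants: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SDState:
    """Simulation state; every field is an array over the run dimension."""

    t: float
    concern: dict[str, np.ndarray]        # C_i per channel
    events_done: dict[str, np.ndarray]    # k_i per channel (int)
    engagement: dict[str, np.ndarray]     # integral of C_i dt per channel
    stocks: dict[str, np.ndarray]         # coupled stocks
    stock_integrals: dict[str, np.ndarray]
    fin_shock: np.ndarray                 # gated financial shock stock
    step_avg: dict[str, np.ndarray] | None = None  # set by the integrator

    @classmethod
    def initial(cls, P: dict[str, np.ndarray], n: int) -> "SDState":
        return cls(
            t=0.0,
            concern={ch: P[f"initial_concern_{ch}"].astype(float).copy()
                     for ch in CHANNELS},
            events_done={ch: np.zeros(n, dtype=int) for ch in CHANNELS},
            engagement={ch: np.zeros(n) for ch in CHANNELS},
            stocks={s: np.zeros(n) for s in STOCKS},
            stock_integrals={s: np.zeros(n) for s in STOCKS},
            fin_shock=np.zeros(n),
        )


def _media_amplifier(P: dict, const: CouplingConstants) -> np.ndarray:
    return 1.0 + P["threatPctOfMedia"] * (
        const.w_tv * P["tvMediaUse"] + const.w_sm * P["socialMediaUse"]
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def apply_hazard_event(state: SDState, channel: str, P: dict,
                       const: CouplingConstants,
                       mask: np.ndarray | None = None) -> SDState:
    """Deliver one hazard event on ``channel`` (Rescorla-Wagner with habituation).

    The effective stimulus asymptote is the channel's hazard intensity
    amplified by threat-focused media exposure; the learning rate decays
    geometrically in the number of events already delivered.
    """
    C = state.concern[channel]
    k = state.events_done[channel]
    lam = P[f"hazard_intensity_{channel}"] * _media_amplifier(P, const)
    alpha = P["base_learning_rate"] * np.exp(-P["habituationRate"] * k)
    delta = alpha * (lam - C)
    if mask is None:
        mask = np.ones_like(C, dtype=bool)
    state.concern[channel] = np.where(mask, C + delta, C)
    state.events_done[channel] = k + mask.astype(int)
    if channel == "financial":
        # financial pressure accumulates habituation-free and unamplified:
        # each economic shock bites regardless of attentional habituation or
        # media framing of its coverage
        state.fin_shock = state.fin_shock + np.where(
            mask, P["base_learning_rate"], 0.0
        )
    return state


def decay_step(state: SDState, P: dict, dt: float) -> SDState:
    """Exact exponential decay of each concern stock over ``dt``.

    The engagement integral accrues the analytic segment integral
    C * (1 - e^{-delta dt}) / delta (C * dt in the delta -> 0 limit), which
    keeps the zero-stimulus integral exact at machine precision.
    """
    delta = P["energyDecay"]
    fac = np.exp(-delta * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = np.where(delta > 0, (1.0 - fac) / np.where(delta > 0, delta, 1.0), dt)
    for ch in CHANNELS:
        C = state.concern[ch]
        state.engagement[ch] = state.engagement[ch] + C * seg
        state.concern[ch] = C * fac
    return state


def _coupling_inputs(stocks: dict, E_sp, E_cfn, fin_shock, P: dict,
                     const: CouplingConstants) -> dict:
    rel = P["rel_frequency"] / 9.0
    N = stocks["nationalism_level"]
    AP = stocks["anthropomorphic_promiscuity"]
    gate_n = 1.0 - _sigmoid((N - const.gate_n_mid) / const.gate_n_steep)
    gate_rel = 1.0 - _sigmoid((rel - const.gate_rel_mid) / const.gate_rel_steep)
    media_exposure = P["threatPctOfMedia"] * (
        const.w_tv_ais * P["tvMediaUse"] + const.w_sm_ais * P["socialMediaUse"]
    )
    return {
        "nationalism_level": (
            const.a_sp * E_sp - const.a_cfn * E_cfn + const.k_rel_nat * rel
        ),
        "anthropomorphic_promiscuity": (
            const.k_ap_base + const.k_ap * (E_sp - E_cfn)
            - const.k_ap_open * P["big_5_openness"]
        ),
        "sociographic_prudery": const.k_sgp_rel * rel + const.k_sgp_sp * E_sp,
        "social_conservativism": (
            const.c_soc_sp * E_sp - const.c_soc_cfn * E_cfn
            - const.c_nat_soc * N + const.b_sbs_soc * AP
        ),
        "economic_conservativism": (
            const.c_eco_sp * E_sp - const.c_eco_cfn * E_cfn
            - const.c_nat_eco * N + const.b_sbs_eco * AP
        ),
        "anti_immigrant_sentiment": (
            (const.susc_base + const.susc_consc * P["big_5_conscientiousness"])
            * (const.b_wvs_polsoc * stocks["social_conservativism"]
               + const.b_wvs_nat * N)
            + (const.susc_open_base - const.susc_open * P["big_5_openness"])
            * (-const.g_fin_gate * gate_n * fin_shock
               - const.m_media * gate_rel * media_exposure)
            + const.b_wvs_rel * rel
            + const.b_wvs_open * P["big_5_openness"]
            - const.b_wvs_consc * P["big_5_conscientiousness"]
            - const.b_wvs_agree * P["big_5_agreeableness"]
        ),
    }


def update_couplings(state: SDState, P: dict, const: CouplingConstants,
                     dt: float) -> SDState:
    """Advance the coupled socio-political stocks by one step.

    Engagements aggregate the concern channels (E_sp = mean of social &
    predation, E_cfn = mean of contagion, financial & natural); the batched
    integrator supplies their exact step averages via ``state.step_avg``,
    otherwise the instantaneous values are used.  Each stock relaxes toward
    input/rho with an exact exponential step; a Heun predictor-corrector on
    the inputs makes the scheme second-order in dt.
    """
    avg = getattr(state, "step_avg", None)
    concern = avg if avg is not None else state.concern
    E_sp = 0.5 * (concern["social"] + concern["predation"])
    E_cfn = (concern["contagion"] + concern["financial"]
             + concern["natural"]) / 3.0
    shock = avg["fin_shock"] if avg is not None else state.fin_shock

    S = state.stocks
    inputs0 = _coupling_inputs(S, E_sp, E_cfn, shock, P, const)
    fac = {}
    gain = {}
    for name in STOCKS:
        rho = const.rho_ais if name == "anti_immigrant_sentiment" else const.rho
        fac[name] = np.exp(-rho * dt)
        gain[name] = (1.0 - fac[name]) / rho
    predicted = {n: S[n] * fac[n] + inputs0[n] * gain[n] for n in STOCKS}
    inputs1 = _coupling_inputs(predicted, E_sp, E_cfn, shock, P, const)
    for name in STOCKS:
        x = S[name]
        state.stock_integrals[name] = state.stock_integrals[name] + x * dt
        x_new = x * fac[name] + 0.5 * (inputs0[name] + inputs1[name]) * gain[name]
        if not np.all(np.isfinite(x_new)):
            raise IntegrationError(name, state.t)
        S[name] = x_new
    state.t += dt
    return state


def _as_param_arrays(params: SDParameters | pd.DataFrame) -> tuple[dict, int]:
    if isinstance(params, SDParameters):
        params.validate()
        d = {k: np.asarray([v], dtype=float) for k, v in params.to_dict().items()}
        return d, 1
    df = params
    n = len(df)
    defaults = SDParameters().to_dict()
    d = {}
    for k, dv in defaults.items():
        if k in df.columns:
            d[k] = df[k].to_numpy(dtype=float)
        else:
            d[k] = np.full(n, float(dv))
    return d, n


def simulate_batch(params: pd.DataFrame | SDParameters,
                   constants: CouplingConstants | None = None,
                   record_trajectory: bool = False) -> pd.DataFrame:
    """Integrate one or many parameter sets (vectorised, fully deterministic).

    Events on each channel are scheduled evenly: event j of m at t = j*T/m,
    delivered at the first grid point >= its scheduled time.  Each step runs
    decay -> due events -> coupling updates.

    Returns one output row per parameter set: final and time-averaged values
    of every coupled stock, the per-channel engagement integral, and final /
    mean concern per channel, with the input parameters echoed.
    """
    const = constants or CouplingConstants()
    P, n = _as_param_arrays(params)
    horizon = float(P["horizon"][0])
    dt = float(P["dt"][0])
    if not (np.all(P["horizon"] == horizon) and np.all(P["dt"] == dt)):
        raise ConfigurationError("horizon and dt must be shared across a batch")
    n_steps = round(horizon / dt)
    if abs(horizon / dt - n_steps) > 1e-9:
        raise ConfigurationError("dt must divide the horizon")

    counts = {ch: P[f"hazard_event_count_{ch}"].astype(int) for ch in CHANNELS}
    state = SDState.initial(P, n)
    traj = [] if record_trajectory else None

    delta = P["energyDecay"]

    def _seg_decay(C, eng, seg):
        """Exact decay of C over per-run segment lengths with exact accrual."""
        fac = np.exp(-delta * seg)
        with np.errstate(divide="ignore", invalid="ignore"):
            acc = np.where(delta > 0, (1.0 - fac) / np.where(delta > 0, delta, 1.0), seg)
        return C * fac, eng + C * acc

    for step in range(1, n_steps + 1):
        t0 = (step - 1) * dt
        t_now = step * dt
        step_avg: dict[str, np.ndarray] = {}
        shock_before = state.fin_shock
        for ch in CHANNELS:
            eng_before = state.engagement[ch]
            # events are delivered at their exact scheduled times j*T/m by
            # splitting the decay into analytic segments, so results are
            # independent of how the grid aligns with the schedule
            C = state.concern[ch]
            eng = state.engagement[ch]
            k = state.events_done[ch]
            s = np.full(n, t0)
            if ch == "financial":
                shock = state.fin_shock
            while True:
                with np.errstate(divide="ignore", invalid="ignore"):
                    next_time = np.where(
                        counts[ch] > 0,
                        (k + 1) * horizon / np.maximum(counts[ch], 1),
                        np.inf,
                    )
                due = (k < counts[ch]) & (next_time <= t_now + 1e-9)
                if not np.any(due):
                    break
                seg = np.where(due, next_time - s, 0.0)
                C, eng = _seg_decay(C, eng, seg)
                lam = P[f"hazard_intensity_{ch}"] * _media_amplifier(P, const)
                alpha = P["base_learning_rate"] * np.exp(-P["habituationRate"] * k)
                C = np.where(due, C + alpha * (lam - C), C)
                if ch == "financial":
                    shock = shock * np.exp(-const.rho_shock * seg)
                    shock = shock + np.where(due, P["base_learning_rate"], 0.0)
                k = k + due.astype(int)
                s = np.where(due, next_time, s)
            C, eng = _seg_decay(C, eng, t_now - s)
            if ch == "financial":
                state.fin_shock = shock * np.exp(-const.rho_shock * (t_now - s))
            state.concern[ch] = C
            state.engagement[ch] = eng
            state.events_done[ch] = k
            step_avg[ch] = (eng - eng_before) / dt
        step_avg["fin_shock"] = 0.5 * (shock_before + state.fin_shock)
        state.step_avg = step_avg
        update_couplings(state, P, const, dt)
        state.step_avg = None
        if record_trajectory:
            row = {"t": t_now}
            for ch in CHANNELS:
                row[f"concern_{ch}"] = state.concern[ch].copy()
            for s in STOCKS:
                row[s] = state.stocks[s].copy()
            traj.append(row)

    out = {}
    for ch in CHANNELS:
        out[f"engagement_{ch}"] = state.engagement[ch]
        out[f"final_concern_{ch}"] = state.concern[ch]
        out[f"mean_concern_{ch}"] = state.engagement[ch] / horizon
    for s in STOCKS:
        out[s] = state.stocks[s]
        out[f"mean_{s}"] = state.stock_integrals[s] / horizon
    result = pd.DataFrame(out)
    echo = pd.DataFrame({k: v for k, v in P.items()})
    result = pd.concat([echo, result], axis=1)
    if record_trajectory:
        frames = []
        for row in traj:
            t_val = row.pop("t")
            f = pd.DataFrame({k: v for k, v in row.items()})
            f.insert(0, "t", t_val)
            f.insert(0, "run", np.arange(n))
            frames.append(f)
        result.attrs["trajectory"] = pd.concat(frames, ignore_index=True)
    return result


def run_simulation(params: SDParameters,
                   constants: CouplingConstants | None = None) -> pd.Series:
    """Run one deterministic simulation; returns the single output record."""
    return simulate_batch(params, constants).iloc[0]


class ThreatDynamicsModel:
    """Model object wrapping one parameter set plus coupling constants."""

    def __init__(self, params: SDParameters | None = None,
                 constants: CouplingConstants | None = None):
        self.params = params or SDParameters()
        self.constants = constants or CouplingConstants()

    def run(self, record_trajectory: bool = True) -> "SimulationResult":
        table = simulate_batch(self.params, self.constants,
                               record_trajectory=record_trajectory)
        traj = table.attrs.get("trajectory") if record_trajectory else None
        return SimulationResult(self, table.iloc[0], traj)


class SimulationResult:
    """One simulated trajectory and its output record."""

    def __init__(self, model: ThreatDynamicsModel, record: pd.Series,
                 trajectory: pd.DataFrame | None):
        self.model = model
        self.record = record
        self.trajectory = trajectory

    def summary(self) -> str:
        lines = ["Threat-dynamics simulation (deterministic)",
                 f"  horizon = {self.model.params.horizon}, dt = {self.model.params.dt}"]
        for ch in CHANNELS:
            lines.append(
                f"  {ch:>10s}: engagement integral = "
                f"{self.record[f'engagement_{ch}']:.4f}, "
                f"final concern = {self.record[f'final_concern_{ch}']:.4f}"
            )
        for s in STOCKS:
            lines.append(f"  {s}: final = {self.record[s]:.4f}, "
                         f"mean = {self.record[f'mean_{s}']:.4f}")
        return "\n".join(lines)

    def to_tidy_csv(self, path) -> None:
        """Trajectory as tidy (t, stock, value) CSV."""
        if self.trajectory is None:
            raise ConfigurationError("run with record_trajectory=True first")
        tidy = self.trajectory.melt(id_vars=["run", "t"], var_name="stock",
                                    value_name="value")
        tidy.to_csv(path, index=False)
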