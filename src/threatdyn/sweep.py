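"""Uniform parameter-space sampling and deterministic sweep execution.

The design of experiment mirrors the published study: a large number of
parameter sets drawn independently and uniformly within per-parameter bounds
(20,000 by default), each integrated exactly once because the simulator is
deterministic.  Execution is chunked and checkpointable by run id; results
are independent of execution order and chunking because the integrator is
elementwise over runs.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    CHANNELS,
    CouplingConstants,
    SDParameters,
    simulate_batch,
)
from .errors import ConfigurationError, SweepError

__all__ = [
    "SweepDesign",
    "default_sweep_design",
    "generate_parameter_table",
    "generate_parameter_sets",
    "run_sweep",
    "ParameterSweep",
    "SweepResult",
]

#: parameters drawn as integers over an inclusive range
_INTEGER_PARAMS = {f"hazard_event_count_{c}" for c in CHANNELS} | {"rel_frequency"}


@dataclass
class SweepDesign:
    """Uniform design: bounds per swept parameter plus fixed values."""

    n_sets: int = 20000
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def validate(self):
        if self.n_sets < 0:
            raise ConfigurationError("n_sets must be >= 0")
        if not self.bounds:
            raise ConfigurationError("sweep design has no swept parameters")
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigurationError(f"bounds for '{k}' must satisfy low < high")
        overlap = set(self.bounds) & set(self.fixed)
        if overlap:
            raise ConfigurationError(f"parameters both swept and fixed: {sorted(overlap)}")


def default_sweep_design(n_sets: int = 20000, seed: int = 0) -> SweepDesign:
    """The default broad uniform design.

    Normalised use-frequencies, personality traits and initial concerns span
    [0, 1]; hazard intensities [0, 5]; event counts are integers 0..20;
    attendance is the ordinal 0..9; habituation [0, 1]; concern decay
    [0, 0.3] (timescales of a few time units, so concern persists between
    events).  The natural channel starts at zero concern and the base
    learning rate is held at 0.5.
    """
    bounds: dict[str, tuple[float, float]] = {
        "tvMediaUse": (0.0, 1.0),
        "socialMediaUse": (0.0, 1.0),
        "threatPctOfMedia": (0.0, 1.0),
        "rel_frequency": (0, 9),
        "habituationRate": (0.0, 1.0),
        "energyDecay": (0.0, 0.3),
        "big_5_openness": (0.0, 1.0),
        "big_5_conscientiousness": (0.0, 1.0),
        "big_5_agreeableness": (0.0, 1.0),
        "big_5_extraversion": (0.0, 1.0),
        "big_5_neuroticism": (0.0, 1.0),
    }
    for ch in CHANNELS:
        bounds[f"hazard_intensity_{ch}"] = (0.0, 5.0)
        bounds[f"hazard_event_count_{ch}"] = (0, 20)
        if ch != "natural":
            bounds[f"initial_concern_{ch}"] = (0.0, 1.0)
    fixed = {"initial_concern_natural": 0.0, "base_learning_rate": 0.5,
             "horizon": 20.0, "dt": 0.1}
    return SweepDesign(n_sets=n_sets, seed=seed, bounds=bounds, fixed=fixed)


def generate_parameter_table(design: SweepDesign) -> pd.DataFrame:
    """Draw the uniform parameter table (reproducible given the seed).

    One seeded stream; parameters are drawn column-wise in sorted name order
    so the table is invariant to dict insertion order.  Integer-valued
    parameters are uniform over their inclusive integer range.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_sets
    cols: dict[str, np.ndarray] = {"run_id": np.arange(n, dtype=int)}
    for name in sorted(design.bounds):
        lo, hi = design.bounds[name]
        if name in _INTEGER_PARAMS:
            cols[name] = rng.integers(int(lo), int(hi) + 1, size=n)
        else:
            cols[name] = rng.uniform(lo, hi, size=n)
    for name, val in design.fixed.items():
        cols[name] = np.full(n, val)
    return pd.DataFrame(cols)


def generate_parameter_sets(design: SweepDesign) -> list[SDParameters]:
    """The parameter table as a list of validated parameter objects."""
    table = generate_parameter_table(design)
    out = []
    for _, row in table.iterrows():
        d = row.drop("run_id").to_dict()
        for k in _INTEGER_PARAMS:
            if k in d:
                d[k] = int(d[k])
        out.append(SDParameters.from_dict(d))
    return out


def run_sweep(params_table: pd.DataFrame,
              constants: CouplingConstants | None = None,
              checkpoint_path: str | None = None,
              chunk_size: int = 2000,
              progress_log=None,
              max_failure_rate: float = 0.01) -> pd.DataFrame:
    """Execute one deterministic simulation per parameter set.

    Runs in chunks; with ``checkpoint_path`` each completed chunk is appended
    to a CSV keyed by ``run_id`` and an interrupted sweep resumes from it,
    producing a table identical to an uninterrupted run.  Non-finite runs are
    recorded with ``status='error'`` rather than dropped; if more than
    ``max_failure_rate`` of runs fail the sweep aborts with a summary.
    """
    const = constants or CouplingConstants()
    if "run_id" not in params_table.columns:
        params_table = params_table.assign(run_id=np.arange(len(params_table)))
    done = None
    if checkpoint_path and os.path.exists(checkpoint_path):
        done = pd.read_csv(checkpoint_path)
    done_ids = set(done["run_id"].astype(int)) if done is not None else set()

    frames = [] if done is None else [done]
    todo = params_table[~params_table["run_id"].isin(done_ids)]
    for start in range(0, len(todo), chunk_size):
        chunk = todo.iloc[start:start + chunk_size]
        t0 = time.perf_counter()
        out = simulate_batch(chunk.drop(columns=["run_id"]), const)
        out.insert(0, "run_id", chunk["run_id"].to_numpy())
        value_cols = [c for c in out.columns if c != "run_id"]
        finite = np.isfinite(out[value_cols].to_numpy()).all(axis=1)
        out["status"] = np.where(finite, "ok", "error")
        wall_ms = (time.perf_counter() - t0) * 1000 / max(len(chunk), 1)
        if progress_log is not None:
            for rid, st in zip(out["run_id"], out["status"]):
                progress_log.write(f"{rid},{st},{wall_ms:.3f}\n")
        if checkpoint_path:
            out.to_csv(checkpoint_path, mode="a", index=False,
                       header=not os.path.exists(checkpoint_path))
        frames.append(out)
    result = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(result):
        result = result.sort_values("run_id", ignore_index=True)
        fail = (result["status"] == "error").mean()
        if fail > max_failure_rate:
            raise SweepError(
                f"{fail:.1%} of runs failed (> {max_failure_rate:.0%}); "
                f"first failures: {result.loc[result.status == 'error', 'run_id'].head().tolist()}"
            )
    return result


class ParameterSweep:
    """Model-style wrapper: a design plus constants, executed on demand."""

    def __init__(self, design: SweepDesign | None = None,
                 constants: CouplingConstants | None = None):
        self.design = design or default_sweep_design()
        self.constants = constants or CouplingConstants()

    def run(self, checkpoint_path: str | None = None,
            progress_log=None) -> "SweepResult":
        table = generate_parameter_table(self.design)
        out = run_sweep(table, self.constants, checkpoint_path=checkpoint_path,
                        progress_log=progress_log)
        return SweepResult(self, out)


class SweepResult:
    """A completed sweep; analysis methods live in :mod:`threatdyn.sweep_analysis`."""

    def __init__(self, sweep: ParameterSweep, table: pd.DataFrame):
        self.sweep = sweep
        self.table = table

    def summary(self) -> str:
        ok = (self.table["status"] == "ok").sum() if "status" in self.table else len(self.table)
        lines = [
            f"Parameter sweep: {len(self.table)} runs ({ok} ok), "
            f"seed {self.sweep.design.seed}",
        ]
        for col in ("nationalism_level", "anti_immigrant_sentiment"):
            s = self.table[col]
            lines.append(f"  {col}: mean {s.mean():.3f}, sd {s.std():.3f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
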