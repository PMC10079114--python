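"""Plot helpers: correlation heat maps, binned trends, trajectories.

All functions return a matplotlib Figure; callers decide whether to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_correlation_map", "plot_binned_trend", "plot_trajectory"]


def plot_correlation_map(corr: pd.DataFrame, title: str = "Correlation map"):
    fig, ax = plt.subplots(figsize=(0.45 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig


def plot_binned_trend(trend: dict, xlabel: str, ylabel: str):
    s = trend["summary"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        s.index.to_numpy(dtype=float), s["mean"],
        yerr=np.vstack([s["mean"] - s["q25"], s["q75"] - s["mean"]]),
        fmt="o-", capsize=3,
    )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"Spearman rho = {trend['spearman_rho']:.3f}")
    fig.tight_layout()
    return fig


def plot_trajectory(trajectory: pd.DataFrame, columns: list[str] | None = None):
    cols = columns or [c for c in trajectory.columns if c not in ("run", "t")]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in cols:
        ax.plot(trajectory["t"], trajectory[c], label=c, lw=1.2)
    ax.set_xlabel("time")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
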