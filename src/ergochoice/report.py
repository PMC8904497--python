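"""Diagnostic figures: per-couple estimates with group bands, and the
cumulative response-time box plot. Numeric outputs never depend on these."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_estimates", "plot_times", "plot_trajectories"]

_COLORS = {"timed": "tab:orange", "control": "tab:blue"}


def plot_estimates(estimates, comparisons: dict, path) -> None:
    """Scatter of per-couple safer-bet probabilities (posterior mean ± sd)
    per setting, with horizontal bands at the aggregated group estimates."""
    settings = sorted({e.setting.value for e in estimates})
    fig, axes = plt.subplots(1, len(settings), figsize=(6 * len(settings), 4), squeeze=False)
    for ax, setting in zip(axes[0], settings):
        for group, color in _COLORS.items():
            sub = [e for e in estimates if e.group == group and e.setting.value == setting]
            sub.sort(key=lambda e: e.couple_index)
            x = np.arange(1, len(sub) + 1)
            ax.errorbar(
                x,
                [e.mean for e in sub],
                yerr=[e.sd for e in sub],
                fmt="o",
                ms=3,
                color=color,
                label=group,
                alpha=0.8,
            )
            comp = comparisons.get(setting, {})
            p_s = comp.get(f"p_{group}")
            sd_s = comp.get(f"sd_{group}")
            if p_s is not None:
                ax.axhspan(p_s - sd_s, p_s + sd_s, color=color, alpha=0.2)
        ax.set_title(f"{setting} setting")
        ax.set_xlabel("bet couple")
        ax.set_ylabel("P(safer bet)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_times(totals: pd.DataFrame, path) -> None:
    """Box plot of cumulative response time per group."""
    fig, ax = plt.subplots(figsize=(4, 4))
    groups = sorted(totals["group"].unique())
    data = [totals.loc[totals["group"] == g, "total_time_s"] for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("cumulative response time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(ensemble, path, expected_curve: bool = True) -> None:
    """Capital trajectories with the expected-value curve overlaid."""
    from .dynamics import Dynamic, ensemble_ev

    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.arange(ensemble.n_rounds + 1)
    ax.plot(t, ensemble.capital.T, color="gray", lw=0.3, alpha=0.5)
    if expected_curve:
        ev = ensemble_ev(ensemble.bet, ensemble.dynamic)
        if ensemble.dynamic is Dynamic.ADDITIVE:
            ax.plot(t, ensemble.start_capital + ev * t, color="black", lw=2)
        else:
            ax.plot(t, ensemble.start_capital * ev**t, color="black", lw=2)
            ax.set_yscale("log")
    ax.set_xlabel("round")
    ax.set_ylabel("capital")
    ax.set_title(f"{ensemble.dynamic.value} dynamic")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
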