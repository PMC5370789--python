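"""Report figures: love plot, Kaplan–Meier curves, subgroup forest plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .balance import BalanceReport
from .survival import SurvivalCurve


def love_plot(report: BalanceReport, path=None, threshold: float = 0.1):
    """Absolute SMD per covariate, before vs after matching."""
    tab = report.table.iloc[::-1]
    y = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1.5))
    ax.scatter(tab["smd_before"].abs(), y, marker="o", label="before", color="tab:red")
    ax.scatter(tab["smd_after"].abs(), y, marker="s", label="after", color="tab:blue")
    ax.axvline(threshold, ls="--", color="gray", lw=1)
    ax.set_yticks(y, tab["name"])
    ax.set_xlabel("|standardized difference|")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def km_plot(curves: dict[str, SurvivalCurve], path=None, title=""):
    """Step survival curves per arm."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.event_times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("days from match")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def forest_plot(subgroups, path=None, title=""):
    """Hazard ratios with 95% CIs per subgroup level."""
    tab = subgroups.dropna(subset=["hr"]).iloc[::-1]
    labels = [f"{r.subgroup}: {r.level}" for r in tab.itertuples()]
    y = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(tab) + 1.5))
    ax.errorbar(tab["hr"], y,
                xerr=[tab["hr"] - tab["ci95_low"], tab["ci95_high"] - tab["hr"]],
                fmt="o", color="k", ecolor="gray", capsize=2)
    ax.axvline(1.0, ls="--", color="gray", lw=1)
    ax.set_xscale("log")
    ax.set_yticks(y, labels)
    ax.set_xlabel("hazard ratio (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
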