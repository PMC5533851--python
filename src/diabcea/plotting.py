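"""Cost-effectiveness plane and acceptability-curve figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .psa import PSAResult

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(result: PSAResult, title: str = "", threshold: float = 50_000.0):
    """Scatter of per-replicate (ΔQALY, Δcost) with the willingness-to-pay line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.delta_qaly, result.delta_cost, s=6, alpha=0.4, linewidths=0)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    if threshold:
        q = np.array(ax.get_xlim())
        ax.plot(q, threshold * q, "--", color="tab:red", lw=0.8,
                label=f"{threshold:,.0f} €/QALY")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (€)")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_ceac(thresholds, probabilities, title: str = ""):
    """Probability of cost-effectiveness against the willingness-to-pay threshold."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(thresholds, probabilities)
    ax.set_xlabel("Willingness to pay (€ per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    fig.tight_layout()
    return fig
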