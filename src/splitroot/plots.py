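"""Plotting helpers (matplotlib, non-interactive friendly)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .experiment import Replicate, allocation_summary  # noqa: E402

__all__ = ["plot_allocation"]


def plot_allocation(replicates: list[Replicate], compartment: str,
                    metric: str = "length", ax=None):
    """Bar chart of the mean proportion of a metric allocated to one
    compartment per branching number (error bars: ±1 sd)."""
    summary = allocation_summary(replicates, compartment, metric)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(summary.index, summary["mean_proportion"],
           yerr=summary["sd_proportion"], color="#4878a8", capsize=3)
    ax.axhline(0.5, ls="--", lw=0.8, color="0.4")
    ax.set_xlabel("root branching number")
    ax.set_ylabel(f"proportion of {metric}\ntoward {compartment}")
    ax.set_ylim(0, 1)
    return ax
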