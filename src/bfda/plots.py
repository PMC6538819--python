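"""Optional matplotlib visualizations of design-analysis output.

Requires matplotlib (install extra ``bfda[plot]``).  Each function draws on
a provided or fresh Axes and returns it; saving is left to the caller.
"""

from __future__ import annotations

import numpy as np

from .fixed_n import FixedNResult
from .sequential import SequentialResult


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_bf_distribution(result: FixedNResult, bounds=None, ax=None):
    """Histogram of log10 Bayes factors, with optional decision boundaries."""
    ax = _axes(ax)
    ax.hist(result.log_bfs / np.log(10), bins=60, color="#4878a8")
    if bounds is not None:
        for b in (bounds.lower, bounds.upper):
            ax.axvline(np.log10(b), color="crimson", ls="--")
    ax.set_xlabel("log10 BF10")
    ax.set_ylabel("simulated studies")
    return ax


def plot_trajectories(result: SequentialResult, ax=None):
    """Spaghetti plot of stored sequential sampling trajectories."""
    if not result.trajectories:
        raise ValueError("no stored trajectories; rerun with store_paths > 0")
    ax = _axes(ax)
    for traj in result.trajectories:
        ax.plot(traj.ns, traj.log_bfs / np.log(10), lw=0.8, alpha=0.6)
    for b in (result.bounds.lower, result.bounds.upper):
        ax.axhline(np.log10(b), color="black", ls="--", lw=1)
    ax.set_xlabel("observations per group")
    ax.set_ylabel("log10 BF10")
    return ax


def plot_final_n(result: SequentialResult, ax=None):
    """Violin of the final per-group sample-size distribution (log scale)."""
    ax = _axes(ax)
    decided = result.final_n[result.side != "censored"]
    ax.violinplot(np.log10(decided), showmedians=True)
    ax.set_ylabel("log10 final n per group")
    ax.set_xticks([])
    return ax
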