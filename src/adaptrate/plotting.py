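"""Static figures for sweep, window-study and empirical results.

All functions draw on a supplied Axes (or create one) and return it;
nothing is shown interactively.
"""

from __future__ import annotations

import numpy as np

_COLORS = {"gold": "black", "silver": "gray",
           "conventional": "tab:red", "analytic": "tab:cyan"}


def _ax(ax):
    if ax is None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_sweep(result, ax=None, absolute: bool = True, band: bool = True):
    """Mean adaptation rate (|AR| by convention) vs the swept parameter,
    one line per estimator, with +/- 1 SD bands."""
    ax = _ax(ax)
    t = result.table
    for name, color in _COLORS.items():
        mean = t[f"mean_abs_{name}" if absolute else f"mean_{name}"]
        ax.plot(t["value"], mean, color=color, label=name)
        if band:
            sd = t[f"sd_{name}"]
            ax.fill_between(t["value"], mean - sd, mean + sd,
                            color=color, alpha=0.15, lw=0)
    ax.set_xscale("log")
    ax.set_xlabel(result.config.varied)
    ax.set_ylabel("|adaptation rate|" if absolute else "adaptation rate")
    ax.legend()
    return ax


def plot_sweep_mse(result, ax=None):
    """Mean squared error vs the gold AR across the sweep."""
    ax = _ax(ax)
    t = result.table
    for name in ("silver", "conventional", "analytic"):
        ax.plot(t["value"], t[f"mse_{name}"], color=_COLORS[name], label=name)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(result.config.varied)
    ax.set_ylabel("MSE vs gold AR")
    ax.legend()
    return ax


def plot_window_study(result, ax=None):
    """Run-to-run SD of each estimator vs analysis-window size."""
    ax = _ax(ax)
    t = result.table
    for name, color in _COLORS.items():
        ax.plot(t["window"], t[f"sd_{name}"], color=color, label=name)
    ax.set_xlabel("trials analyzed")
    ax.set_ylabel("SD of estimate across runs")
    ax.legend()
    return ax


def plot_condition_means(block_table, ax=None, absolute: bool = True):
    """Group mean +/- SD per noise condition for each empirical estimator."""
    ax = _ax(ax)
    from .empirical import CONDITIONS
    x = np.arange(len(CONDITIONS))
    for name in ("silver", "conventional", "analytic"):
        vals = block_table.pivot(index="subject", columns="condition",
                                 values=name)[list(CONDITIONS)]
        if absolute:
            vals = vals.abs()
        ax.errorbar(x, vals.mean(), yerr=vals.std(), label=name,
                    color=_COLORS[name], capsize=3, marker="o")
    ax.set_xticks(x, CONDITIONS)
    ax.set_xlabel("added-noise condition")
    ax.set_ylabel("|adaptation rate|" if absolute else "adaptation rate")
    ax.legend()
    return ax
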