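"""Basic plotting helpers for the study outputs (matplotlib, optional).

Convenience views only: intramural-profile families, the convergence table,
raincloud-style emulator distributions and Sobol bar charts.  All functions
take an optional matplotlib Axes and return it.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_intramural_profiles(result, stations, ax=None):
    """Through-wall strain vs distance ratio for a set of stations."""
    from .metrics import intramural_profile

    ax = _ax(ax)
    for j in stations:
        t, e1 = intramural_profile(result, j)
        ax.plot(t, e1, marker="o", ms=3, label=f"z = {result.z[j]:.1f} mm")
    ax.set_xlabel("distance ratio (inner to outer)")
    ax.set_ylabel("1st principal Lagrangian strain")
    ax.legend(fontsize=8)
    return ax


def plot_convergence(table, ax=None):
    """95th/99th percentile strain vs wall layer count."""
    ax = _ax(ax)
    ax.plot(table.n_layers, table.strain_p95, "o-", label="95th %ile")
    ax.plot(table.n_layers, table.strain_p99, "s-", label="99th %ile")
    ax.set_xlabel("wall layers")
    ax.set_ylabel("1st principal strain")
    ax.legend()
    return ax


def plot_emulator_raincloud(samples_by_metric: dict, ax=None, rng=None):
    """Jittered strip + median/extrema markers per output metric."""
    ax = _ax(ax)
    rng = rng or np.random.default_rng(0)
    for i, (name, y) in enumerate(samples_by_metric.items()):
        y = np.asarray(y, dtype=float)
        x = i + 0.08 * rng.standard_normal(len(y))
        ax.plot(x, y, ".", ms=2, alpha=0.3)
        ax.plot([i], [np.median(y)], "k_", ms=18)
        ax.plot([i, i], [y.min(), y.max()], "k-", lw=0.8)
    ax.set_xticks(range(len(samples_by_metric)), list(samples_by_metric), rotation=30)
    return ax


def plot_sobol(sobol_frame, metric: str, ax=None):
    """Paired first/total-order index bars for one output metric."""
    ax = _ax(ax)
    sub = sobol_frame[sobol_frame.metric == metric]
    x = np.arange(len(sub))
    ax.bar(x - 0.2, sub.S_first, width=0.4, label="first order")
    ax.bar(x + 0.2, sub.S_total, width=0.4, label="total order")
    ax.set_xticks(x, sub.parameter)
    ax.set_ylabel("Sobol index")
    ax.set_title(metric)
    ax.legend()
    return ax
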