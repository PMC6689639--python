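"""Simple summary plots for runs and sweeps (matplotlib, imported lazily)."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .types import RunRecord

__all__ = ["plot_run", "plot_sweep_heatmap"]


def plot_run(record: RunRecord, ax=None):
    """Mean false positive rate and false discovery rates over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(record.times, record.mean_alpha, "--", label=r"mean $\alpha$")
    ax.plot(record.times, record.fdr_cumulative, "-", label="F (cumulative)")
    ax.plot(record.times, record.fdr_windowed, ":", label="F (windowed)")
    ax.set_xlabel("iteration")
    ax.set_ylabel("rate")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_sweep_heatmap(
    summary: pd.DataFrame,
    x: str,
    y: str,
    value: str = "eq_fdr_mean",
    ax=None,
    label: Optional[str] = None,
):
    """Heatmap of an aggregated sweep statistic over two axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = summary.pivot_table(index=y, columns=x, values=value)
    im = ax.imshow(
        pivot.values, origin="lower", aspect="auto", vmin=0, vmax=1,
        cmap="viridis",
    )
    ax.set_xticks(range(len(pivot.columns)), [str(c) for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [str(i) for i in pivot.index])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.figure.colorbar(im, ax=ax, label=label or value)
    return ax
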