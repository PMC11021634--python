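"""Ridgeline-style visualisation of capture-probability posteriors."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import beta_posterior


def plot_beta_ridgeline(records: pd.DataFrame, path=None, ax=None):
    """Stacked beta-posterior densities of the capture probability per size
    group (records pooled within each group).  Returns the matplotlib Axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pooled = records.groupby("size_group", observed=True)[["n", "N"]].sum().reset_index()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 1.2 * max(len(pooled), 2)))
    x = np.linspace(0, 1, 512)
    offset = 0.0
    yticks, ylabels = [], []
    for _, row in pooled.iterrows():
        post = beta_posterior(int(row["n"]), int(row["N"]))
        dens = post.pdf(x)
        peak = dens.max() if np.isfinite(dens.max()) and dens.max() > 0 else 1.0
        ax.fill_between(x, offset, offset + dens / peak, alpha=0.6)
        yticks.append(offset)
        ylabels.append(f"{row['size_group']} (n={int(row['n'])}/N={int(row['N'])})")
        offset += 1.1
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels)
    ax.set_xlabel("capture probability")
    ax.set_xscale("log")
    ax.set_xlim(1e-4, 1)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
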