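"""Plotting helpers: ERP traces, t-maps, epoch grids, Bayes-factor traces.

These are conveniences for inspection; nothing downstream depends on them.
"""

from __future__ import annotations

import numpy as np

from .datasets import ERPDataset
from .stats import ClusterResult, EpochAggregate, clamp_bf


def plot_erp(dataset: ERPDataset, channel: str, ax=None, conditions=None, **kwargs):
    """Grand-average traces for one channel, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond in conditions or dataset.conditions:
        ax.plot(dataset.times_ms, dataset.grand_average(cond)[dataset.layout.index(channel)],
                label=cond, **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"amplitude ({dataset.units})")
    ax.set_title(channel)
    ax.legend()
    return ax


def plot_tmap(result: ClusterResult, ax=None):
    """Channel x time map of paired t values with significant samples hatched."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = np.abs(result.t_map).max() or 1.0
    im = ax.imshow(result.t_map, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=[result.times_ms[0], result.times_ms[-1],
                           len(result.channel_names) - 0.5, -0.5])
    ys, xs = np.nonzero(result.sig_mask)
    ax.scatter(result.times_ms[xs], ys, marker=".", s=4, c="k")
    ax.set_yticks(range(len(result.channel_names)), result.channel_names)
    ax.set_xlabel("time (ms)")
    plt.colorbar(im, ax=ax, label="paired t")
    return ax


def plot_epoch_grid(agg: EpochAggregate, channel_names, ax=None):
    """Electrode x 50-ms-epoch significance grid (asterisk = significant)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(agg.grid, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_yticks(range(len(channel_names)), channel_names)
    ax.set_xticks(range(agg.n_epochs),
                  [f"{int(e)}" for e in agg.epoch_edges_ms[:-1]], rotation=90)
    ax.set_xlabel("epoch start (ms)")
    return ax


def plot_bf_trace(times_ms, bf10, cap: float = 30.0, ax=None):
    """Per-sample BF10 (capped for display) and BF01 traces."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    capped = np.array([clamp_bf(b, cap) for b in bf10])
    ax.plot(times_ms, capped, color="green", label=f"BF10 (capped at {cap:g})")
    ax.plot(times_ms, 1.0 / np.asarray(bf10), color="gray", label="BF01")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_yscale("log")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("Bayes factor")
    ax.legend()
    return ax
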