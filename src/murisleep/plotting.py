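"""Minimal figures: hypnogram trace and group bar plots."""
from __future__ import annotations

import numpy as np

from .hypnogram import NREM, REM, WAKE, Hypnogram
from .summary import SleepSummary

_LEVELS = {WAKE: 2, NREM: 1, REM: 0}


def plot_hypnogram(hyp: Hypnogram, ax=None):
    """Step plot of the stage sequence (WAKE on top, REM at the bottom)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    t = np.arange(len(hyp)) * hyp.epoch_s / 3600.0
    ax.step(t, [_LEVELS[s] for s in hyp.stages], where="post", lw=0.8)
    ax.set_yticks([0, 1, 2], ["REM", "NREM", "WAKE"])
    ax.set_xlabel("time (h)")
    return ax


def plot_group_means(
    summaries_by_group: dict[str, list[SleepSummary]],
    metric: str,
    windows=("LIGHT", "DARK", "H24"),
    ax=None,
):
    """Bar plot of group means ± SEM for one metric across windows."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = list(summaries_by_group)
    width = 0.8 / len(groups)
    xs = np.arange(len(windows))
    for gi, g in enumerate(groups):
        vals = np.array(
            [[s.value(metric, w) for s in summaries_by_group[g]] for w in windows]
        )
        mean = np.nanmean(vals, axis=1)
        sem = np.nanstd(vals, axis=1, ddof=1) / np.sqrt(vals.shape[1])
        ax.bar(xs + gi * width, mean, width=width, yerr=sem, capsize=3, label=g)
    ax.set_xticks(xs + width * (len(groups) - 1) / 2, list(windows))
    ax.set_ylabel(metric)
    ax.legend()
    return ax
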