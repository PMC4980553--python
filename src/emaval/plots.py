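"""Optional matplotlib views of the two analysis arms (visual aids only)."""

from __future__ import annotations

import pandas as pd


def plot_window_curves(sens_spec: pd.DataFrame, ax=None):
    """Sensitivity and specificity versus window half-width, per food group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for group, sub in sens_spec.groupby("food_group"):
        sub = sub.sort_values("w")
        ax.plot(sub["w"], sub["sensitivity"], label=f"{group} sens")
        ax.plot(sub["w"], sub["specificity"], linestyle="--", label=f"{group} spec")
    ax.set_xlabel("window half-width (min)")
    ax.set_ylabel("percent")
    ax.set_ylim(0, 100)
    ax.legend(fontsize="x-small", ncol=2)
    return ax


def plot_participant_means(means: pd.DataFrame, ax=None):
    """Per-participant mean derived CPM by reported level (paradox audit)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    levels = [c for c in means.columns if means[c].notna().any()]
    x = range(len(levels))
    for _, row in means.iterrows():
        ax.plot(x, [row[lv] for lv in levels], color="grey", alpha=0.5, marker="o", markersize=3)
    ax.set_xticks(list(x), levels)
    ax.set_ylabel("mean pre-prompt CPM")
    return ax
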