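"""Optional, thin plotting helpers (non-contractual presentation layer).

Everything here renders data that the evaluation module already computes;
nothing downstream depends on these figures.  Requires matplotlib.
"""

from __future__ import annotations

import numpy as np

from .activities import ActivityClass
from .evaluation import confusion, normalize_chart


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_confusion_chart(chart, ax=None, title=None):
    """Heatmap of an 8x8 confusion chart with row-normalized annotations."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    codes = [c.code for c in ActivityClass]
    im = ax.imshow(np.asarray(chart), cmap="Blues")
    row = normalize_chart(chart, "row")
    for i in range(len(codes)):
        for j in range(len(codes)):
            if chart[i][j]:
                ax.text(j, i, f"{chart[i][j]}\n{row[i, j]:.0f}%",
                        ha="center", va="center", fontsize=7)
    ax.set_xticks(range(8), codes, rotation=45, ha="right")
    ax.set_yticks(range(8), codes)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_precision_boxes(records, ax=None, measure="precision"):
    """Per-class boxplots of a measure over participants."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    codes = [c.code for c in ActivityClass]
    data = [records.loc[records["class"] == code, measure].dropna()
            for code in codes]
    ax.boxplot(data, tick_labels=codes, whis=1.5)
    ax.set_ylabel(measure)
    ax.set_ylim(-0.02, 1.02)
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_timeline(fold_result, ax=None):
    """Predicted vs true class index over time for one validation fold."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    t = np.arange(len(fold_result.y_true)) / 10.0
    ax.plot(t, fold_result.y_true, lw=1.2, label="annotated")
    ax.plot(t, fold_result.y_pred, ls="--", lw=0.9, label="predicted")
    ax.set_yticks(range(8), [c.code for c in ActivityClass])
    ax.set_xlabel("time (s)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_fold(fold_result, path=None):
    """Confusion chart + timeline for one fold; optionally save to path."""
    plt = _plt()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(13, 4),
                                   gridspec_kw={"width_ratios": [1, 1.6]})
    chart = confusion(fold_result.y_true, fold_result.y_pred)
    plot_confusion_chart(chart, ax=ax1,
                         title=fold_result.val_participant_id)
    plot_timeline(fold_result, ax=ax2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
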