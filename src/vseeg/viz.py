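"""Report figures: score timelines with significance bars and pattern heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["score_timeline_figure", "pattern_heatmap", "save_report_figures"]


def score_timeline_figure(scores, intervals, ax=None, label=None):
    """Fold-mean AUC over time with SEM band and significance bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    mean = scores.fold_mean()
    sem = scores.scores.std(axis=0, ddof=1) / np.sqrt(scores.n_folds)
    ax.plot(scores.times, mean, label=label or scores.space)
    ax.fill_between(scores.times, mean - sem, mean + sem, alpha=0.25)
    ax.axhline(0.5, color="k", lw=0.8, ls="--")
    for lo, hi in intervals:
        ax.hlines(0.42, lo, hi, lw=4, color="C3")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROC-AUC")
    ax.set_ylim(0.35, 1.0)
    ax.legend(loc="upper left", fontsize=8)
    return ax


def pattern_heatmap(timeline, ax=None, title=None):
    """Channel x time-bin heatmap of activation-pattern values."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    vmax = np.abs(timeline.values).max() or 1.0
    ax.imshow(timeline.values, aspect="auto", cmap="RdBu_r",
              vmin=-vmax, vmax=vmax,
              extent=[timeline.bin_edges_s[0], timeline.bin_edges_s[-1],
                      timeline.values.shape[0], 0])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel")
    if title:
        ax.set_title(title)
    return ax


def save_report_figures(out_dir, scores, intervals, timelines, cfg_hash):
    out_dir = Path(out_dir)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for space, sc in scores.items():
        score_timeline_figure(sc, intervals.get(space, []), ax=ax, label=space)
    ax.set_title(f"decoding timelines [config {cfg_hash}]", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_dir / "scores.png", dpi=110)
    plt.close(fig)
    for space, tl in timelines.items():
        fig, ax = plt.subplots(figsize=(7, 5))
        pattern_heatmap(tl, ax=ax,
                        title=f"{space} activation patterns [config {cfg_hash}]")
        fig.tight_layout()
        fig.savefig(out_dir / f"patterns_{space.replace(':', '_')}.png", dpi=110)
        plt.close(fig)
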