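"""Figure emission: stacked mention bars, user-activity density, trend lines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mentions import MentionCountTable, UserActivityStats
from .sentiment import LABELS
from .trends import TrendSeries


def plot_mentions_stacked(table: MentionCountTable, path) -> Path:
    """Horizontal stacked bars: mentions per 2-week bin, stacked by group."""
    fig, ax = plt.subplots(figsize=(10, 6))
    bins = [str(c) for c in table.counts.columns]
    left = np.zeros(len(bins))
    for g in table.counts.index:
        vals = table.counts.loc[g].to_numpy(dtype=float)
        ax.barh(bins, vals, left=left, label=g)
        left += vals
    ax.set_xlabel("mentions")
    ax.set_ylabel(f"{table.bin_width_days}-day bin start")
    ax.invert_yaxis()
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_user_activity_density(stats: UserActivityStats, path, platform: str = "") -> Path:
    """Density-style histogram of log posts-per-user."""
    fig, ax = plt.subplots(figsize=(6, 4))
    counts, edges = stats.log_hist
    widths = np.diff(edges)
    density = counts / counts.sum() / widths if counts.sum() else counts
    ax.bar(edges[:-1], density, width=widths, align="edge", alpha=0.7)
    ax.set_xlabel("log posts per user")
    ax.set_ylabel("density")
    if platform:
        ax.set_title(platform)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_weekly_trend(series: TrendSeries, path) -> Path:
    """Per-week label proportions as lines, with event annotations."""
    fig, ax = plt.subplots(figsize=(10, 5))
    t = series.table
    x = list(t.index)
    for lab in LABELS:
        ax.plot(x, t[f"prop_{lab}"], marker="o", markersize=3, label=lab)
    for b, texts in sorted(series.events.items()):
        ax.axvline(b, color="grey", linestyle=":", linewidth=0.8)
        ax.annotate("; ".join(texts), (b, 1.0), fontsize=6, rotation=90, va="top")
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("proportion of posts")
    ax.set_xlabel("week start")
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
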