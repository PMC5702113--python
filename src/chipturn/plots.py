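"""Optional rendering of the summary tables (requires matplotlib).

Every figure here is a direct visualization of a table produced by
:mod:`chipturn.pipeline`; nothing is computed in this module.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install chipturn[plot])") from exc
    return plt


def plot_heatmap(heatmap: pd.DataFrame, path: str) -> None:
    """Loci x time heatmap of 0-1 scaled coverage, rows sorted by argmax time."""
    plt = _plt()
    order = np.argsort(heatmap.values.argmax(axis=1))
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(heatmap.values[order], aspect="auto", cmap="viridis")
    ax.set_xlabel("time point")
    ax.set_ylabel("locus")
    ax.set_xticks(range(len(heatmap.columns)))
    ax.set_xticklabels([f"{c:g}" for c in heatmap.columns], fontsize=7)
    fig.colorbar(im, ax=ax, label="scaled coverage")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_category_pie(proportions: pd.Series, path: str) -> None:
    plt = _plt()
    fig, ax = plt.subplots()
    ax.pie(proportions.values, labels=list(proportions.index), autopct="%.1f%%")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_tti_histogram(
    ttis: Sequence[float], bins, path: str, title: Optional[str] = None
) -> None:
    plt = _plt()
    fig, ax = plt.subplots()
    ax.hist(ttis, bins=bins)
    ax.set_xlabel("turnover time index")
    ax.set_ylabel("loci")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_feature_boxes(samples: dict, path: str) -> None:
    """Boxplot of TTI distributions per genome feature."""
    plt = _plt()
    names = list(samples)
    data = [[tti for _, tti in samples[n]] for n in names]
    fig, ax = plt.subplots()
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel("turnover time index")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
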