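"""Minimal stacked-area plots for observed/predicted compositions."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def stacked_area(
    profiles: Sequence[Mapping[str, float]],
    taxa: Sequence[str],
    path: str | Path,
    title: str = "",
    xlabel: str = "step",
) -> None:
    """Write a stacked-area plot of a sequence of compositions."""
    xs = range(1, len(profiles) + 1)
    ys = [[p.get(t, 0.0) for p in profiles] for t in taxa]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(xs, ys, labels=taxa)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("relative abundance")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1.0, 0.5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
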