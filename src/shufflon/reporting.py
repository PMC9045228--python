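"""Figures for variant-frequency and transfer-rate tables.

Bar charts show per-variant relative abundances with mean +/- SD whiskers
over biological replicates; the transfer heat map marks censored
(below-detection-limit) cells with a cross, following the convention used
for conjugation-frequency matrices.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["abundance_bar_chart", "transfer_heatmap"]

_ABUNDANCE_COLS = {"sample", "variant", "frequency"}
_HEATMAP_COLS = {"variant", "recipient", "frequency", "censored"}


def abundance_bar_chart(table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Per-variant frequency bars; replicates (rows sharing a variant)
    collapse to mean with SD whiskers, a single sample gets plain bars."""
    missing = _ABUNDANCE_COLS - set(table.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    grouped = table.groupby("variant")["frequency"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    replicated = table.groupby("variant").size().max() > 1
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(
        mean.index,
        mean.to_numpy(),
        yerr=sd.to_numpy() if replicated else None,
        capsize=3,
        color="steelblue",
    )
    ax.set_ylabel("relative abundance")
    ax.set_xlabel("pilV variant")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def transfer_heatmap(table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Variant-by-recipient log10 transfer-frequency heat map.

    Cells whose frequency is censored (at the limit of detection) are
    overlaid with a cross mark.
    """
    missing = _HEATMAP_COLS - set(table.columns)
    if missing:
        raise ValueError(f"heat-map table missing columns: {sorted(missing)}")
    pivot = table.pivot(index="variant", columns="recipient", values="frequency")
    censored = table.pivot(index="variant", columns="recipient", values="censored")
    data = np.log10(pivot.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2, 0.5 * len(pivot) + 2))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot)), pivot.index)
    for yi in range(len(pivot)):
        for xi in range(len(pivot.columns)):
            if bool(censored.iloc[yi, xi]):
                ax.plot(xi, yi, marker="x", color="white", markersize=10, mew=2)
    fig.colorbar(im, ax=ax, label="log10 conjugation frequency")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
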