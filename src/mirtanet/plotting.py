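"""Minimal diagnostic plots."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_ma(normalized: pd.DataFrame, array_id: str, path: str | Path):
    """MA plot of one array before and after lowess normalization.

    ``normalized`` is the frame produced by
    :func:`mirtanet.array_de.normalize_arrays`.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = normalized[normalized["array_id"] == array_id]
    if sub.empty:
        raise ValueError(f"array {array_id!r} not present")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, col, title in ((axes[0], "M_raw", "raw"),
                           (axes[1], "M", "lowess-normalized")):
        ax.scatter(sub["A"], sub[col], s=6, alpha=0.5)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("A (mean log2 intensity)")
        ax.set_title(f"{array_id} ({title})")
    axes[0].set_ylabel("M (log2 sample/reference)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
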