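"""Diagnostic figures: volcano plot and qPCR enrichment boxes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def volcano_plot(contrast: pd.DataFrame, path, alpha: float = 0.05,
                 fc_threshold: float = 1.2) -> None:
    """log2 FC versus -log10 q with the three-way hit coloring.

    Green: enriched (FC above threshold and q below alpha); golden:
    significant but below the FC threshold; blue: not significant.
    Zero q-values use the reporting substitution so -log10 is finite.
    """
    plt = _pyplot()
    frame = contrast.dropna(subset=["q"]).copy()
    q = frame["q"].to_numpy(dtype=float)
    nonzero = q[q > 0]
    if nonzero.size:
        q = np.where(q == 0, nonzero.min(), q)
    x = frame["x"].to_numpy(dtype=float)
    y = -np.log10(q)
    sig = frame["q"].to_numpy() < alpha
    high_fc = frame["FC"].to_numpy() > fc_threshold

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x[~sig], y[~sig], s=6, c="#4472c4", alpha=0.5, label=f"q > {alpha:g}")
    golden = sig & ~high_fc
    ax.scatter(x[golden], y[golden], s=6, c="#c49a00", alpha=0.7,
               label=f"q < {alpha:g}, FC < {fc_threshold:g}")
    hits = sig & high_fc
    ax.scatter(x[hits], y[hits], s=8, c="#2e9e3f", alpha=0.8,
               label=f"q < {alpha:g}, FC > {fc_threshold:g}")
    ax.axvline(np.log2(fc_threshold), ls="--", lw=0.8, c="grey")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="grey")
    ax.set_xlabel("log2 fold change (on-target vs untargeted labeling)")
    ax.set_ylabel("-log10 q")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def qpcr_box_plot(replicates: pd.DataFrame, path) -> None:
    """Box-and-whisker of per-replicate qPCR fold changes by condition."""
    plt = _pyplot()
    groups = {c: s["fc"].to_numpy() for c, s in replicates.groupby("condition")}
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(list(groups.values()), tick_labels=list(groups))
    ax.axhline(1.0, ls="--", lw=0.8, c="grey")
    ax.set_ylabel("fold change (2^-ddCt)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
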