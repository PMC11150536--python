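"""Matplotlib views: biplots with quadrant lines, pie summaries, heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import QuadrantThresholds


def biplot(metrics: pd.DataFrame, thresholds: QuadrantThresholds, locus: str, ax=None):
    """Scatter of (%MFI>1500, H_norm) for one locus with quadrant lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sub = metrics[(metrics["locus"] == locus) & metrics["included"]]
    ax.scatter(sub["pct_above_1500"], sub["h_norm"], s=6, alpha=0.4, lw=0)
    ax.axvline(thresholds.x_threshold, color="crimson", lw=1)
    ax.axhline(thresholds.y_threshold, color="crimson", lw=1)
    ax.set_xlim(-2, 102)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("%MFI > 1500")
    ax.set_ylabel(r"$H_{norm}$")
    ax.set_title(f"HLA-{locus}")
    return ax


def quadrant_pie(composition: pd.DataFrame, ax=None):
    """Pie of overall quadrant fractions from a composition table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    overall = composition[composition["stratum"] == "all"]
    ax.pie(
        overall["count"],
        labels=overall["quadrant"],
        autopct="%1.1f%%",
        startangle=90,
    )
    return ax


def elevation_heatmap(matrix: pd.DataFrame, ax=None, vmax: float | None = None):
    """Heatmap of the beads x risk-alleles elevation matrix (pct points)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(0.4 * max(matrix.shape[1], 4), 0.12 * max(matrix.shape[0], 10))
        )
    data = matrix.to_numpy(dtype=float)
    if vmax is None:
        vmax = np.nanmax(np.abs(data)) if data.size else 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("risk allele")
    ax.set_ylabel("antibody bead")
    ax.figure.colorbar(im, ax=ax, label="Δ producers (pct points)")
    return ax
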