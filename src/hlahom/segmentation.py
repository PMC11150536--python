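"""Biplot quadrant segmentation of (breadth, entropy) antibody profiles.

Each included individual x locus is a point with x = %MFI>1500 and
y = H_norm. Both axes are dichotomized (default: slope-weighted average
threshold computed from the pooled values; alternatively a fixed published
pair such as 49.5% / 0.579) and each point is labelled with a two-letter
quadrant code: first letter = breadth level, second = entropy level, so HH =
broad, uniformly high antibody producers, and HL (broad but spiky) is
expected to be empty in real sera.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

QUADRANTS = ("LL", "LH", "HH", "HL")


@dataclass(frozen=True)
class QuadrantThresholds:
    """Dichotomization thresholds for the breadth (x) and entropy (y) axes."""

    x_threshold: float
    y_threshold: float
    source: str = "computed"  # "computed" | "fixed"

    def __post_init__(self):
        if not 0.0 <= self.x_threshold <= 100.0:
            raise ValueError("x_threshold must be in [0, 100]")
        if not 0.0 <= self.y_threshold <= 1.0:
            raise ValueError("y_threshold must be in [0, 1]")


def slope_weighted_threshold(values) -> float:
    """Slope-weighted average of a 1-D sample, used as dichotomization cut.

    Sort the values ascending, weight the midpoint of each consecutive pair
    by the gap between them, and average:
    ``t = sum(g_i * (x_i + x_{i+1}) / 2) / sum(g_i)`` with
    ``g_i = x_{i+1} - x_i``. For a bimodal sample the large between-mode gap
    dominates, placing the cut between the modes. Degenerate (all-equal)
    samples return the common value with a warning.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two values to compute a threshold")
    gaps = np.diff(v)
    if gaps.sum() == 0:
        warnings.warn(
            "degenerate distribution: all values identical", stacklevel=2
        )
        return float(v[0])
    mids = (v[1:] + v[:-1]) / 2.0
    return float((gaps * mids).sum() / gaps.sum())


def compute_thresholds(
    metrics: pd.DataFrame,
    fixed: tuple[float, float] | None = None,
    per_locus: bool = False,
) -> QuadrantThresholds | dict[str, QuadrantThresholds]:
    """Thresholds from a metrics table, pooled (default) or per locus.

    ``fixed=(x, y)`` bypasses the computation, e.g. ``(49.5, 0.579)`` to use
    an externally published threshold pair.
    """
    if fixed is not None:
        t = QuadrantThresholds(float(fixed[0]), float(fixed[1]), source="fixed")
        if per_locus:
            return {locus: t for locus in metrics["locus"].unique()}
        return t
    incl = metrics[metrics["included"]]
    if per_locus:
        out = {}
        for locus, sub in incl.groupby("locus", sort=True):
            out[locus] = QuadrantThresholds(
                slope_weighted_threshold(sub["pct_above_1500"]),
                slope_weighted_threshold(sub["h_norm"]),
            )
        return out
    return QuadrantThresholds(
        slope_weighted_threshold(incl["pct_above_1500"]),
        slope_weighted_threshold(incl["h_norm"]),
    )


def assign_quadrants(
    metrics: pd.DataFrame,
    thresholds: QuadrantThresholds | dict[str, QuadrantThresholds],
) -> pd.DataFrame:
    """Label every included metrics row LL / LH / HH / HL.

    Values at or above a threshold are "high" (boundary ties go high).
    Not-included rows are skipped; the skipped count is reported via the
    returned frame's ``attrs["n_skipped"]``.
    """
    incl = metrics[metrics["included"]].copy()
    n_skipped = len(metrics) - len(incl)
    if isinstance(thresholds, dict):
        xt = incl["locus"].map(lambda l: thresholds[l].x_threshold)
        yt = incl["locus"].map(lambda l: thresholds[l].y_threshold)
    else:
        xt, yt = thresholds.x_threshold, thresholds.y_threshold
    x_high = incl["pct_above_1500"] >= xt
    y_high = incl["h_norm"] >= yt
    incl["quadrant"] = np.char.add(
        np.where(x_high, "H", "L"), np.where(y_high, "H", "L")
    )
    out = incl[["individual_id", "locus", "quadrant"]].reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def quadrant_composition(
    assignments: pd.DataFrame, strata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-quadrant counts and proportions, overall and per stratum.

    ``strata`` (optional) has columns ``individual_id, stratum`` (e.g.
    homozygous / heterozygous); rows without a stratum are excluded from the
    stratified part with a warning.
    """
    frames = []
    overall = assignments.groupby("quadrant", sort=True).size().reset_index(
        name="count"
    )
    overall.insert(0, "stratum", "all")
    overall["proportion"] = overall["count"] / overall["count"].sum()
    frames.append(overall)
    if strata is not None:
        merged = assignments.merge(strata, on="individual_id", how="left")
        n_missing = int(merged["stratum"].isna().sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} assignments without stratum excluded", stacklevel=2
            )
            merged = merged.dropna(subset=["stratum"])
        by = merged.groupby(["stratum", "quadrant"], sort=True).size().reset_index(
            name="count"
        )
        by["proportion"] = by["count"] / by.groupby("stratum")["count"].transform(
            "sum"
        )
        frames.append(by)
    return pd.concat(frames, ignore_index=True)
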