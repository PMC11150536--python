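"""Locus-wise and allele-wise homozygosity derived from an HLA typing table.

The typing table is long-format with one row per individual x locus and the
two allele calls as strings (``individual_id, locus, allele1, allele2``).
Homozygosity is decided after truncating both calls to a configurable field
depth (default 1 = allele group), so A*02:01 / A*02:05 is homozygous at
depth 1 and heterozygous at depth 2.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
import pandas as pd

from .alleles import LOCI, parse_allele

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
UNTYPED = "untyped"

TYPING_COLUMNS = ("individual_id", "locus", "allele1", "allele2")


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def _truncation_map(values: Iterable, depth: int) -> dict:
    """Map each distinct allele string to its depth-truncated group string."""
    out: dict = {}
    for v in set(values):
        if _is_blank(v):
            out[v] = None
        else:
            out[v] = str(parse_allele(v).truncate(depth))
    return out


def homozygosity_profiles(
    typing: pd.DataFrame,
    depth: int = 1,
    assume_blank_homozygous: bool = False,
) -> pd.DataFrame:
    """Per-individual, per-locus homozygosity flags.

    Parameters
    ----------
    typing:
        Long-format table with columns ``individual_id, locus, allele1,
        allele2``. At most one row per individual x locus.
    depth:
        Field depth at which the two calls are compared (1 = allele group).
    assume_blank_homozygous:
        When one of the two calls is blank, treat the locus as homozygous
        for the reported allele. Default is to treat it as typed but not
        homozygous (an unresolved second allele).

    Returns
    -------
    DataFrame with columns ``individual_id, locus, status,
    homozygous_group`` where status is homozygous / heterozygous / untyped
    and ``homozygous_group`` holds the shared truncated allele for
    homozygous loci (else NA).
    """
    missing = [c for c in TYPING_COLUMNS if c not in typing.columns]
    if missing:
        raise ValueError(f"typing table missing columns {missing}")
    dup = typing.duplicated(subset=["individual_id", "locus"])
    if dup.any():
        bad = typing.loc[dup, ["individual_id", "locus"]].iloc[0]
        raise ValueError(
            f"duplicate typing record for individual {bad['individual_id']!r} "
            f"locus {bad['locus']!r}"
        )
    unknown = set(typing["locus"]) - set(LOCI)
    if unknown:
        raise ValueError(f"unsupported loci in typing table: {sorted(unknown)}")

    trunc = _truncation_map(
        itertools.chain(typing["allele1"], typing["allele2"]), depth
    )
    g1 = typing["allele1"].map(trunc)
    g2 = typing["allele2"].map(trunc)

    both_blank = g1.isna() & g2.isna()
    one_blank = g1.isna() ^ g2.isna()
    equal = (g1 == g2) & ~g1.isna()

    status = np.where(
        both_blank,
        UNTYPED,
        np.where(
            equal | (one_blank & assume_blank_homozygous), HOMOZYGOUS, HETEROZYGOUS
        ),
    )
    group = pd.Series(
        np.where(status == HOMOZYGOUS, g1.fillna(g2), None), index=typing.index
    )
    out = pd.DataFrame(
        {
            "individual_id": typing["individual_id"],
            "locus": typing["locus"],
            "status": status,
            "homozygous_group": group,
        }
    )
    return out.sort_values(["individual_id", "locus"], kind="stable").reset_index(
        drop=True
    )


def degrees(profiles: pd.DataFrame) -> pd.DataFrame:
    """Homozygosity degree (count of homozygous loci) per individual."""
    g = profiles.groupby("individual_id", sort=True)
    out = pd.DataFrame(
        {
            "degree": g["status"].agg(lambda s: int((s == HOMOZYGOUS).sum())),
            "n_typed": g["status"].agg(lambda s: int((s != UNTYPED).sum())),
        }
    ).reset_index()
    return out


def prevalence_summary(profiles: pd.DataFrame) -> dict:
    """Cohort-level homozygosity prevalence.

    Returns a dict of three DataFrames:

    - ``degree_distribution``: count and proportion of individuals per
      homozygosity degree (0-8).
    - ``combinations``: within each degree >= 1, the proportion of each
      combination of homozygous loci (``"DPA1+DPB1"`` style keys, ordered
      by canonical locus order); proportions sum to 1 within a degree.
    - ``locus_fractions``: per-locus homozygote fraction, using only
      individuals typed at the locus as denominator.
    """
    if profiles.empty:
        raise ValueError("empty cohort: no homozygosity profiles")

    deg = degrees(profiles)
    counts = deg["degree"].value_counts().sort_index()
    degree_distribution = pd.DataFrame(
        {
            "degree": counts.index,
            "count": counts.values,
            "proportion": counts.values / counts.values.sum(),
        }
    )

    order = {locus: i for i, locus in enumerate(LOCI)}
    hom = profiles[profiles["status"] == HOMOZYGOUS]
    combos = (
        hom.groupby("individual_id", sort=True)["locus"]
        .agg(lambda loci: "+".join(sorted(loci, key=order.__getitem__)))
        .reset_index(name="combination")
    )
    combos["degree"] = combos["combination"].str.count(r"\+") + 1
    combo_counts = (
        combos.groupby(["degree", "combination"], sort=True)
        .size()
        .reset_index(name="count")
    )
    combo_counts["proportion"] = combo_counts["count"] / combo_counts.groupby(
        "degree"
    )["count"].transform("sum")

    typed = profiles[profiles["status"] != UNTYPED]
    per_locus = typed.groupby("locus", sort=False).agg(
        n_typed=("status", "size"),
        n_homozygous=("status", lambda s: int((s == HOMOZYGOUS).sum())),
    )
    per_locus = per_locus.reindex([l for l in LOCI if l in per_locus.index])
    per_locus["fraction_homozygous"] = (
        per_locus["n_homozygous"] / per_locus["n_typed"]
    )
    locus_fractions = per_locus.reset_index()

    return {
        "degree_distribution": degree_distribution,
        "combinations": combo_counts,
        "locus_fractions": locus_fractions,
    }


def allele_homozygote_census(
    profiles: pd.DataFrame, min_homozygotes: int = 10
) -> pd.DataFrame:
    """Allele groups with strictly more than ``min_homozygotes`` homozygotes.

    For each retained allele group, ``n_heterozygous`` counts every
    individual typed at the locus who is *not* homozygous for that group
    (non-carriers included).
    """
    hom = profiles[profiles["status"] == HOMOZYGOUS]
    typed_per_locus = (
        profiles[profiles["status"] != UNTYPED].groupby("locus").size()
    )
    if hom.empty:
        return pd.DataFrame(
            columns=["locus", "allele_group", "n_homozygous", "n_heterozygous"]
        )
    counts = (
        hom.groupby(["locus", "homozygous_group"], sort=True)
        .size()
        .reset_index(name="n_homozygous")
        .rename(columns={"homozygous_group": "allele_group"})
    )
    counts = counts[counts["n_homozygous"] > min_homozygotes].copy()
    counts["n_heterozygous"] = (
        counts["locus"].map(typed_per_locus) - counts["n_homozygous"]
    ).astype(int)
    order = {locus: i for i, locus in enumerate(LOCI)}
    counts["_o"] = counts["locus"].map(order)
    counts = counts.sort_values(["_o", "allele_group"], kind="stable").drop(
        columns="_o"
    )
    return counts.reset_index(drop=True)
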