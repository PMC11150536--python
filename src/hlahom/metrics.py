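"""Per-individual, per-locus antibody repertoire statistics.

Two complementary measures are computed over the single-antigen beads of one
locus:

- breadth: the percentage of beads whose MFI strictly exceeds the positivity
  cutoff (manufacturer-recommended 1,500 fluorescence units);
- specificity: the normalized Shannon entropy ``H_norm = H / log2(N)`` of the
  relative per-bead MFI distribution ``p_i = MFI_i / sum(MFI)``, ranging from
  0 (a single dominant antibody) to 1 (perfectly uniform reactivity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 1500.0

METRICS_COLUMNS = (
    "individual_id",
    "locus",
    "hla_class",
    "n_beads",
    "pct_above_1500",
    "h_norm",
    "included",
)


def _clean_mfi(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("MFI values must be finite")
    return np.clip(v, 0.0, None)  # negative Luminex exports clamp to 0


def pct_above_cutoff(values, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Percentage of beads with MFI strictly above ``cutoff`` (0-100)."""
    v = _clean_mfi(values)
    if v.size == 0:
        raise ValueError("no beads supplied")
    return 100.0 * float((v > cutoff).sum()) / v.size


def normalized_entropy(values) -> float:
    """Normalized Shannon entropy of a bead MFI profile.

    ``H = -sum(p_i log2 p_i)`` with ``p_i = MFI_i / sum(MFI)`` and the
    ``0 * log 0 = 0`` convention, normalized by ``log2(N)``. Returns NaN when
    the metric is undefined (fewer than two beads, or all MFIs zero).
    """
    v = _clean_mfi(values)
    if v.size < 2:
        return float("nan")
    total = v.sum()
    if total <= 0:
        return float("nan")
    p = v / total
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return float(h / np.log2(v.size) + 0.0)  # +0.0 normalizes -0.0


def metrics_table(
    antibodies: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    mask_self: bool = False,
    typing: pd.DataFrame | None = None,
    duplicate_policy: str = "max",
) -> pd.DataFrame:
    """Breadth and entropy for every individual x locus with antibody data.

    Parameters
    ----------
    antibodies:
        Long-format bead table (``individual_id, hla_class, bead_id, locus,
        target_allele, mfi``).
    cutoff:
        MFI positivity cutoff for the breadth measure.
    mask_self:
        Drop beads whose target allele group is carried by the individual
        (requires ``typing``); N shrinks accordingly before both metrics.
    duplicate_policy:
        How duplicate (individual, locus, target) beads are merged:
        ``"max"`` (default), ``"mean"`` or ``"error"``.

    Rows whose entropy is undefined (single bead or all-zero MFI after
    masking) carry ``included=False`` and NaN entropy.
    """
    required = {"individual_id", "locus", "target_allele", "mfi"}
    missing = required - set(antibodies.columns)
    if missing:
        raise ValueError(f"antibody table missing columns {sorted(missing)}")
    df = antibodies.copy()
    df["mfi"] = _clean_mfi(df["mfi"].to_numpy())

    dup_key = ["individual_id", "locus", "target_allele"]
    if df.duplicated(subset=dup_key).any():
        if duplicate_policy == "error":
            raise ValueError("duplicate bead targets within an individual profile")
        agg = {"mfi": duplicate_policy}
        keep = {
            c: "first" for c in df.columns if c not in dup_key and c != "mfi"
        }
        df = df.groupby(dup_key, sort=False, as_index=False).agg({**agg, **keep})

    if mask_self:
        if typing is None:
            raise ValueError("mask_self requires a typing table")
        carried = typing.melt(
            id_vars=["individual_id", "locus"],
            value_vars=["allele1", "allele2"],
            value_name="allele",
        ).dropna(subset=["allele"])
        carried = carried[carried["allele"].astype(str).str.strip() != ""]
        carried["group"] = (
            carried["allele"].astype(str).str.split("*").str[-1].str.split(":").str[0]
        )
        carried = carried[["individual_id", "locus", "group"]].drop_duplicates()
        carried["_self"] = True
        df["group"] = df["target_allele"].str.split(":").str[0]
        df = df.merge(carried, on=["individual_id", "locus", "group"], how="left")
        df = df[df["_self"].isna()].drop(columns=["group", "_self"])

    if df.empty:
        return pd.DataFrame(columns=list(METRICS_COLUMNS))

    g = df.groupby(["individual_id", "locus"], sort=True)
    total = g["mfi"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, df["mfi"] / total, 0.0)
        logp = np.log2(p, out=np.zeros_like(p), where=p > 0)
        term = np.where(p > 0, -p * logp, 0.0)
    df = df.assign(_term=term, _pos=(df["mfi"] > cutoff).astype(float))

    out = g.agg(
        n_beads=("mfi", "size"),
        _total=("mfi", "sum"),
    )
    out["pct_above_1500"] = df.groupby(["individual_id", "locus"], sort=True)[
        "_pos"
    ].mean() * 100.0
    out["_H"] = df.groupby(["individual_id", "locus"], sort=True)["_term"].sum()
    if "hla_class" in df.columns:
        out["hla_class"] = df.groupby(["individual_id", "locus"], sort=True)[
            "hla_class"
        ].first()
    else:
        out["hla_class"] = pd.NA
    out = out.reset_index()

    computable = (out["n_beads"] >= 2) & (out["_total"] > 0)
    out["h_norm"] = np.where(
        computable, out["_H"] / np.log2(out["n_beads"].clip(lower=2)), np.nan
    )
    out["included"] = computable
    out = out[list(METRICS_COLUMNS)]
    return out.reset_index(drop=True)
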