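"""Association testing between homozygosity and antibody repertoire shape.

Locus level: Wilcoxon rank-sum on breadth and entropy, and a Freeman-Halton
(Fisher exact r x c) test on the populated-quadrant x zygosity table.
Allele level: the same Fisher test for every allele group with enough
homozygotes, Bonferroni-corrected over the screened family. Per-bead
elevation profiles quantify, for each risk allele, the difference in the
proportion of antibody producers (MFI > cutoff) between homozygous and
heterozygous individuals, over every bead of both panels.

All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .alleles import LOCI
from .metrics import DEFAULT_CUTOFF
from .zygosity import HETEROZYGOUS, HOMOZYGOUS, UNTYPED

_REL_TOL = 1e-7  # tie tolerance when comparing table point probabilities


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first group
    pvalue: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class FisherResult:
    pvalue: float
    method: str  # "enumeration" | "monte_carlo"
    se: float | None = None  # Monte-Carlo standard error, if applicable


def wilcoxon_rank_sum(group_a, group_b, exact_limit: int = 10) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact null distribution when the smaller group has <= ``exact_limit``
    observations and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= exact_limit and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    rank_sum = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return WilcoxonResult(rank_sum, float(res.pvalue), method)


def _log_point_prob(table: np.ndarray, const: float) -> float:
    return const - gammaln(table + 1).sum()


def _enumerate_free2(rows: np.ndarray, cols: np.ndarray, log_obs: float) -> float:
    """Vectorized Freeman-Halton for tables with (r-1)(c-1) <= 2 and c == 2.

    Enumerates the first column's free cells on a grid; covers 2x2 and 3x2.
    """
    r = rows.size
    c1 = cols[0]
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(rows.sum() + 1)
    if r == 2:
        a1 = np.arange(max(0, c1 - rows[1]), min(rows[0], c1) + 1)
        cells = np.stack(
            [a1, rows[0] - a1, c1 - a1, rows[1] - (c1 - a1)], axis=1
        )
        logp = const - gammaln(cells + 1).sum(axis=1)
    else:  # r == 3
        a1 = np.arange(0, min(rows[0], c1) + 1)
        a2 = np.arange(0, min(rows[1], c1) + 1)
        g1, g2 = np.meshgrid(a1, a2, indexing="ij")
        a3 = c1 - g1 - g2
        valid = (a3 >= 0) & (a3 <= rows[2])
        g1, g2, a3 = g1[valid], g2[valid], a3[valid]
        cells = np.stack(
            [g1, rows[0] - g1, g2, rows[1] - g2, a3, rows[2] - a3], axis=1
        )
        logp = const - gammaln(cells + 1).sum(axis=1)
    keep = logp <= log_obs + np.log1p(_REL_TOL)
    return float(np.exp(logp[keep]).sum())


class _BudgetExceeded(Exception):
    pass


def _enumerate_general(
    rows: np.ndarray, cols: np.ndarray, log_obs: float, max_tables: int
) -> float:
    """Recursive enumeration of all tables with the given margins."""
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(rows.sum() + 1)
    total = 0.0
    count = 0
    thresh = log_obs + np.log1p(_REL_TOL)

    def rec(i: int, remaining_cols: np.ndarray, log_acc: float) -> None:
        nonlocal total, count
        if i == rows.size - 1:
            # last row is forced
            count += 1
            if count > max_tables:
                raise _BudgetExceeded
            logp = log_acc - gammaln(remaining_cols + 1).sum()
            if logp <= thresh:
                total += np.exp(logp)
            return
        for comp in _compositions(rows[i], remaining_cols):
            rec(
                i + 1,
                remaining_cols - comp,
                log_acc - gammaln(comp + 1).sum(),
            )

    rec(0, cols.astype(int).copy(), float(const))
    return total


def _compositions(total: int, bounds: np.ndarray):
    """All non-negative integer vectors summing to ``total`` within bounds."""
    k = bounds.size
    vec = np.zeros(k, dtype=int)

    def rec(j: int, rem: int):
        if j == k - 1:
            if rem <= bounds[j]:
                vec[j] = rem
                yield vec.copy()
            return
        lo = max(0, rem - int(bounds[j + 1 :].sum()))
        hi = min(int(bounds[j]), rem)
        for v in range(lo, hi + 1):
            vec[j] = v
            yield from rec(j + 1, rem - v)

    yield from rec(0, int(total))


def fisher_exact_rxc(
    table,
    max_tables: int = 5_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    Freeman-Halton rule: the p-value is the total null probability (margins
    fixed) of all tables whose point probability does not exceed that of the
    observed table. Exact enumeration is used while the number of candidate
    tables stays within ``max_tables``; beyond that a seeded Monte-Carlo
    sample of ``n_mc`` tables (Patefield's algorithm) estimates the p-value,
    with its standard error reported.
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        ti = np.asarray(np.rint(t), dtype=int)
        if not np.allclose(t, ti):
            raise ValueError("table entries must be integers")
        t = ti
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")

    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        t = t[keep_rows][:, keep_cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return FisherResult(1.0, "enumeration")

    # orient so columns are the smaller dimension
    if t.shape[1] > t.shape[0]:
        t = t.T
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(t.sum() + 1)
    log_obs = _log_point_prob(t, const)

    if t.shape[1] == 2 and t.shape[0] <= 3:
        grid = np.prod([min(int(r), int(cols[0])) + 1 for r in rows[:-1]])
        if grid <= max_tables:
            p = _enumerate_free2(rows, cols, log_obs)
            return FisherResult(min(p, 1.0), "enumeration")
    else:
        try:
            p = _enumerate_general(rows, cols, log_obs, max_tables)
            return FisherResult(min(p, 1.0), "enumeration")
        except _BudgetExceeded:
            pass

    rng = np.random.default_rng(seed)
    sampler = sps.random_table(rows, cols)
    draws = sampler.rvs(n_mc, random_state=rng)
    logp = const - gammaln(draws + 1).sum(axis=(1, 2))
    hits = logp <= log_obs + np.log1p(_REL_TOL)
    p_hat = float(hits.mean())
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_mc))
    return FisherResult(p_hat, "monte_carlo", se)


# ---------------------------------------------------------------------------
# pipeline-level association tables
# ---------------------------------------------------------------------------

_QUADRANT_ORDER = ("LL", "LH", "HH", "HL")

RESULT_COLUMNS = (
    "target",
    "target_type",
    "test",
    "n_homozygous",
    "n_heterozygous",
    "statistic",
    "p_raw",
    "p_bonferroni",
    "n_LL_hom",
    "n_LL_het",
    "n_LH_hom",
    "n_LH_het",
    "n_HH_hom",
    "n_HH_het",
    "n_HL_hom",
    "n_HL_het",
    "hh_prop_hom",
    "hh_prop_het",
)


def _quadrant_table(assign_status: pd.DataFrame) -> tuple[np.ndarray, dict, list]:
    """3(or fewer) x 2 quadrant-by-zygosity table; empty quadrants dropped."""
    counts = {}
    for q in _QUADRANT_ORDER:
        sub = assign_status[assign_status["quadrant"] == q]
        counts[q] = (
            int((sub["_hom"]).sum()),
            int((~sub["_hom"]).sum()),
        )
    populated = [q for q in _QUADRANT_ORDER if sum(counts[q]) > 0]
    table = np.array([counts[q] for q in populated], dtype=int)
    return table, counts, populated


def _fisher_row(assign_status: pd.DataFrame, target: str, target_type: str) -> dict:
    table, counts, populated = _quadrant_table(assign_status)
    n_hom = int(assign_status["_hom"].sum())
    n_het = int((~assign_status["_hom"]).sum())
    res = fisher_exact_rxc(table) if len(populated) >= 2 else FisherResult(1.0, "enumeration")
    hh_hom, hh_het = counts["HH"]
    row = {
        "target": target,
        "target_type": target_type,
        "test": "fisher_quadrants",
        "n_homozygous": n_hom,
        "n_heterozygous": n_het,
        "statistic": np.nan,
        "p_raw": res.pvalue,
        "hh_prop_hom": hh_hom / n_hom if n_hom else np.nan,
        "hh_prop_het": hh_het / n_het if n_het else np.nan,
    }
    for q in _QUADRANT_ORDER:
        row[f"n_{q}_hom"], row[f"n_{q}_het"] = counts[q]
    return row


def locus_association(
    metrics: pd.DataFrame,
    assignments: pd.DataFrame,
    profiles: pd.DataFrame,
    min_per_stratum: int = 2,
) -> pd.DataFrame:
    """Locus-level homozygous-vs-heterozygous tests.

    For every locus with at least ``min_per_stratum`` individuals in each
    zygosity stratum: Wilcoxon rank-sum on %MFI>1500, Wilcoxon rank-sum on
    H_norm, and the Fisher exact test on the populated quadrant x zygosity
    table. Bonferroni correction is per test family across tested loci.
    """
    status = profiles[profiles["status"] != UNTYPED][
        ["individual_id", "locus", "status"]
    ]
    m = metrics[metrics["included"]].merge(
        status, on=["individual_id", "locus"], how="inner"
    )
    a = assignments.merge(status, on=["individual_id", "locus"], how="inner")
    rows = []
    for locus in [l for l in LOCI if l in set(m["locus"])]:
        sub = m[m["locus"] == locus]
        hom = sub[sub["status"] == HOMOZYGOUS]
        het = sub[sub["status"] == HETEROZYGOUS]
        if len(hom) < min_per_stratum or len(het) < min_per_stratum:
            warnings.warn(
                f"locus {locus}: fewer than {min_per_stratum} individuals in a "
                "stratum; skipped",
                stacklevel=2,
            )
            continue
        for test, col in (
            ("wilcoxon_pct", "pct_above_1500"),
            ("wilcoxon_entropy", "h_norm"),
        ):
            res = wilcoxon_rank_sum(hom[col], het[col])
            rows.append(
                {
                    "target": locus,
                    "target_type": "locus",
                    "test": test,
                    "n_homozygous": len(hom),
                    "n_heterozygous": len(het),
                    "statistic": res.statistic,
                    "p_raw": res.pvalue,
                }
            )
        asub = a[a["locus"] == locus].copy()
        asub["_hom"] = asub["status"] == HOMOZYGOUS
        rows.append(_fisher_row(asub, locus, "locus"))
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    out["p_bonferroni"] = out.groupby("test")["p_raw"].transform(
        lambda p: np.minimum(1.0, p * p.size)
    )
    return out.reindex(columns=list(RESULT_COLUMNS)).reset_index(drop=True)


def allele_screen(
    assignments: pd.DataFrame,
    census: pd.DataFrame,
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    min_per_stratum: int = 2,
) -> pd.DataFrame:
    """Fisher quadrant test for every allele group in the homozygote census.

    For each allele group the homozygous stratum is the individuals
    homozygous for that group; the heterozygous stratum is everyone else
    typed at the locus (non-carriers included). Bonferroni correction is
    over the number of alleles actually tested. ``significant`` flags
    p_raw < ``alpha``.
    """
    typed = profiles[profiles["status"] != UNTYPED]
    rows = []
    for rec in census.itertuples():
        locus, group = rec.locus, rec.allele_group
        loc = typed[typed["locus"] == locus]
        hom_ids = set(
            loc[
                (loc["status"] == HOMOZYGOUS)
                & (loc["homozygous_group"] == group)
            ]["individual_id"]
        )
        asub = assignments[assignments["locus"] == locus].merge(
            loc[["individual_id"]], on="individual_id"
        )
        asub = asub.copy()
        asub["_hom"] = asub["individual_id"].isin(hom_ids)
        if (
            asub["_hom"].sum() < min_per_stratum
            or (~asub["_hom"]).sum() < min_per_stratum
        ):
            warnings.warn(
                f"allele {group}: fewer than {min_per_stratum} individuals with "
                "antibody data in a stratum; skipped",
                stacklevel=2,
            )
            continue
        rows.append(_fisher_row(asub, group, "allele"))
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(columns=list(RESULT_COLUMNS))
        out["significant"] = pd.Series(dtype=bool)
        return out
    n_tested = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * n_tested)
    out = out.reindex(columns=list(RESULT_COLUMNS))
    out["significant"] = out["p_raw"] < alpha
    return out.reset_index(drop=True)


def elevation_profiles(
    antibodies: pd.DataFrame,
    risk_alleles: pd.DataFrame,
    profiles: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bead producer-proportion differences for each risk allele.

    ``risk_alleles`` needs columns ``locus, allele_group``. For every bead
    in the antibody table, Delta = 100 x (proportion of allele-homozygous
    individuals with bead MFI > cutoff minus the same proportion among the
    heterozygous stratum), in percentage points. Beads untested in a stratum
    yield missing values.

    Returns ``(long, matrix)``: a tidy frame and a beads x risk-alleles
    pivot whose rows are ordered by class/locus.
    """
    typed = profiles[profiles["status"] != UNTYPED]
    ab = antibodies.copy()
    ab["_pos"] = (ab["mfi"] > cutoff).astype(float)
    frames = []
    for rec in risk_alleles.itertuples():
        locus, group = rec.locus, rec.allele_group
        loc = typed[typed["locus"] == locus]
        hom_ids = set(
            loc[
                (loc["status"] == HOMOZYGOUS)
                & (loc["homozygous_group"] == group)
            ]["individual_id"]
        )
        het_ids = set(loc["individual_id"]) - hom_ids
        sub = ab[ab["individual_id"].isin(hom_ids | het_ids)].copy()
        sub["_hom"] = sub["individual_id"].isin(hom_ids)
        agg = sub.groupby(["bead_id", "locus", "target_allele", "hla_class", "_hom"])[
            "_pos"
        ].agg(["mean", "size"]).unstack("_hom")
        prop_hom = agg[("mean", True)] if ("mean", True) in agg else pd.Series(np.nan, index=agg.index)
        prop_het = agg[("mean", False)] if ("mean", False) in agg else pd.Series(np.nan, index=agg.index)
        n_hom = agg[("size", True)] if ("size", True) in agg else pd.Series(0, index=agg.index)
        n_het = agg[("size", False)] if ("size", False) in agg else pd.Series(0, index=agg.index)
        frame = agg.index.to_frame(index=False)
        frame["risk_allele"] = group
        frame["delta_pct"] = (100.0 * (prop_hom - prop_het)).to_numpy()
        frame["n_hom_tested"] = n_hom.fillna(0).astype(int).to_numpy()
        frame["n_het_tested"] = n_het.fillna(0).astype(int).to_numpy()
        frames.append(frame)
    if not frames:
        long = pd.DataFrame(
            columns=[
                "risk_allele",
                "bead_id",
                "locus",
                "target_allele",
                "hla_class",
                "delta_pct",
                "n_hom_tested",
                "n_het_tested",
            ]
        )
        return long, pd.DataFrame()
    long = pd.concat(frames, ignore_index=True)[
        [
            "risk_allele",
            "bead_id",
            "locus",
            "target_allele",
            "hla_class",
            "delta_pct",
            "n_hom_tested",
            "n_het_tested",
        ]
    ]
    order = {locus: i for i, locus in enumerate(LOCI)}
    matrix = long.pivot_table(
        index=["hla_class", "locus", "bead_id"],
        columns="risk_allele",
        values="delta_pct",
        sort=False,
    )
    matrix = matrix.sort_index(
        key=lambda idx: idx.map(order) if idx.name == "locus" else idx
    )
    return long, matrix
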