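import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hlahom.stats import (
    allele_screen,
    elevation_profiles,
    fisher_exact_rxc,
    locus_association,
    wilcoxon_rank_sum,
)
from hlahom.zygosity import HETEROZYGOUS, HOMOZYGOUS


# ---------------------------------------------------------------- oracles
def rank_sum_permutation_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()  # midranks
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = [
        sum(combo) for combo in itertools.combinations(ranks, n_a)
    ]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(sums)


def fisher_brute_force_p(table):
    """Freeman-Halton p by exact Fraction arithmetic over all tables with the
    observed margins."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()

    def point_prob(cells):
        num = Fraction(1)
        for r in rows:
            num *= math.factorial(int(r))
        for c in cols:
            num *= math.factorial(int(c))
        den = Fraction(math.factorial(int(n)))
        for x in cells:
            den *= math.factorial(int(x))
        return num / den

    def tables(row_idx, remaining_cols):
        if row_idx == len(rows) - 1:
            yield list(remaining_cols)
            return
        r = int(rows[row_idx])
        bounds = [int(c) for c in remaining_cols]

        def comps(j, rem):
            if j == len(bounds) - 1:
                if rem <= bounds[j]:
                    yield [rem]
                return
            for v in range(min(bounds[j], rem) + 1):
                for rest in comps(j + 1, rem - v):
                    yield [v] + rest

        for comp in comps(0, r):
            rest_cols = [c - x for c, x in zip(bounds, comp)]
            for tail in tables(row_idx + 1, rest_cols):
                yield comp + tail

    p_obs = point_prob(t.flatten())
    total = Fraction(0)
    for cells in tables(0, cols):
        p = point_prob(cells)
        if p <= p_obs:
            total += p
    return float(total)


# ---------------------------------------------------------------- wilcoxon
def test_wilcoxon_identical_groups():
    a = [1.0, 2.0, 3.0, 4.0]
    res = wilcoxon_rank_sum(a, a)
    assert res.pvalue >= 0.99


def test_wilcoxon_fully_separated_small_groups():
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(0.1, abs=1e-12)  # 2 * (1/20)


def test_wilcoxon_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        wilcoxon_rank_sum([], [1.0])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_wilcoxon_exact_matches_full_permutation(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=8)
    b = rng.normal(0.5, size=8)
    res = wilcoxon_rank_sum(a, b)
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(rank_sum_permutation_p(a, b), abs=1e-12)


def test_wilcoxon_ties_fall_back_to_asymptotic():
    a = [1.0, 2.0, 2.0, 3.0]
    b = [2.0, 4.0, 5.0, 6.0]
    res = wilcoxon_rank_sum(a, b)
    assert res.method == "asymptotic"
    assert 0 < res.pvalue <= 1


# ---------------------------------------------------------------- fisher
def test_fisher_2x2_hand_enumeration():
    # hypergeometric point probs {1,16,36,16,1}/70 -> p = 34/70
    res = fisher_exact_rxc([[3, 1], [1, 3]])
    assert res.method == "enumeration"
    assert res.pvalue == pytest.approx(34 / 70, abs=1e-12)


def test_fisher_matches_reference_implementation():
    """Frozen p-values computed with R's fisher.test (stats 4.3.3)."""
    cases = [
        ([[5, 2, 1], [1, 4, 2], [2, 1, 6]], 0.077897401896),
        ([[8, 2], [3, 5], [1, 9]], 0.005256205633),
        ([[1, 0, 3], [2, 5, 0], [4, 2, 2], [0, 1, 6]], 0.004994456034),
    ]
    for table, expected in cases:
        assert fisher_exact_rxc(table).pvalue == pytest.approx(expected, abs=1e-9)


def test_fisher_independence_large_margins():
    res = fisher_exact_rxc([[40, 40], [40, 40], [40, 40]])
    assert res.pvalue >= 0.99


def test_fisher_zero_margin_dropped():
    with pytest.warns(UserWarning, match="zero-margin"):
        res = fisher_exact_rxc([[3, 1, 0], [1, 3, 0]])
    assert res.pvalue == pytest.approx(34 / 70, abs=1e-12)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_fisher_enumeration_matches_brute_force_3x2(seed):
    rng = np.random.default_rng(seed)
    table = rng.integers(0, 8, size=(3, 2))
    table[0, 0] += 1  # avoid all-zero corner cases
    assert fisher_exact_rxc(table).pvalue == pytest.approx(
        fisher_brute_force_p(table), rel=1e-9, abs=1e-12
    )


def test_fisher_monte_carlo_agrees_with_enumeration():
    table = [[9, 3], [4, 8], [2, 10]]
    exact = fisher_exact_rxc(table)
    mc = fisher_exact_rxc(table, max_tables=5, n_mc=100_000, seed=3)
    assert mc.method == "monte_carlo"
    assert mc.se is not None
    assert abs(mc.pvalue - exact.pvalue) < 3 * mc.se


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError, match="non-negative"):
        fisher_exact_rxc([[1, -1], [2, 3]])
    with pytest.raises(ValueError, match="integers"):
        fisher_exact_rxc([[1.5, 1], [2, 3]])


# ------------------------------------------------------- pipeline stats
def _profiles(rows):
    return pd.DataFrame(
        rows, columns=["individual_id", "locus", "status", "homozygous_group"]
    )


def test_allele_screen_perfectly_separated():
    """10 homozygotes all HH vs 10 heterozygotes all LH: the two-sided
    Freeman-Halton p equals 2 / C(20,10) (both extreme tables are equally
    improbable under the hypergeometric null)."""
    rows, assigns = [], []
    for i in range(10):
        rows.append((f"h{i}", "A", HOMOZYGOUS, "A*01"))
        assigns.append((f"h{i}", "A", "HH"))
    for i in range(10):
        rows.append((f"g{i}", "A", HETEROZYGOUS, None))
        assigns.append((f"g{i}", "A", "LH"))
    census = pd.DataFrame(
        [("A", "A*01", 10, 10)],
        columns=["locus", "allele_group", "n_homozygous", "n_heterozygous"],
    )
    assignments = pd.DataFrame(
        assigns, columns=["individual_id", "locus", "quadrant"]
    )
    out = allele_screen(assignments, census, _profiles(rows))
    assert len(out) == 1
    assert out.iloc[0]["p_raw"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
    assert out.iloc[0]["significant"]
    assert out.iloc[0]["hh_prop_hom"] == 1.0
    assert out.iloc[0]["hh_prop_het"] == 0.0


def test_bonferroni_invariants(small_cohort):
    from hlahom.metrics import metrics_table
    from hlahom.segmentation import assign_quadrants, compute_thresholds
    from hlahom.zygosity import allele_homozygote_census, homozygosity_profiles

    _, typing, antibodies, _ = small_cohort
    m = metrics_table(antibodies)
    a = assign_quadrants(m, compute_thresholds(m))
    prof = homozygosity_profiles(typing)
    census = allele_homozygote_census(prof, min_homozygotes=10)
    screen = allele_screen(a, census, prof)
    assert (screen["p_bonferroni"] >= screen["p_raw"] - 1e-15).all()
    assert (
        (screen["p_bonferroni"] < 0.05).sum() <= (screen["p_raw"] < 0.05).sum()
    )
    # screened set respects the census filter (> 10 homozygotes)
    assert set(screen["target"]) <= set(census["allele_group"])
    assert (census["n_homozygous"] > 10).all()


def test_locus_association_direction_under_effect(small_cohort):
    """With a positive homozygosity effect, the HH proportion is higher in
    homozygous individuals wherever the strata are populated."""
    from hlahom.metrics import metrics_table
    from hlahom.segmentation import assign_quadrants, compute_thresholds
    from hlahom.zygosity import homozygosity_profiles

    _, typing, antibodies, _ = small_cohort
    m = metrics_table(antibodies)
    a = assign_quadrants(m, compute_thresholds(m))
    prof = homozygosity_profiles(typing)
    res = locus_association(m, a, prof)
    fisher = res[res["test"] == "fisher_quadrants"]
    assert len(fisher) == 8
    big = fisher[(fisher["n_homozygous"] >= 50) & (fisher["n_heterozygous"] >= 50)]
    assert (big["hh_prop_hom"] >= big["hh_prop_het"]).all()
    # quadrant margins add up to the stratum sizes
    for rec in fisher.to_dict(orient="records"):
        hom_margin = sum(rec[f"n_{q}_hom"] for q in ("LL", "LH", "HH", "HL"))
        het_margin = sum(rec[f"n_{q}_het"] for q in ("LL", "LH", "HH", "HL"))
        assert hom_margin == rec["n_homozygous"]
        assert het_margin == rec["n_heterozygous"]


def test_locus_association_skips_thin_strata():
    m = pd.DataFrame(
        {
            "individual_id": ["p1", "p2", "p3"],
            "locus": "A",
            "hla_class": "I",
            "n_beads": 10,
            "pct_above_1500": [10.0, 20.0, 30.0],
            "h_norm": [0.5, 0.6, 0.7],
            "included": True,
        }
    )
    a = pd.DataFrame(
        {"individual_id": ["p1", "p2", "p3"], "locus": "A", "quadrant": ["LH", "LH", "HH"]}
    )
    prof = _profiles(
        [("p1", "A", HOMOZYGOUS, "A*01"), ("p2", "A", HETEROZYGOUS, None),
         ("p3", "A", HETEROZYGOUS, None)]
    )
    with pytest.warns(UserWarning, match="skipped"):
        res = locus_association(m, a, prof)
    assert res.empty


# ------------------------------------------------------- elevation
def _ab(rows):
    return pd.DataFrame(
        rows,
        columns=["individual_id", "hla_class", "bead_id", "locus", "target_allele", "mfi"],
    )


def test_elevation_zero_for_identical_strata():
    rows = []
    for pid in ("h1", "h2", "g1", "g2"):
        rows += [(pid, "I", "A*01:01", "A", "01:01", 2000.0),
                 (pid, "I", "A*02:01", "A", "02:01", 100.0)]
    prof = _profiles(
        [("h1", "A", HOMOZYGOUS, "A*03"), ("h2", "A", HOMOZYGOUS, "A*03"),
         ("g1", "A", HETEROZYGOUS, None), ("g2", "A", HETEROZYGOUS, None)]
    )
    risk = pd.DataFrame([("A", "A*03")], columns=["locus", "allele_group"])
    long, matrix = elevation_profiles(_ab(rows), risk, prof)
    assert (long["delta_pct"] == 0).all()


def test_elevation_direct_subtraction():
    rows = []
    # 4/5 homozygous produce the bead, 1/5 wrongly low; heterozygous 30%
    for i in range(5):
        rows.append((f"h{i}", "I", "A*01:01", "A", "01:01",
                     5000.0 if i < 4 else 100.0))
    for i in range(10):
        rows.append((f"g{i}", "I", "A*01:01", "A", "01:01",
                     5000.0 if i < 3 else 100.0))
    prof = _profiles(
        [(f"h{i}", "A", HOMOZYGOUS, "A*01") for i in range(5)]
        + [(f"g{i}", "A", HETEROZYGOUS, None) for i in range(10)]
    )
    risk = pd.DataFrame([("A", "A*01")], columns=["locus", "allele_group"])
    long, matrix = elevation_profiles(_ab(rows), risk, prof)
    assert long.iloc[0]["delta_pct"] == pytest.approx(80.0 - 30.0)
    assert matrix.loc[("I", "A", "A*01:01"), "A*01"] == pytest.approx(50.0)


def test_elevation_matrix_matches_independent_scan(small_cohort):
    from hlahom.zygosity import homozygosity_profiles

    cfg, typing, antibodies, _ = small_cohort
    prof = homozygosity_profiles(typing)
    risk = pd.DataFrame([("DPA1", "DPA1*01"), ("A", "A*02")],
                        columns=["locus", "allele_group"])
    long, matrix = elevation_profiles(antibodies, risk, prof)
    # independent scan for one allele and a few beads
    hom_ids = set(
        prof[(prof["locus"] == "DPA1") & (prof["homozygous_group"] == "DPA1*01")][
            "individual_id"
        ]
    )
    typed = set(prof[(prof["locus"] == "DPA1") & (prof["status"] != "untyped")][
        "individual_id"
    ])
    het_ids = typed - hom_ids
    sub = long[long["risk_allele"] == "DPA1*01"]
    for bead in sub["bead_id"].head(5):
        bead_rows = antibodies[antibodies["bead_id"] == bead]
        p_hom = (bead_rows[bead_rows["individual_id"].isin(hom_ids)]["mfi"] > 1500).mean()
        p_het = (bead_rows[bead_rows["individual_id"].isin(het_ids)]["mfi"] > 1500).mean()
        expected = 100 * (p_hom - p_het)
        got = sub[sub["bead_id"] == bead]["delta_pct"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-9)
    assert ((long["delta_pct"].dropna() >= -100) & (long["delta_pct"].dropna() <= 100)).all()
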