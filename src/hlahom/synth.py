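"""Synthetic cohort generator: HWE genotypes and single-antigen-bead MFI tables.

The generator emulates the structure of a transplant-centre registry cohort:

- genotypes drawn per locus under Hardy-Weinberg equilibrium from allele-group
  frequency vectors, with default vectors shaped so that per-locus homozygote
  fractions span the observed range (about 8% at the highly polymorphic HLA-B
  up to about 73% at the skewed, allele-poor DPA1);
- partially overlapping availability of class I and class II antibody panels;
- a two-component log-normal MFI emission model: non-immunized individuals
  draw every bead from a baseline distribution, immunized individuals respond
  on a random subset of beads (drawn from a high "response" distribution),
  with the per-bead response probability scaled by
  ``homozygosity_effect ** (number of homozygous loci)``;
- self-tolerance: beads whose target allele group is carried by the
  individual never exceed the positivity cutoff.

Identical config + seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alleles import CLASS_I, LOCI, LOCUS_CLASS
from .zygosity import HOMOZYGOUS, homozygosity_profiles

PANEL_COLUMNS = ("bead_id", "hla_class", "locus", "target_allele")
ANTIBODY_COLUMNS = (
    "individual_id",
    "hla_class",
    "bead_id",
    "locus",
    "target_allele",
    "mfi",
)

# Per-locus homozygote-fraction anchors and allele-group inventories used to
# build the default frequency vectors. The vectors are two-level (one dominant
# group + uniform rest), solved so that sum(f^2) hits the anchor; they are
# synthetic shapes, not real population frequencies.
_HOMOZYGOSITY_ANCHORS = {
    "A": 0.15,
    "B": 0.079,
    "C": 0.14,
    "DRB1": 0.10,
    "DQA1": 0.25,
    "DQB1": 0.20,
    "DPA1": 0.729,
    "DPB1": 0.35,
}
_GROUPS = {
    "A": "01 02 03 11 23 24 25 26 29 30 31 32 33 36 43 66 68 69 74 80".split(),
    "B": (
        "07 08 13 14 15 18 27 35 37 38 39 40 41 42 44 45 46 47 48 49 "
        "50 51 52 53 54 55 56 57 58 78"
    ).split(),
    "C": "01 02 03 04 05 06 07 08 12 14 15 16 17 18".split(),
    "DRB1": "01 03 04 07 08 09 10 11 12 13 14 15 16".split(),
    "DQA1": "01 02 03 04 05 06".split(),
    "DQB1": "02 03 04 05 06".split(),
    "DPA1": "01 02 03".split(),
    "DPB1": "01 02 03 04 05 06 09 10 11 13 14 15 17 19".split(),
}
_DOMINANT = {
    "A": "02",
    "B": "07",
    "C": "07",
    "DRB1": "15",
    "DQA1": "01",
    "DQB1": "03",
    "DPA1": "01",
    "DPB1": "04",
}
# Bead counts per locus (~97 class I + ~96 class II, typical LSA panel sizes).
_PANEL_SIZES = {
    "A": 31,
    "B": 35,
    "C": 31,
    "DRB1": 28,
    "DQA1": 14,
    "DQB1": 18,
    "DPA1": 8,
    "DPB1": 28,
}


def _two_level_freqs(groups: list[str], dominant: str, target_ss: float) -> dict:
    """Frequencies p (dominant) + uniform rest so that sum(f^2) = target_ss."""
    m = len(groups) - 1
    a = (m + 1) / m
    b = -2.0 / m
    c = 1.0 / m - target_ss
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("homozygosity target unreachable for this group count")
    p = (-b + math.sqrt(disc)) / (2 * a)
    rest = (1.0 - p) / m
    return {g: (p if g == dominant else rest) for g in groups}


def default_allele_freqs() -> dict[str, dict[str, float]]:
    """Default per-locus allele-group frequency vectors (synthetic shapes)."""
    return {
        locus: _two_level_freqs(
            _GROUPS[locus], _DOMINANT[locus], _HOMOZYGOSITY_ANCHORS[locus]
        )
        for locus in LOCI
    }


def default_panel() -> pd.DataFrame:
    """Default single-antigen-bead panel (~97 class I, ~96 class II beads).

    Beads cycle through each locus' allele groups with two-field suffixes
    :01, :02, ... until the locus' bead count is reached.
    """
    rows = []
    for locus in LOCI:
        groups = _GROUPS[locus]
        n = _PANEL_SIZES[locus]
        for k in range(n):
            group = groups[k % len(groups)]
            suffix = k // len(groups) + 1
            target = f"{group}:{suffix:02d}"
            rows.append(
                {
                    "bead_id": f"{locus}*{target}",
                    "hla_class": LOCUS_CLASS[locus],
                    "locus": locus,
                    "target_allele": target,
                }
            )
    return pd.DataFrame(rows, columns=list(PANEL_COLUMNS))


def validate_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns {missing}")
    if panel["bead_id"].duplicated().any():
        raise ValueError("panel bead_ids are not unique")
    unknown = set(panel["locus"]) - set(LOCI)
    if unknown:
        raise ValueError(f"panel contains unsupported loci {sorted(unknown)}")
    bad = panel[panel["hla_class"] != panel["locus"].map(LOCUS_CLASS)]
    if not bad.empty:
        raise ValueError(
            f"bead {bad.iloc[0]['bead_id']!r} has class inconsistent with its locus"
        )


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``class1_fraction``, ``class2_fraction`` and ``overlap_fraction`` give the
    probabilities that an individual has class I data, class II data, and
    both; defaults reproduce the availability proportions of a mixed
    transplant registry (62.4% / 80.1% / 42.5% of antibody-tested patients).
    ``homozygosity_effect`` multiplies the per-bead response probability once
    per homozygous locus (1.0 = null model). MFI emission is log-normal with
    log-scale means ``mfi_baseline_mu`` / ``mfi_response_mu`` and common
    ``mfi_sigma``.
    """

    n_individuals: int = 2000
    loci: tuple[str, ...] = LOCI
    allele_freqs: dict = field(default_factory=default_allele_freqs)
    class1_fraction: float = 4515 / 7234
    class2_fraction: float = 5793 / 7234
    overlap_fraction: float = 3074 / 7234
    immunization_rate: float = 0.30
    response_rate: float = 0.03
    homozygosity_effect: float = 2.0
    mfi_baseline_mu: float = math.log(100.0)
    mfi_response_mu: float = math.log(8000.0)
    mfi_sigma: float = 1.0
    cutoff_mfi: float = 1500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for locus in self.loci:
            if locus not in self.allele_freqs:
                raise ValueError(f"no allele frequencies for locus {locus}")
            freqs = np.asarray(list(self.allele_freqs[locus].values()), float)
            if (freqs < 0).any():
                raise ValueError(f"negative allele frequency at locus {locus}")
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"allele frequencies at locus {locus} sum to {freqs.sum()!r}, "
                    "expected 1"
                )
        for name in (
            "class1_fraction",
            "class2_fraction",
            "overlap_fraction",
            "immunization_rate",
            "response_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.overlap_fraction > min(self.class1_fraction, self.class2_fraction):
            raise ValueError("overlap_fraction cannot exceed either class fraction")
        if self.class1_fraction + self.class2_fraction - self.overlap_fraction > 1 + 1e-12:
            raise ValueError("availability fractions imply probability > 1")
        if self.homozygosity_effect < 0:
            raise ValueError("homozygosity_effect must be >= 0")
        if not self.mfi_response_mu > self.mfi_baseline_mu:
            raise ValueError("mfi_response_mu must exceed mfi_baseline_mu")
        if self.mfi_sigma <= 0:
            raise ValueError("mfi_sigma must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loci"] = list(self.loci)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "loci" in d:
            d["loci"] = tuple(d["loci"])
        return cls(**d)


def sample_genotypes(config: CohortConfig) -> pd.DataFrame:
    """Draw HWE genotypes: two independent allele groups per individual x locus."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_individuals
    ids = np.array([f"I{i:06d}" for i in range(n)])
    frames = []
    for locus in config.loci:
        groups = np.array(
            [f"{locus}*{g}" for g in config.allele_freqs[locus].keys()]
        )
        freqs = np.asarray(list(config.allele_freqs[locus].values()), float)
        freqs = freqs / freqs.sum()
        draws = rng.choice(len(groups), size=(n, 2), p=freqs)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ids,
                    "locus": locus,
                    "allele1": groups[draws[:, 0]],
                    "allele2": groups[draws[:, 1]],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    order = {locus: i for i, locus in enumerate(LOCI)}
    out["_o"] = out["locus"].map(order)
    out = out.sort_values(["individual_id", "_o"], kind="stable").drop(columns="_o")
    return out.reset_index(drop=True)


def sample_antibody_profiles(
    typing: pd.DataFrame, panel: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Emit per-bead MFI values for the individuals in ``typing``.

    See the module docstring for the emission model. Beads targeting an
    allele group the individual carries are clipped at the cutoff so a self
    bead is never scored antibody-positive.
    """
    config.validate()
    validate_panel(panel)
    panel_loci = set(panel["locus"])
    typing_loci = set(typing["locus"])
    if not panel_loci <= typing_loci:
        raise ValueError(
            f"panel loci {sorted(panel_loci - typing_loci)} absent from typing table"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    ids = np.sort(typing["individual_id"].unique())
    n = len(ids)
    id_index = {v: i for i, v in enumerate(ids)}
    beads = panel.reset_index(drop=True)
    n_beads = len(beads)
    bead_index = {v: i for i, v in enumerate(beads["bead_id"])}

    # Self mask: bead target group carried by the individual at that locus.
    carried = typing.melt(
        id_vars=["individual_id", "locus"],
        value_vars=["allele1", "allele2"],
        value_name="allele",
    ).dropna(subset=["allele"])
    carried = carried[carried["allele"].astype(str).str.strip() != ""]
    carried["group"] = (
        carried["allele"].astype(str).str.split("*").str[-1].str.split(":").str[0]
    )
    bead_groups = beads[["bead_id", "locus", "target_allele"]].copy()
    bead_groups["group"] = bead_groups["target_allele"].str.split(":").str[0]
    self_pairs = carried.merge(bead_groups, on=["locus", "group"])
    self_mask = np.zeros((n, n_beads), dtype=bool)
    if not self_pairs.empty:
        rows = self_pairs["individual_id"].map(id_index).to_numpy()
        cols = self_pairs["bead_id"].map(bead_index).to_numpy()
        self_mask[rows, cols] = True

    profiles = homozygosity_profiles(typing, depth=1)
    deg = (
        profiles[profiles["status"] == HOMOZYGOUS]
        .groupby("individual_id")
        .size()
        .reindex(ids, fill_value=0)
        .to_numpy()
    )

    # Availability categories: both / class I only / class II only / none.
    p_both = config.overlap_fraction
    p1_only = config.class1_fraction - p_both
    p2_only = config.class2_fraction - p_both
    u = rng.random(n)
    has_c1 = (u < p_both + p1_only)
    has_c2 = (u < p_both) | ((u >= p_both + p1_only) & (u < p_both + p1_only + p2_only))

    immunized = rng.random(n) < config.immunization_rate
    p_resp = np.clip(
        config.response_rate * config.homozygosity_effect ** deg, 0.0, 1.0
    )
    responds = (rng.random((n, n_beads)) < p_resp[:, None]) & immunized[:, None]
    responds &= ~self_mask

    mu = np.where(responds, config.mfi_response_mu, config.mfi_baseline_mu)
    mfi = np.exp(mu + config.mfi_sigma * rng.standard_normal((n, n_beads)))
    # self-tolerance by construction: self beads never exceed the cutoff
    mfi[self_mask] = np.minimum(mfi[self_mask], config.cutoff_mfi)
    mfi = np.round(mfi, 1)

    is_class1 = (beads["hla_class"] == "I").to_numpy()
    avail = np.where(is_class1[None, :], has_c1[:, None], has_c2[:, None])
    rows, cols = np.nonzero(avail)
    out = pd.DataFrame(
        {
            "individual_id": ids[rows],
            "hla_class": beads["hla_class"].to_numpy()[cols],
            "bead_id": beads["bead_id"].to_numpy()[cols],
            "locus": beads["locus"].to_numpy()[cols],
            "target_allele": beads["target_allele"].to_numpy()[cols],
            "mfi": mfi[rows, cols],
        }
    )
    return out.reset_index(drop=True)


def simulate_cohort(
    config: CohortConfig, panel: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (typing, antibodies, panel) for one config."""
    if panel is None:
        panel = default_panel()
    typing = sample_genotypes(config)
    antibodies = sample_antibody_profiles(typing, panel, config)
    return typing, antibodies, panel


def write_cohort(
    outdir: str | Path,
    typing: pd.DataFrame,
    antibodies: pd.DataFrame,
    panel: pd.DataFrame,
    config: CohortConfig,
) -> dict[str, Path]:
    """Write typing/antibody/panel TSVs and the generating config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "typing": outdir / "typing.tsv",
        "antibodies": outdir / "antibodies.tsv",
        "panel": outdir / "panel.tsv",
        "config": outdir / "cohort_config.yaml",
    }
    typing.to_csv(paths["typing"], sep="\t", index=False)
    antibodies.to_csv(paths["antibodies"], sep="\t", index=False)
    panel.to_csv(paths["panel"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
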