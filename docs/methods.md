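# Methods

## Problem setting

Anti-HLA antibodies measured by single-antigen-bead (SAB) assays are the
main serological risk marker in organ transplantation. The package tests a
specific immunogenetic hypothesis: individuals homozygous at one or more
HLA loci (A, B, C, DRB1, DQA1, DQB1, DPA1, DPB1; DRB3/4/5 are excluded
because they travel in tight linkage with DRB1) produce antibodies against
a broader range of HLA specificities than heterozygous individuals. The
unit of analysis is the individual × locus antibody profile.

## Antibody profile measures

For the N beads of one locus in one serum:

- **Breadth** `pct_above_1500 = 100 · #{MFI_i > c} / N` with cutoff
  c = 1500 fluorescence units (manufacturer-recommended positivity
  threshold; the inequality is strict). Negative raw MFIs, which Luminex
  exports can contain, are clamped to 0 first.
- **Specificity** `H_norm = H / log2(N)` with
  `H = −Σ p_i log2 p_i`, `p_i = MFI_i / Σ MFI_i`, and the `0·log 0 = 0`
  convention. `H_norm` is invariant under rescaling all MFIs and ranges
  from 0 (single dominant antibody) to 1 (uniform reactivity).

Profiles with a single bead (log2 N = 0) or all-zero MFI are marked
not-included rather than imputed; the pipeline logs their count. When the
same bead target appears more than once (e.g. duplicate lots), the maximum
MFI is kept by default (configurable: mean, or reject). An optional
`mask_self` flag removes beads whose target allele group the individual
carries before computing both measures.

## Quadrant segmentation

All included (breadth, entropy) points are pooled and each axis is
dichotomized at its **slope-weighted average**: after sorting the values
x(1) ≤ … ≤ x(n), the threshold is the gap-weighted mean of consecutive
midpoints, t = Σ gᵢ·(xᵢ+xᵢ₊₁)/2 / Σ gᵢ with gᵢ = xᵢ₊₁ − xᵢ. (The sum
telescopes to (min+max)/2; the formula is kept in gap form because it is
the definition being implemented, and the identity is used as a property
test.) For bimodal data the cut lands in the dominant density gap. A fixed
threshold pair — e.g. the published 49.5 % / 0.579 — can be supplied
instead, and per-locus thresholds are available behind a flag; the default
is one global pair because a single pair of values is what is quoted for
the reference analysis. Boundary ties go to the "high" side so that fixed
published thresholds classify stably. Labels: first letter = breadth
level, second = entropy level (LL, LH, HH, HL).

## Association testing

- **Locus level**: for each locus with at least 2 individuals per zygosity
  stratum, Wilcoxon rank-sum on breadth and on entropy, plus a
  Freeman–Halton Fisher exact test on the populated quadrant × zygosity
  table (empty quadrants, typically HL, are dropped). Bonferroni per test
  family over the tested loci.
- **Allele level**: alleles with **strictly more than 10** homozygous
  individuals enter the screen; for each, the Fisher quadrant test compares
  individuals homozygous for that allele group against everyone else typed
  at the locus (non-carriers included in the comparator — this maximizes
  power; carrier-only comparators would be a stricter alternative).
  Bonferroni is over the number of alleles actually tested.
- **Elevation profiles**: for each risk allele, every bead of both panels
  gets Δ = 100·(P(MFI>1500 | homozygous) − P(MFI>1500 | heterozygous))
  percentage points; beads untested in a stratum yield missing values. The
  beads × risk-alleles matrix is the heatmap input.

### Test implementations

Wilcoxon rank-sum uses midranks; the exact null distribution is used when
the smaller group has ≤ 10 observations and the pooled sample is tie-free,
otherwise the normal approximation with tie and continuity corrections
(delegated to `scipy.stats.mannwhitneyu`; an independent full-permutation
enumeration oracle backs it in the tests). All tests are two-sided.

The Fisher r×c test follows the Freeman–Halton rule: p = total null
probability (margins fixed) of all tables whose point probability is at
most that of the observed table (relative tie tolerance 1e−7 to absorb
floating-point ties). Tables with ≤ 2 free cells (2×2, 3×2) are enumerated
on a vectorized grid; larger shapes are enumerated recursively while the
candidate-table count stays within a budget (default 5×10⁶), beyond which
a seeded Monte-Carlo sample (Patefield's algorithm via
`scipy.stats.random_table`, default 10⁵ tables) estimates p with a reported
standard error. Enumeration agrees with R's `fisher.test` to ≥ 9 decimals
on reference tables and with an exact-rational-arithmetic oracle on an
exhaustive 3×2 sweep.

## Synthetic cohort generator

The generator is the package's test bed; it emulates the statistical
structure of a transplant-registry cohort, not any real population.

- **Genotypes**: two allele groups per individual × locus drawn i.i.d.
  from per-locus frequency vectors (Hardy–Weinberg), so the expected
  homozygote fraction is Σf². Default vectors are two-level shapes (one
  dominant group + uniform remainder) solved so Σf² matches realistic
  anchors: 7.9 % at the highly polymorphic HLA-B up to 72.9 % at DPA1,
  with the remaining loci interpolated (A 15 %, C 14 %, DRB1 10 %,
  DQA1 25 %, DQB1 20 %, DPB1 35 %). They are synthetic shapes, not
  population frequency databases, and carry no linkage disequilibrium
  between loci.
- **Availability**: each individual has class I and/or class II antibody
  data with probabilities 0.624 / 0.801 and overlap 0.425 — the
  availability proportions of a mixed registry antibody subcohort.
- **MFI emission**: a latent immunization indicator (rate 0.30); a
  non-immunized serum draws every bead from the baseline log-normal
  (median 100 MFI, σ = 1 on the log scale, so P(MFI > 1500) ≈ 0.3 %);
  an immunized serum responds on each bead independently with probability
  `min(1, response_rate · homozygosity_effect^d)` where d is the
  individual's homozygosity degree, responding beads drawn from the
  response log-normal (median 8000 MFI). Defaults: `response_rate = 0.03`
  — chosen so the response probability stays far from saturation over the
  realistic degree range (mean d ≈ 2) and the high-risk HH quadrant stays
  sparsely populated, as in real cohorts — and `homozygosity_effect = 2`,
  a moderate positive effect; 1.0 gives the null model.
- **Self-tolerance**: beads whose target allele group the individual
  carries never respond, and their baseline draw is clipped at the cutoff,
  so a self bead is never scored antibody-positive. Because heterozygotes
  carry more distinct groups (hence more self beads), this mechanism alone
  induces a very small homozygous > heterozygous breadth bias even under
  the null effect; at the default response rate it is negligible (measured
  type-I error 0.05 at n = 1000 over 200 replicates).
- Default panel: ~97 class I and ~96 class II beads (typical LSA panel
  sizes), cycling two-field variants over each locus' allele groups.
- Identical config + seed give byte-identical tables (genotype and
  antibody stages use independent child seeds of the config seed).

What the generator does **not** model: haplotype/linkage structure across
loci, immunizing-event covariates (pregnancy, transfusion history), bead
saturation and lot effects, or population-specific allele frequencies.
Passing tests therefore demonstrate the correctness and calibration of the
analysis machinery under the stated generative model, not epidemiological
claims about real cohorts. With the default moderate effect the synthetic
HH quadrant holds ~1 % of individual × locus points (rising to ~9 % at
effect 3), lower than the 4–13 % seen in real sensitized cohorts — real
cohorts mix many immunization histories that the single-rate model
compresses.

## Calibration results computed by the suite

All of the following are recomputed by `tests/` on fixed seeds: per-locus
homozygote fractions within 3 binomial SE of Σf² at n = 10,000; type-I
error of the locus-A Fisher quadrant test 0.05 (band 0.02–0.08) over 200
null cohorts at n = 1,000; rejection in 30/30 replicates at
homozygosity_effect = 3, n = 2,000; and HH-enrichment monotone in the true
effect over {1, 2, 3}.

## Problem sizes used by the test suite

Simulation-based checks use n = 500–3,000 individuals and 30–200
replicates; the exhaustive Fisher oracle sweep covers all 3×2 tables with
total count ≤ 10 (8,008 tables) plus 150 seeded random tables with total
≤ 30; the Wilcoxon permutation oracle covers group sizes up to 8. These
sizes were chosen to give stable Monte-Carlo margins (3 SE) at interactive
runtimes.

## Degenerate inputs and tie-breaks

- All-equal threshold input → the common value, with a warning.
- Zero-margin rows/columns in a contingency table are dropped (warning);
  a table reduced below 2×2 returns p = 1.
- A typing record with one blank allele counts as typed but not homozygous
  by default (`assume_blank_homozygous` flips this); fully blank records
  are untyped and excluded from the degree denominator.
- Boundary biplot points (exactly at a threshold) go high, so the
  published-threshold override reproduces a stable partition.

## Known limitations

- The heterozygous comparator at allele level includes non-carriers; both
  definitions are computable from the profiles table but only one is wired
  into the screen.
- Class I and class II metrics of one individual are tested independently
  per locus; no joint modelling of the two availability strata.
- The slope-weighted threshold is sensitive to extreme outliers (it
  reduces to the midrange); with heavy-tailed metric distributions the
  fixed-threshold override or per-locus thresholds are preferable.
- No regression adjustment for immunizing events, age, or centre effects;
  the tests are marginal associations.
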