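# Methods

## Phasing model

Each animal carries two unphased region genotypes: an unordered pair of
promoter/exon-1 variants and an unordered pair of intron-2/exon-3
variants.  The two regions are treated as fully linked — a haplotype is
one variant from each region, and no recombination between them is
modelled.  A diplotype (unordered pair of haplotypes) is compatible with
an animal iff its region-wise collapse equals the observed genotypes:
one compatible diplotype when either region is homozygous, exactly two
(the cis/trans pairings) when both are heterozygous.

Sires are reconstructed from their half-sib families.  Candidate sire
diplotypes (enumerated from the sire's own genotypes when present,
otherwise all pairs over the haplotypes seen in any progeny candidate)
are ranked by a two-part score:

1. **compatibility** — the number of progeny that have at least one
   candidate phasing sharing a haplotype with the sire candidate; and
2. **transmission support** — over the sire candidate's two chromosome
   slots (counted with multiplicity), the number of *directly phased*
   progeny carrying that slot's haplotype.

Requiring full compatibility first makes the estimate robust to a single
mistyped progeny; the multiplicity in the support term is what lets a
homozygous sire outrank a heterozygous candidate that pairs the same
haplotype with one observed on no progeny chromosome.  The unique
maximiser is chosen; a tie is reported as ambiguous and never broken
arbitrarily.  Double-heterozygous progeny are then resolved only when
exactly one of their two phasings shares a haplotype with the chosen
sire; zero survivors mark the animal inconsistent (mistyping), two leave
it unresolved.  Unresolved and inconsistent animals keep a null
diplotype and are dropped per-trait downstream — exclusion, not
imputation.  Dams are an unobserved population pool throughout.

Two consequences worth knowing:

- Under the default frequency vector (two haplotypes near 36% and 46%),
  roughly 4% of lambs are double heterozygotes whose two phasings *both*
  share a paternal haplotype.  These are information-theoretically
  unresolvable by Mendelian reasoning, so cohort resolution plateaus
  near 96%, with every resolution exact.
- Because that exclusion is differential (it hits trans configurations
  of the common haplotypes hardest), chromosome-counting frequencies
  over resolved animals are mildly biased — the most common haplotype
  is undercounted by a few percentage points.  The estimator is exact
  for the animals it counts; the bias is a property of the resolvable
  subset, and would apply equally to any hand-curated version of this
  design.

A brute-force oracle (exhaustive enumeration over sire diplotypes and
chromosome-origin assignments) verifies the incremental implementation
exactly on hundreds of random small families in the test suite.

## Association models

All three series are linear models fitted per trait with a random sire
intercept estimated by REML (`statsmodels` `MixedLM`).  If the sire
variance estimate is numerically zero or the optimiser fails, the model
collapses to ordinary least squares and the result is flagged.  Wald
tests use the normal reference for mixed fits and the t/F reference for
the OLS fallback.

Structural terms per trait: gender and birth rank for birth weight;
gender, rearing rank and weaning age for tailing and weaning weight;
gender and rearing rank for growth rate; rearing rank and slaughter age
for carcass traits, which exist only for slaughtered males (a
single-level gender factor is dropped automatically).  A helper
(`select_structure_term`) chooses among birth rank, birth weight and
rearing rank by largest F when the choice is open, with a fixed
priority order on exact ties.

Group summaries are estimated marginal means: model predictions averaged
with equal weight over the combinations of the other fixed-factor
levels, covariates (and co-fitted presence terms) at their observed
means.  The presence-term p-value equals the Wald test of the EMM
difference.  Thresholds: effects are significant at p < 0.05 and trends
at 0.05 ≤ p < 0.20 (the boundary p = 0.05 counts as a trend, matching
the strict inequality); haplotypes enter the adjusted series when their
single-model p < 0.20; diplotypes enter series 3 when their frequency
in the trait's analysed subset exceeds 5% — computed per trait, so
carcass traits filter on the male slaughter subset.  Pairwise diplotype
comparisons are LSD contrasts of EMMs with p multiplied by k(k−1)/2
(capped at 1) for k groups; the compact letter display is built by
insert-and-absorb, so two groups share no letter exactly when their
adjusted p < 0.05.

Degenerate inputs are statuses, not crashes: an empty presence group is
"not estimable", a constant trait reports equal means with p = 1 and a
zero-variance flag, fewer than two diplotype groups skips series 3, and
a rank-deficient design raises an error naming the dependent columns.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 17 sire
lines with 70 lambs each (1,190 genotyped progeny), sire and dam
haplotypes drawn i.i.d. from an eight-haplotype frequency vector
(36.23, 0.53, 10.16, 45.91, 1.47, 5.56, 0.07, 0.07 %), each lamb
receiving one uniformly chosen sire haplotype and one dam haplotype.
Gender is Bernoulli(½); birth rank is single/twin/triplet at
0.30/0.60/0.10 with a 10% chance of being reared one rank lower;
weaning age ~ N(100, 7²) days.

Phenotypes follow the association model's own form: intercept + gender
and rank effects + presence-coded haplotype effects (optionally 0/1/2
dosage) + N(0, σ²_s) sire deviation + N(0, σ²_e) residual.  Weights are
made internally consistent by construction: weaning weight = birth
weight + growth·age/1000, so the growth-rate identity holds exactly.
Leg, loin and shoulder lean-meat yields are generated first and the
total and proportion yields derived from them, so the composition
identities (total = leg+loin+shoulder; proportions sum to 100) hold for
every record.  Carcass phenotypes are emitted only for males whose
simulated live weight (weaning weight plus a fixed 120 g/day gain over
100 days) exceeds 36 kg, reproducing male-only slaughter selection.
Observed genotypes are the region-wise collapse of the true diplotype;
an optional per-region mislabel rate exercises the inconsistency path
(off by default).

Variance components are not published for this design; the defaults
(growth: σ_s = 8, σ_e = 55 g/day; yields: σ_s ≈ 0.3, σ_e ≈ 1.0–1.3 %;
V-GR: σ_s = 0.35, σ_e = 1.6 mm; weights: σ_e ≈ 0.9–4.5 kg) are
calibration choices giving standard errors of the magnitude typical for
cohorts of this size — e.g. growth-rate EMM SEs of a few g/day.  V-GR
is generated unbounded and can (rarely) go slightly negative in the
tails; it is left untruncated to keep the linear model exact.

What passing tests do and do not show: the generator draws from exactly
the model family the association stage fits, so effect-recovery and
calibration results demonstrate correctness of the estimator, not
robustness to real-data features it does not emulate — non-normal
residuals, dam effects and maternal environment, litter common
environment, heteroscedasticity across sires, or linkage to unmodelled
loci.

## Numerical and design choices

- Seeds are mandatory everywhere; a cohort, its phasing and all rendered
  tables are byte-reproducible from (config, seed).  Tie-sensitive steps
  iterate in canonical (sorted) order, so record order never matters.
- Sampling-noise checks in the tests use exact binomial 99% bounds on
  the i.i.d. components of the design (dam-derived chromosomes, sire
  founder draws); total chromosome counts are *not* binomial because
  half of them descend from only 34 founder chromosomes.
- The type-I error of the presence model is calibrated by simulation
  (1,000 null replicates at n ≈ 400 in the test suite, band
  0.035–0.065 at α = 0.05).
- Problem sizes in the default suite — 500 oracle families, one full
  1,190-lamb cohort, 1,000 calibration replicates — run in about three
  minutes on one core and were chosen as the smallest sizes at which
  the corresponding statistical bounds are meaningful.
- Missing phenotype cells parse to null and propagate to per-trait case
  deletion; no imputation anywhere.  An explicit growth-rate column wins
  over recomputation from weights.
- Rendered tables round to field conventions (weights 2 dp, growth rate
  1 dp, yields 2 dp, p-values 3 dp, frequencies 2 dp percentages);
  machine-readable outputs keep full precision via `repr`.

## Known limitations

- Sire reconstruction is combinatorial (consistency + transmission
  support), not a likelihood or EM over dam haplotype frequencies; in
  very small or uninformative families it reports ambiguity where a
  probabilistic method would produce a posterior.
- The random-intercept Wald test uses the normal reference; with far
  fewer sires than the default 17 it would become anticonservative
  (no Satterthwaite/Kenward–Roger correction is applied).
- Only two loci, one random factor and presence-coded effects are
  supported; no genomic relationship matrices, multi-trait models or
  Hardy–Weinberg testing.
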