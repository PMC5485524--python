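# lambhap

Two-locus haplotype phasing and trait association for half-sib sheep
cohorts.

Candidate-gene studies in commercial flocks often genotype lambs at two
amplified regions of a gene — here a promoter/exon-1 fragment and an
intron-2/exon-3 fragment of the adiponectin gene (*ADIPOQ*) — and ask
whether the two-locus haplotypes (e.g. `A1–A3`, a promoter variant linked
to a coding-region variant) are associated with growth and carcass
traits.  The genotypes come unphased, but the pedigree is a set of
half-sib families: every lamb shares a recorded sire with tens of
paternal sibs, while dams are an unpedigreed population pool.  `lambhap`
turns that structure into a complete, reproducible pipeline for animal
geneticists:

1. **Phasing.**  A lamb homozygous at either region has a single
   compatible diplotype (pair of haplotypes) and is phased *directly*.  A
   double heterozygote has exactly two compatible phasings; the sire's
   diplotype — reconstructed from the whole family by a
   consistency-plus-transmission-support rule — decides between them when
   exactly one phasing shares a paternal haplotype.  Ambiguities are
   surfaced, never imputed.
2. **Frequencies.**  Haplotype frequencies by chromosome counting over
   resolved animals; diplotype frequencies by animal counting.
3. **Association.**  Three model series per trait, each a linear model
   with a REML random sire intercept: (i) presence/absence of one
   haplotype, coded 1/0; (ii) the same with every other haplotype whose
   single-model p < 0.20 co-fitted; (iii) diplotype as a fixed factor
   over the diplotypes above 5% frequency, with least-significant-
   difference pairwise comparisons, Bonferroni-corrected and summarised
   as a compact letter display.  Group summaries are estimated marginal
   means (equal factor-level weights, covariates at their means):
   for trait *y* of animal *ijk*,

   *y* = μ + presence·β + gender + rank (+ age) + sire*_i_* + ε,
   sire*_i_* ~ N(0, σ²_s), ε ~ N(0, σ²_e).

A seeded synthetic cohort generator reproduces the study design (17 sire
lines, ~70 lambs each, an eight-haplotype frequency vector, male-only
slaughter above a 36 kg live-weight threshold) with known latent truth,
so every stage is testable end to end.

## Worked example

```python
from lambhap import synthetic, phasing, assoc
from lambhap.genodata import Haplotype

cfg = synthetic.SimConfig(seed=1).with_effects("growth_rate", {"A1-A3": -15.0})
cohort = synthetic.generate_cohort(cfg)          # 1,190 lambs, 17 sires
phased = phasing.phase_cohort(cohort.records)
n_resolved = sum(o.resolved is not None for o in phased.outcomes.values())
print(n_resolved)                                 # 1141  (95.9% resolved)

df = assoc.build_dataset(cohort.records, phased)
r = assoc.fit_presence_model(df, "growth_rate", Haplotype("A1", "A3"))
print(f"{r.emm_absent:.1f} vs {r.emm_present:.1f} g/day, p = {r.p_value:.3f}")
# 275.0 vs 263.3 g/day, p = 0.001
```

The two numbers are the estimated marginal mean pre-weaning growth rates
of non-carriers and carriers of `A1–A3`; the planted 15 g/day deficit is
recovered (11.8 ± 3.5 g/day) and detected at p < 0.05.  Phasing resolves
95.9% of lambs — the remainder are double heterozygotes whose two
phasings both share a paternal haplotype, which no Mendelian rule can
separate — and every resolved diplotype matches the generator's truth.

The same pipeline runs from a shell:

```sh
lambhap simulate --config run.yaml --seed 1
lambhap phase    --config run.yaml --input out/cohort.csv
lambhap associate --config run.yaml --input out/cohort.csv
lambhap report   --in out
```

Downstream arithmetic helpers translate model output into breeding
terms: `derived_growth_effect(275.9, 268.2, 100)` → a 7.7 g/day deficit,
770 g from birth to a 100-day weaning; `derived_meat_effect(0.71, 18)` →
128 g of lean meat on an 18 kg carcass per 0.71 percentage-point total
yield gain.

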