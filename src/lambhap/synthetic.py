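"""Synthetic half-sib cohort generator.

Emulates a commercial ram-breeding cohort: a fixed number of sire lines,
each siring a family of lambs out of an unpedigreed dam population.  Each
sire carries two two-locus haplotypes drawn from a population frequency
vector; every lamb inherits one sire haplotype (uniformly) and one dam
haplotype drawn from the same vector.  Observed genotypes are the
region-wise collapse of the true diplotype, so the generator exercises
exactly the information loss the phasing stage must undo.

Phenotypes follow the association stage's own model: a linear predictor
of structural effects (gender, rank) plus additive-on-presence haplotype
effects, a normal sire deviation and a normal residual.  Carcass traits
are produced only for males whose simulated live weight at slaughter age
clears a threshold, reproducing the male-only slaughter selection.

Defaults: 17 sires with 70 lambs each (1,190 genotyped progeny), the
eight-haplotype frequency vector observed in the study population this
design emulates, and variance components giving standard errors of
realistic magnitude (e.g. growth-rate EMM standard errors of a few g/day
at full cohort size).  No dam pedigree, no recombination between the two
regions, and no genotyping error unless a mislabel rate is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genodata import (AnimalRecord, Diplotype, Gender, Haplotype,
                       PhenotypeSet, Rank, RegionGenotype,
                       VariantRegistry, DEFAULT_REGISTRY, derive_composition)

#: the eight two-locus haplotypes segregating in the emulated population
DEFAULT_HAPLOTYPES: tuple[Haplotype, ...] = (
    Haplotype("A1", "A3"), Haplotype("A1", "B3"), Haplotype("A1", "C3"),
    Haplotype("B1", "A3"), Haplotype("B1", "B3"), Haplotype("B1", "C3"),
    Haplotype("D1", "A3"), Haplotype("D1", "C3"),
)

#: population haplotype frequencies (sum to 1)
DEFAULT_FREQUENCIES: tuple[float, ...] = (
    0.3623, 0.0053, 0.1016, 0.4591, 0.0147, 0.0556, 0.0007, 0.0007)


@dataclass(frozen=True)
class TraitSim:
    """Generating model for one simulated trait.

    ``hap_effects`` maps haplotype display names to additive-on-presence
    effects in the trait's own units; ``dosage`` switches to a 0/1/2
    additive coding for sensitivity checks.
    """

    intercept: float
    sire_sd: float
    resid_sd: float
    gender_effect: float = 0.0          # added for males
    rank_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)  # single/twin/triplet
    hap_effects: dict[str, float] = field(default_factory=dict)
    dosage: bool = False


def _traits(**overrides: TraitSim) -> dict[str, TraitSim]:
    base = {
        # weights kg; growth g/day; vgr mm; yields % of carcass weight
        "birth_weight": TraitSim(5.3, 0.15, 0.9, gender_effect=0.25,
                                 rank_effects=(0.5, 0.0, -0.5)),
        "growth_rate": TraitSim(272.0, 8.0, 55.0, gender_effect=8.0,
                                rank_effects=(15.0, 0.0, -15.0)),
        "hot_carcass_weight": TraitSim(18.0, 0.4, 1.6),
        "vgr": TraitSim(3.2, 0.35, 1.6),
        "leg_yield": TraitSim(20.5, 0.35, 1.3),
        "loin_yield": TraitSim(14.0, 0.25, 0.95),
        "shoulder_yield": TraitSim(16.5, 0.3, 1.1),
    }
    base.update(overrides)
    return base


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_sires: int = 17
    progeny_per_sire: int = 70
    haplotypes: tuple[Haplotype, ...] = DEFAULT_HAPLOTYPES
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    traits: dict[str, TraitSim] = field(default_factory=_traits)
    rank_probs: tuple[float, float, float] = (0.30, 0.60, 0.10)
    rank_demotion_prob: float = 0.10     # reared one rank below birth rank
    weaning_age_mean: float = 100.0
    weaning_age_sd: float = 7.0
    slaughter_age_offset: float = 100.0  # days after weaning
    post_weaning_gain: float = 120.0     # g/day, fixed
    slaughter_threshold: float = 36.0    # kg live weight
    missing_rate: float = 0.0            # per growth-phenotype cell
    mislabel_rate: float = 0.0           # per observed region genotype
    include_sire_rows: bool = False

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("haplotype frequencies must be non-negative")
        for name, t in self.traits.items():
            if t.sire_sd < 0 or t.resid_sd < 0:
                raise ValueError(f"negative SD for trait {name}")

    def with_effects(self, trait: str, hap_effects: dict[str, float]
                     ) -> "SimConfig":
        """Copy of the config with planted haplotype effects on one trait."""
        traits = dict(self.traits)
        traits[trait] = replace(traits[trait], hap_effects=hap_effects)
        return replace(self, traits=traits)


@dataclass
class TruthRow:
    animal_id: str
    sire_id: str
    diplotype: Diplotype
    sire_diplotype: Diplotype
    sire_hap: Haplotype
    dam_hap: Haplotype


@dataclass
class SyntheticCohort:
    records: list[AnimalRecord]
    truth: dict[str, TruthRow]
    sire_truth: dict[str, Diplotype]


_RANKS = (Rank.SINGLE, Rank.TWIN, Rank.TRIPLET)


def _trait_value(t: TraitSim, rng: np.random.Generator, male: bool,
                 rank_i: int, dip: Diplotype, sire_dev: float) -> float:
    value = t.intercept + (t.gender_effect if male else 0.0) \
        + t.rank_effects[rank_i] + sire_dev + rng.normal(0.0, t.resid_sd)
    for hap_name, beta in t.hap_effects.items():
        hap = Haplotype.parse(hap_name)
        count = sum(h == hap for h in dip.haplotypes)
        value += beta * (count if t.dosage else min(count, 1))
    return value


def _mislabel(g: RegionGenotype, rng: np.random.Generator,
              registry: VariantRegistry) -> RegionGenotype:
    labels = list(g.labels)
    i = int(rng.integers(0, 2))
    choices = [l for l in registry.labels(g.region) if l != labels[i]]
    labels[i] = choices[int(rng.integers(0, len(choices)))]
    return RegionGenotype.of(g.region, *labels)


def generate_cohort(config: SimConfig,
                    registry: VariantRegistry = DEFAULT_REGISTRY
                    ) -> SyntheticCohort:
    """Draw a complete cohort plus its latent truth table."""
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.frequencies, dtype=float)
    haps = config.haplotypes

    records: list[AnimalRecord] = []
    truth: dict[str, TruthRow] = {}
    sire_truth: dict[str, Diplotype] = {}

    for s in range(config.n_sires):
        sire_id = f"S{s + 1:02d}"
        pair = rng.choice(len(haps), size=2, p=freqs)
        sire_dip = Diplotype.of(haps[pair[0]], haps[pair[1]])
        sire_truth[sire_id] = sire_dip
        sire_devs = {t: rng.normal(0.0, ts.sire_sd)
                     for t, ts in config.traits.items()}
        if config.include_sire_rows:
            gp, gc = sire_dip.collapse()
            records.append(AnimalRecord(
                animal_id=sire_id, sire_id=None, gender=Gender.MALE,
                birth_rank=Rank.SINGLE, rearing_rank=Rank.SINGLE,
                genotype_prom=gp, genotype_coding=gc))

        for p in range(config.progeny_per_sire):
            aid = f"L{s + 1:02d}{p + 1:03d}"
            sire_hap = sire_dip.haplotypes[int(rng.integers(0, 2))]
            dam_hap = haps[int(rng.choice(len(haps), p=freqs))]
            dip = Diplotype.of(sire_hap, dam_hap)
            male = bool(rng.random() < 0.5)
            birth_i = int(rng.choice(3, p=config.rank_probs))
            rear_i = max(0, birth_i - 1) if (
                birth_i > 0 and rng.random() < config.rank_demotion_prob
            ) else birth_i
            age_wean = float(np.clip(round(
                rng.normal(config.weaning_age_mean, config.weaning_age_sd)),
                60, None))

            tv = {t: _trait_value(ts, rng, male, birth_i, dip, sire_devs[t])
                  for t, ts in config.traits.items()}
            birth_w = max(0.5, tv["birth_weight"])
            growth = tv["growth_rate"]
            weaning_w = birth_w + growth * age_wean / 1000.0
            tailing_w = birth_w + growth * 21.0 / 1000.0

            ph = PhenotypeSet(
                birth_weight=birth_w, tailing_weight=tailing_w,
                weaning_weight=weaning_w, growth_rate=growth)
            age_slaughter: Optional[float] = None
            live_weight = weaning_w + config.post_weaning_gain \
                * config.slaughter_age_offset / 1000.0
            if male and live_weight > config.slaughter_threshold:
                age_slaughter = age_wean + config.slaughter_age_offset
                leg = max(0.1, tv["leg_yield"])
                loin = max(0.1, tv["loin_yield"])
                shoulder = max(0.1, tv["shoulder_yield"])
                total, p_leg, p_loin, p_sh = derive_composition(
                    leg, loin, shoulder)
                ph.hot_carcass_weight = max(1.0, tv["hot_carcass_weight"])
                ph.vgr = tv["vgr"]
                ph.leg_yield, ph.loin_yield, ph.shoulder_yield = leg, loin, shoulder
                ph.total_yield = total
                ph.prop_leg, ph.prop_loin, ph.prop_shoulder = p_leg, p_loin, p_sh
            if config.missing_rate > 0:
                for t in ("birth_weight", "tailing_weight", "weaning_weight",
                          "growth_rate"):
                    if rng.random() < config.missing_rate:
                        setattr(ph, t, None)

            gp, gc = dip.collapse()
            if config.mislabel_rate > 0:
                if rng.random() < config.mislabel_rate:
                    gp = _mislabel(gp, rng, registry)
                if rng.random() < config.mislabel_rate:
                    gc = _mislabel(gc, rng, registry)
            records.append(AnimalRecord(
                animal_id=aid, sire_id=sire_id,
                gender=Gender.MALE if male else Gender.FEMALE,
                birth_rank=_RANKS[birth_i], rearing_rank=_RANKS[rear_i],
                age_weaning=age_wean, age_slaughter=age_slaughter,
                genotype_prom=gp, genotype_coding=gc, phenotypes=ph))
            truth[aid] = TruthRow(aid, sire_id, dip, sire_dip,
                                  sire_hap, dam_hap)
    return SyntheticCohort(records, truth, sire_truth)
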