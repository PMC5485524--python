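"""Two-locus diplotype inference in half-sib families.

The two amplified regions are treated as fully linked, so each animal's
diplotype is a pair of two-locus haplotypes whose region-wise "collapse"
must reproduce the observed unphased genotypes.  An animal homozygous at
either region has a single compatible diplotype and is phased *directly*;
a double heterozygote has exactly two compatible diplotypes and is phased
by comparison with its sire: the candidate that shares a haplotype with
the reconstructed sire diplotype wins.  A sire transmits one of its two
haplotypes to each progeny (roughly half/half across a family), which is
what makes the reconstruction possible; dams are an unobserved population
pool.  Ambiguity is surfaced, never broken arbitrarily.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genodata import (AnimalRecord, Diplotype, Haplotype, IntegrityError,
                       Region, RegionGenotype)


class PhaseMethod(str, enum.Enum):
    DIRECT = "direct"
    SIRE_INFORMED = "sire_informed"
    UNRESOLVED = "unresolved"
    INCONSISTENT = "inconsistent"


@dataclass
class PhasingOutcome:
    animal_id: str
    candidates: frozenset[Diplotype]
    resolved: Optional[Diplotype]
    method: PhaseMethod

    def __post_init__(self) -> None:
        has = self.method in (PhaseMethod.DIRECT, PhaseMethod.SIRE_INFORMED)
        if (self.resolved is not None) != has:
            raise ValueError("resolved diplotype inconsistent with method")


@dataclass
class SireDiplotypeEstimate:
    sire_id: str
    support: dict[Diplotype, int]
    chosen: Optional[Diplotype]
    ambiguous: bool
    n_consistent_progeny: int = 0


def enumerate_candidate_diplotypes(g1: RegionGenotype, g2: RegionGenotype
                                   ) -> frozenset[Diplotype]:
    """All diplotypes whose region-wise collapse equals ``(g1, g2)``.

    One candidate when either region is homozygous, two when both are
    heterozygous (the two cis/trans pairings).
    """
    if g1.region is not Region.PROM_EX1 or g2.region is not Region.INT2_EX3:
        raise ValueError("expected (PROM_EX1, INT2_EX3) genotypes")
    a, b = g1.labels
    x, y = g2.labels
    return frozenset({
        Diplotype.of(Haplotype(a, x), Haplotype(b, y)),
        Diplotype.of(Haplotype(a, y), Haplotype(b, x)),
    })


def _consistent(sire: Diplotype, candidates: frozenset[Diplotype]) -> bool:
    """A progeny is compatible with a sire diplotype iff some candidate of
    the progeny shares at least one haplotype with it."""
    sire_haps = set(sire.haplotypes)
    return any(not sire_haps.isdisjoint(c.haplotypes) for c in candidates)


def _support(sire: Diplotype,
             progeny: Sequence[frozenset[Diplotype]]) -> int:
    """Transmission support: over the sire's two chromosome slots (with
    multiplicity), the number of directly-phased progeny carrying that
    slot's haplotype.  A homozygous sire therefore counts each carrier
    twice, which is what distinguishes it from a heterozygous candidate
    pairing the same haplotype with one seen on no progeny chromosome."""
    direct = [next(iter(cands)) for cands in progeny if len(cands) == 1]
    return sum(sum(d.contains(h) for d in direct) for h in sire.haplotypes)


def reconstruct_sire_diplotype(
        sire_id: str,
        progeny_candidates: Sequence[frozenset[Diplotype]],
        sire_genotypes: Optional[tuple[RegionGenotype, RegionGenotype]] = None,
) -> SireDiplotypeEstimate:
    """Infer a sire's diplotype from its half-sib progeny.

    Candidate sire diplotypes are those enumerable from the sire's own
    genotypes when supplied, otherwise all pairs over the haplotypes seen in
    any progeny candidate.  Candidates are ranked by (number of compatible
    progeny, support); requiring compatibility with *all* progeny first
    makes the estimate robust to a single mistyped progeny.  The estimate is
    ambiguous when no candidate uniquely maximises that ranking.
    """
    if not progeny_candidates:
        raise ValueError("at least one progeny required")
    if sire_genotypes is not None:
        pool: Iterable[Diplotype] = enumerate_candidate_diplotypes(*sire_genotypes)
    else:
        observed = sorted({h for cands in progeny_candidates
                           for c in cands for h in c.haplotypes})
        pool = (Diplotype.of(h1, h2) for h1, h2
                in itertools.combinations_with_replacement(observed, 2))
    scored: dict[Diplotype, tuple[int, int]] = {}
    for d in pool:
        n_cons = sum(_consistent(d, cands) for cands in progeny_candidates)
        scored[d] = (n_cons, _support(d, progeny_candidates))
    if not scored:
        return SireDiplotypeEstimate(sire_id, {}, None, True, 0)
    best = max(scored.values())
    winners = [d for d, s in scored.items() if s == best]
    chosen = winners[0] if len(winners) == 1 else None
    return SireDiplotypeEstimate(
        sire_id=sire_id,
        support={d: s[1] for d, s in sorted(scored.items())},
        chosen=chosen,
        ambiguous=chosen is None,
        n_consistent_progeny=best[0])


def resolve_progeny(animal_id: str, candidates: frozenset[Diplotype],
                    sire: Optional[SireDiplotypeEstimate]) -> PhasingOutcome:
    """Resolve one progeny's diplotype given its sire estimate.

    A single candidate is a direct resolution.  With two candidates, the
    one sharing a haplotype with the chosen sire diplotype is selected;
    zero survivors mean the genotypes contradict the sire (inconsistent),
    two survivors or an ambiguous sire leave the animal unresolved.
    """
    if len(candidates) == 1:
        (d,) = candidates
        return PhasingOutcome(animal_id, candidates, d, PhaseMethod.DIRECT)
    if sire is None or sire.chosen is None:
        return PhasingOutcome(animal_id, candidates, None, PhaseMethod.UNRESOLVED)
    sire_haps = set(sire.chosen.haplotypes)
    survivors = [c for c in sorted(candidates)
                 if not sire_haps.isdisjoint(c.haplotypes)]
    if len(survivors) == 1:
        return PhasingOutcome(animal_id, candidates, survivors[0],
                              PhaseMethod.SIRE_INFORMED)
    if not survivors:
        return PhasingOutcome(animal_id, candidates, None,
                              PhaseMethod.INCONSISTENT)
    return PhasingOutcome(animal_id, candidates, None, PhaseMethod.UNRESOLVED)


@dataclass
class CohortPhasing:
    outcomes: dict[str, PhasingOutcome]
    sires: dict[str, SireDiplotypeEstimate]

    @property
    def resolved(self) -> dict[str, Diplotype]:
        return {aid: o.resolved for aid, o in self.outcomes.items()
                if o.resolved is not None}


def phase_cohort(records: Sequence[AnimalRecord]) -> CohortPhasing:
    """Phase a whole half-sib cohort in two passes.

    Pass 1 enumerates every progeny's candidate diplotypes and reconstructs
    each sire; pass 2 resolves the double heterozygotes against their sire.
    Records with a null ``sire_id`` are treated as sires/founders: their own
    genotypes, when present, constrain the reconstruction but they receive
    no progeny-style outcome.  Unresolved and inconsistent animals keep a
    null diplotype and are dropped downstream.
    """
    by_id = {}
    for r in records:
        if r.animal_id in by_id:
            raise IntegrityError(f"duplicate animal id {r.animal_id!r}")
        by_id[r.animal_id] = r
    progeny = [r for r in records if r.sire_id is not None]
    sire_rows = {r.animal_id: r for r in records if r.sire_id is None}
    if sire_rows:
        # when the table carries explicit sire rows, every progeny must
        # reference one of them
        for r in progeny:
            if r.sire_id not in sire_rows:
                raise IntegrityError(f"unknown sire id {r.sire_id!r} "
                                     f"for progeny {r.animal_id!r}")
    for r in progeny:
        if r.genotype_prom is None or r.genotype_coding is None:
            raise IntegrityError(f"progeny {r.animal_id!r} lacks genotypes")

    families: dict[str, list[AnimalRecord]] = {}
    for r in progeny:
        families.setdefault(r.sire_id, []).append(r)

    candidates = {r.animal_id: enumerate_candidate_diplotypes(
        r.genotype_prom, r.genotype_coding) for r in progeny}

    sires: dict[str, SireDiplotypeEstimate] = {}
    for sire_id in sorted(families):
        fam = sorted(families[sire_id], key=lambda r: r.animal_id)
        geno = None
        row = sire_rows.get(sire_id)
        if row is not None and row.genotype_prom is not None \
                and row.genotype_coding is not None:
            geno = (row.genotype_prom, row.genotype_coding)
        sires[sire_id] = reconstruct_sire_diplotype(
            sire_id, [candidates[r.animal_id] for r in fam], geno)

    outcomes: dict[str, PhasingOutcome] = {}
    for r in sorted(progeny, key=lambda r: r.animal_id):
        outcomes[r.animal_id] = resolve_progeny(
            r.animal_id, candidates[r.animal_id], sires[r.sire_id])
    return CohortPhasing(outcomes=outcomes, sires=sires)


@dataclass
class FrequencyTable:
    """Chromosome-count haplotype (or animal-count diplotype) frequencies."""

    counts: dict  # Haplotype|Diplotype -> int
    total: int

    @property
    def frequencies(self) -> dict:
        return {k: v / self.total for k, v in self.counts.items()}

    def sorted_items(self) -> list[tuple[object, int, float]]:
        """(key, count, frequency) by descending frequency, then label."""
        return sorted(((k, v, v / self.total) for k, v in self.counts.items()),
                      key=lambda t: (-t[1], t[0].display()))


def estimate_frequencies(outcomes: Iterable[PhasingOutcome]
                         ) -> tuple[FrequencyTable, FrequencyTable]:
    """Haplotype (chromosome-counting) and diplotype frequency tables over
    resolved animals only."""
    hap_counts: dict[Haplotype, int] = {}
    dip_counts: dict[Diplotype, int] = {}
    n = 0
    for o in outcomes:
        if o.resolved is None:
            continue
        n += 1
        dip_counts[o.resolved] = dip_counts.get(o.resolved, 0) + 1
        for h in o.resolved.haplotypes:
            hap_counts[h] = hap_counts.get(h, 0) + 1
    if n == 0:
        raise ValueError("no resolved animals: cannot estimate frequencies")
    return (FrequencyTable(hap_counts, 2 * n), FrequencyTable(dip_counts, n))
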