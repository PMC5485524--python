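"""Brute-force oracle for half-sib phasing, independent of the package's
incremental implementation.

Everything here enumerates explicitly: candidate diplotypes are found by
trying every ordered pairing of region alleles; sire candidates are every
unordered pair over the observed haplotypes, scored by walking all
chromosome-origin assignments of the directly-phased progeny.
"""

import itertools

import numpy as np

from lambhap.genodata import Diplotype, Haplotype


def random_family(rng, max_progeny=10):
    """A seeded half-sib family over a 3x3 variant grid: the true sire
    diplotype and the progeny's true diplotypes (one sire chromosome,
    one dam chromosome from a Dirichlet-weighted pool)."""
    pool = [Haplotype(a, x) for a in ("A1", "B1", "C1")
            for x in ("A3", "B3", "C3")]
    w = rng.dirichlet(np.ones(len(pool)) * 0.5)
    sire = Diplotype.of(pool[rng.choice(len(pool), p=w)],
                        pool[rng.choice(len(pool), p=w)])
    n = int(rng.integers(2, max_progeny + 1))
    progeny = [Diplotype.of(sire.haplotypes[rng.integers(0, 2)],
                            pool[rng.choice(len(pool), p=w)])
               for _ in range(n)]
    return sire, progeny


def oracle_candidates(g1, g2):
    """All diplotypes collapsing to (g1, g2), by exhaustive pairing."""
    out = set()
    for prom_perm in itertools.permutations(g1.labels):
        for cod_perm in itertools.permutations(g2.labels):
            h1 = Haplotype(prom_perm[0], cod_perm[0])
            h2 = Haplotype(prom_perm[1], cod_perm[1])
            d = Diplotype.of(h1, h2)
            gp, gc = d.collapse()
            if gp == g1 and gc == g2:
                out.add(d)
    return frozenset(out)


def _compatible(sire_dip, cand_set):
    """Does some (candidate, chromosome-origin) assignment put a sire
    chromosome into this progeny?  Checked by explicit enumeration."""
    for cand in cand_set:
        for origin in cand.haplotypes:          # which chromosome is paternal
            if origin in sire_dip.haplotypes:
                return True
    return False


def _transmission_support(sire_dip, cand_sets):
    """For each of the sire's two chromosomes in turn, count the
    directly-phased progeny that could have inherited it (carry that
    haplotype); sum over both chromosomes."""
    n = 0
    for slot_hap in sire_dip.haplotypes:       # two slots, with multiplicity
        for cand_set in cand_sets:
            if len(cand_set) != 1:
                continue
            (d,) = tuple(cand_set)
            if slot_hap in d.haplotypes:
                n += 1
    return n


def oracle_sire(cand_sets, sire_genotypes=None):
    """Best sire diplotype by exhaustive scoring.

    Returns (chosen_or_None, scores) where scores maps every candidate to
    (n_compatible_progeny, unique_origin_support); chosen is the unique
    maximiser of that pair, or None on a tie.
    """
    if sire_genotypes is not None:
        pool = oracle_candidates(*sire_genotypes)
    else:
        observed = sorted({h for cs in cand_sets for c in cs
                           for h in c.haplotypes})
        pool = {Diplotype.of(a, b) for a, b in
                itertools.combinations_with_replacement(observed, 2)}
    scores = {d: (sum(_compatible(d, cs) for cs in cand_sets),
                  _transmission_support(d, cand_sets)) for d in pool}
    best = max(scores.values())
    winners = [d for d, s in scores.items() if s == best]
    return (winners[0] if len(winners) == 1 else None), scores


def oracle_resolution(cand_set, sire_dip):
    """Forced resolution of one progeny under a known sire diplotype:
    the unique candidate admitting a paternal-origin assignment, else None
    (with a flag distinguishing contradiction from ambiguity)."""
    viable = [c for c in sorted(cand_set)
              if any(o in sire_dip.haplotypes for o in c.haplotypes)]
    if len(viable) == 1:
        return viable[0], "unique"
    return None, ("contradiction" if not viable else "ambiguous")
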