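"""Plain-text rendering of phasing and association outputs.

Decimal conventions follow the field's reporting style: weights to 2 dp,
growth rate to 1 dp, yields and fat depth to 2 dp, p-values to 3 dp,
frequencies as percentages to 2 dp.  All tables are tab-delimited UTF-8.
"""

from __future__ import annotations

import io
from typing import Optional, Sequence

from .assoc import (AssociationResult, DiplotypeResult,
                    classify_significance)
from .phasing import CohortPhasing, FrequencyTable

TRAIT_DECIMALS = {
    "birth_weight": 2, "tailing_weight": 2, "weaning_weight": 2,
    "growth_rate": 1, "hot_carcass_weight": 2, "vgr": 2,
    "leg_yield": 2, "loin_yield": 2, "shoulder_yield": 2, "total_yield": 2,
    "prop_leg": 2, "prop_loin": 2, "prop_shoulder": 2,
}


def _mean_se(mean: Optional[float], se: Optional[float], dp: int) -> str:
    if mean is None:
        return ""
    return f"{mean:.{dp}f} ± {se:.{dp}f}"


def _p(p: Optional[float]) -> str:
    return "" if p is None else f"{p:.3f}"


def _mark(p: Optional[float], alpha: float = 0.05) -> str:
    if p is None:
        return ""
    cls = classify_significance(p, alpha=alpha)
    return {"significant": "*", "trend": "~", "ns": ""}[cls.value]


def render_frequency_tables(hap_table: FrequencyTable,
                            dip_table: FrequencyTable) -> str:
    out = io.StringIO()
    out.write("haplotype\tchromosomes\tfrequency_pct\n")
    for hap, count, freq in hap_table.sorted_items():
        out.write(f"{hap.display()}\t{count}\t{freq * 100:.2f}\n")
    out.write(f"total\t{hap_table.total}\t100.00\n\n")
    out.write("diplotype\tanimals\tfrequency_pct\n")
    for dip, count, freq in dip_table.sorted_items():
        out.write(f"{dip.display()}\t{count}\t{freq * 100:.2f}\n")
    out.write(f"total\t{dip_table.total}\t100.00\n")
    return out.getvalue()


def render_phasing_table(phasing: CohortPhasing) -> str:
    out = io.StringIO()
    out.write("animal_id\tcandidates\tresolved\tmethod\n")
    for aid in sorted(phasing.outcomes):
        o = phasing.outcomes[aid]
        cands = ";".join(c.display() for c in sorted(o.candidates))
        res = o.resolved.display() if o.resolved else ""
        out.write(f"{aid}\t{cands}\t{res}\t{o.method.value}\n")
    return out.getvalue()


def render_sire_table(phasing: CohortPhasing) -> str:
    out = io.StringIO()
    out.write("sire_id\tchosen\tambiguous\tn_consistent_progeny\tsupport\n")
    for sid in sorted(phasing.sires):
        est = phasing.sires[sid]
        chosen = est.chosen.display() if est.chosen else ""
        support = ";".join(f"{d.display()}={s}"
                           for d, s in sorted(est.support.items())
                           if s > 0)
        out.write(f"{sid}\t{chosen}\t{est.ambiguous}\t"
                  f"{est.n_consistent_progeny}\t{support}\n")
    return out.getvalue()


def render_presence_table(results: Sequence[AssociationResult],
                          alpha: float = 0.05) -> str:
    """Series 1/2 table: one row per (trait, haplotype[, co-fits])."""
    out = io.StringIO()
    out.write("trait\thaplotype\tothers_in_model\tmean_se_absent\tn_absent\t"
              "mean_se_present\tn_present\tp_value\tflag\tstatus\n")
    for r in results:
        dp = TRAIT_DECIMALS.get(r.trait, 2)
        others = ",".join(h.display() for h in r.others) or "-"
        out.write("\t".join([
            r.trait, r.haplotype.display(), others,
            _mean_se(r.emm_absent, r.se_absent, dp), str(r.n_absent),
            _mean_se(r.emm_present, r.se_present, dp), str(r.n_present),
            _p(r.p_value), _mark(r.p_value, alpha), r.status]) + "\n")
    return out.getvalue()


def render_diplotype_table(results: Sequence[DiplotypeResult],
                           alpha: float = 0.05) -> str:
    """Series 3 table: per-trait group means with superscript letters."""
    out = io.StringIO()
    out.write("trait\tdiplotype\tn\tmean_se\tletters\toverall_p\tflag\t"
              "status\n")
    for r in results:
        dp = TRAIT_DECIMALS.get(r.trait, 2)
        if r.status != "ok":
            out.write(f"{r.trait}\t\t\t\t\t\t\t{r.status}\n")
            continue
        for d, n, emm, se, letters in zip(r.diplotypes, r.n, r.emm, r.se,
                                          r.letters):
            out.write("\t".join([
                r.trait, d.display(), str(n), _mean_se(emm, se, dp),
                letters, _p(r.overall_p), _mark(r.overall_p, alpha),
                r.status]) + "\n")
    return out.getvalue()


def render_machine_results(singles: Sequence[AssociationResult],
                           adjusted: Sequence[AssociationResult],
                           diplotype: Sequence[DiplotypeResult]) -> str:
    """One row per fitted term, for downstream tooling."""
    out = io.StringIO()
    out.write("series\ttrait\tterm\tothers\tn_absent\tn_present\t"
              "emm_absent\tse_absent\temm_present\tse_present\tp_value\t"
              "status\n")
    for series, results in (("single", singles), ("adjusted", adjusted)):
        for r in results:
            others = ",".join(h.display() for h in r.others)
            vals = [r.emm_absent, r.se_absent, r.emm_present, r.se_present]
            out.write("\t".join(
                [series, r.trait, r.haplotype.display(), others,
                 str(r.n_absent), str(r.n_present)]
                + ["" if v is None else repr(v) for v in vals]
                + [_p(r.p_value), r.status]) + "\n")
    for r in diplotype:
        if r.status != "ok":
            continue
        for d, n, emm, se in zip(r.diplotypes, r.n, r.emm, r.se):
            out.write("\t".join(
                ["diplotype", r.trait, d.display(), "", "", str(n),
                 "", "", repr(emm), repr(se), _p(r.overall_p), r.status])
                + "\n")
    return out.getvalue()
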