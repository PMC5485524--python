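"""Domain types, cohort-table I/O and trait arithmetic.

The pipeline works on lamb records from a half-sib breeding cohort.  Each
animal carries two unphased *region genotypes*: one for a promoter/exon-1
amplicon and one for an intron-2/exon-3 amplicon of the adiponectin gene
(ADIPOQ).  A haplotype pairs one variant from each region (e.g. ``A1–A3``);
a diplotype is the unordered pair of haplotypes an animal carries.
Variant labels are opaque identifiers assigned by gel typing — no sequence
handling happens here.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

EN_DASH = "–"


class Region(str, enum.Enum):
    """The two amplified gene regions whose variants compose a haplotype."""

    PROM_EX1 = "PROM_EX1"
    INT2_EX3 = "INT2_EX3"


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Rank(str, enum.Enum):
    """Birth or rearing rank; litters beyond triplets are not accepted."""

    SINGLE = "single"
    TWIN = "twin"
    TRIPLET = "triplet"


_DEFAULT_LABELS = {
    Region.PROM_EX1: ("A1", "B1", "C1", "D1"),
    Region.INT2_EX3: ("A3", "B3", "C3"),
}

#: SNPs underlying each amplicon, HGVS-style coordinates.  Descriptive
#: metadata only: phasing and association never consult nucleotide states.
SNP_POSITIONS = {
    Region.PROM_EX1: (
        "c.-9831A/G", "c.-9791C/T", "c.-9790G/T", "c.-9644G/A",
        "c.-9640A/G", "c.-9632C/T", "c.-9631A/G",
    ),
    Region.INT2_EX3: ("c.225T/C", "c.387A/G", "c.515G/A"),
}


class VariantRegistry:
    """Set of valid variant labels per region, extensible via config."""

    def __init__(self, labels: Optional[dict[Region, Iterable[str]]] = None):
        src = labels if labels is not None else _DEFAULT_LABELS
        self._labels = {r: tuple(src.get(r, ())) for r in Region}

    def labels(self, region: Region) -> tuple[str, ...]:
        return self._labels[region]

    def is_valid(self, region: Region, label: str) -> bool:
        return label in self._labels[region]

    def extended(self, region: Region, *labels: str) -> "VariantRegistry":
        merged = dict(self._labels)
        merged[region] = tuple(dict.fromkeys(merged[region] + labels))
        return VariantRegistry(merged)


DEFAULT_REGISTRY = VariantRegistry()


@dataclass(frozen=True, order=True)
class Haplotype:
    """One promoter/exon-1 variant linked to one intron-2/exon-3 variant."""

    prom: str
    coding: str

    def display(self) -> str:
        return f"{self.prom}{EN_DASH}{self.coding}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display()

    @classmethod
    def parse(cls, text: str) -> "Haplotype":
        parts = text.replace(EN_DASH, "-").split("-")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"cannot parse haplotype {text!r}")
        return cls(parts[0].strip(), parts[1].strip())


@dataclass(frozen=True, order=True)
class Diplotype:
    """Unordered pair of haplotypes; stored lexicographically sorted."""

    first: Haplotype
    second: Haplotype

    @classmethod
    def of(cls, h1: Haplotype, h2: Haplotype) -> "Diplotype":
        a, b = sorted((h1, h2))
        return cls(a, b)

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (self.first, self.second)

    def contains(self, hap: Haplotype) -> bool:
        return hap == self.first or hap == self.second

    def is_homozygous(self) -> bool:
        return self.first == self.second

    def collapse(self) -> tuple["RegionGenotype", "RegionGenotype"]:
        """Forget the phase: return the two observable region genotypes."""
        return (
            RegionGenotype.of(Region.PROM_EX1, self.first.prom, self.second.prom),
            RegionGenotype.of(Region.INT2_EX3, self.first.coding, self.second.coding),
        )

    def display(self) -> str:
        return f"{self.first.display()}/{self.second.display()}"

    def __str__(self) -> str:  # pragma: no cover
        return self.display()

    @classmethod
    def parse(cls, text: str) -> "Diplotype":
        parts = text.split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse diplotype {text!r}")
        return cls.of(Haplotype.parse(parts[0]), Haplotype.parse(parts[1]))


@dataclass(frozen=True)
class RegionGenotype:
    """Unphased, unordered pair of variant labels at one region."""

    region: Region
    labels: tuple[str, str]

    @classmethod
    def of(cls, region: Region, a: str, b: str) -> "RegionGenotype":
        return cls(region, tuple(sorted((a, b))))  # type: ignore[arg-type]

    def is_homozygous(self) -> bool:
        return self.labels[0] == self.labels[1]

    def display(self) -> str:
        return "/".join(self.labels)

    @classmethod
    def parse(cls, region: Region, text: str,
              registry: VariantRegistry = DEFAULT_REGISTRY) -> "RegionGenotype":
        parts = [p.strip() for p in text.split("/")]
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"cannot parse genotype {text!r}")
        for p in parts:
            if not registry.is_valid(region, p):
                raise ValueError(f"unknown variant {p} for {region.value}")
        return cls.of(region, *parts)


# order matters: weights and yields grouped for rendering conventions
PHENOTYPE_FIELDS = (
    "birth_weight", "tailing_weight", "weaning_weight", "growth_rate",
    "hot_carcass_weight", "vgr",
    "leg_yield", "loin_yield", "shoulder_yield", "total_yield",
    "prop_leg", "prop_loin", "prop_shoulder",
)

CARCASS_TRAITS = frozenset(
    ("hot_carcass_weight", "vgr", "leg_yield", "loin_yield", "shoulder_yield",
     "total_yield", "prop_leg", "prop_loin", "prop_shoulder")
)


@dataclass
class PhenotypeSet:
    """Growth and carcass measurements; any field may be missing (None).

    Weights in kg, growth rate in g/day, V-GR (rib fat depth) in mm, lean
    meat yields in % of hot carcass weight, proportion yields in % of the
    total lean-meat yield.
    """

    birth_weight: Optional[float] = None
    tailing_weight: Optional[float] = None
    weaning_weight: Optional[float] = None
    growth_rate: Optional[float] = None
    hot_carcass_weight: Optional[float] = None
    vgr: Optional[float] = None
    leg_yield: Optional[float] = None
    loin_yield: Optional[float] = None
    shoulder_yield: Optional[float] = None
    total_yield: Optional[float] = None
    prop_leg: Optional[float] = None
    prop_loin: Optional[float] = None
    prop_shoulder: Optional[float] = None

    def get(self, trait: str) -> Optional[float]:
        return getattr(self, trait)

    def check_composition(self, tol: float = 1e-9) -> None:
        """Assert the arithmetic identities linking yields and proportions."""
        parts = (self.leg_yield, self.loin_yield, self.shoulder_yield)
        if all(v is not None for v in parts):
            total = sum(parts)  # type: ignore[arg-type]
            if self.total_yield is not None and abs(self.total_yield - total) > tol:
                raise ValueError("total_yield != leg+loin+shoulder")
            if self.total_yield is not None:
                for part, prop in zip(parts, (self.prop_leg, self.prop_loin,
                                              self.prop_shoulder)):
                    if prop is not None and abs(prop - part / total * 100.0) > tol:
                        raise ValueError("proportion yield inconsistent")
        props = (self.prop_leg, self.prop_loin, self.prop_shoulder)
        if all(v is not None for v in props):
            if abs(sum(props) - 100.0) > tol:  # type: ignore[arg-type]
                raise ValueError("proportion yields do not sum to 100")


@dataclass
class AnimalRecord:
    """Pedigree, structural factors, genotypes and phenotypes for one lamb.

    ``sire_id`` is None for sires/founders themselves.  Carcass phenotypes
    only occur for slaughtered males.
    """

    animal_id: str
    sire_id: Optional[str]
    gender: Gender
    birth_rank: Rank
    rearing_rank: Rank
    age_weaning: Optional[float] = None
    age_slaughter: Optional[float] = None
    genotype_prom: Optional[RegionGenotype] = None
    genotype_coding: Optional[RegionGenotype] = None
    phenotypes: PhenotypeSet = field(default_factory=PhenotypeSet)


def compute_growth_rate(birth_weight: float, weaning_weight: float,
                        age_days: float) -> float:
    """Pre-weaning growth rate in g/day from weights in kg."""
    if age_days <= 0:
        raise ValueError("age must be positive")
    return (weaning_weight - birth_weight) * 1000.0 / age_days


def derive_composition(leg: float, loin: float, shoulder: float
                       ) -> tuple[float, float, float, float]:
    """Total lean-meat yield and the three proportion yields.

    Returns ``(total, prop_leg, prop_loin, prop_shoulder)``; proportions are
    each region's share of the total, in percent, and sum to 100.
    """
    if min(leg, loin, shoulder) < 0:
        raise ValueError("yields must be non-negative")
    total = leg + loin + shoulder
    if total <= 0:
        raise ValueError("total yield must be positive")
    return (total, leg / total * 100.0, loin / total * 100.0,
            shoulder / total * 100.0)


# ---------------------------------------------------------------------------
# Table I/O


@dataclass
class TableSchema:
    """Column-name mapping for the cohort table; defaults match the writer."""

    animal_id: str = "animal_id"
    sire_id: str = "sire_id"
    gender: str = "gender"
    birth_rank: str = "birth_rank"
    rearing_rank: str = "rearing_rank"
    age_weaning: str = "age_weaning"
    age_slaughter: str = "age_slaughter"
    genotype_prom: str = "genotype_prom"
    genotype_coding: str = "genotype_coding"
    phenotypes: dict[str, str] = field(
        default_factory=lambda: {t: t for t in PHENOTYPE_FIELDS})

    MANDATORY = ("animal_id", "sire_id", "gender", "birth_rank",
                 "rearing_rank", "genotype_prom", "genotype_coding")


@dataclass
class ValidationIssue:
    animal_id: str
    column: str
    message: str
    fatal: bool = True


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    n_read: int = 0
    n_accepted: int = 0

    def add(self, animal_id: str, column: str, message: str,
            fatal: bool = True) -> None:
        self.issues.append(ValidationIssue(animal_id, column, message, fatal))

    @property
    def n_excluded(self) -> int:
        return self.n_read - self.n_accepted

    def write(self, stream: TextIO) -> None:
        w = csv.writer(stream)
        w.writerow(["animal_id", "column", "message", "fatal"])
        for it in self.issues:
            w.writerow([it.animal_id, it.column, it.message, it.fatal])


class SchemaError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


def _detect_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") and \
        "\t" in header_line else ","


def _parse_float(text: str) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    value = float(text)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {text!r}")
    return value


def read_animal_table(source: TextIO | str, schema: Optional[TableSchema] = None,
                      registry: VariantRegistry = DEFAULT_REGISTRY,
                      ) -> tuple[list[AnimalRecord], ValidationReport]:
    """Parse a delimited cohort table into records plus a validation report.

    The delimiter (comma or tab) is auto-detected from the header line.
    Rows failing hard validation (bad genotype, rank, gender, duplicate id)
    are excluded and itemised in the report; missing phenotype cells parse
    to None.  Growth rate is recomputed from weights when no explicit
    growth-rate value is present; an explicit value wins and the
    discrepancy, if any, is not reconciled.
    """
    schema = schema or TableSchema()
    if isinstance(source, str):
        source = io.StringIO(source)
    first = source.readline()
    if not first:
        raise SchemaError("empty input: no header row")
    delim = _detect_delimiter(first)
    reader = csv.DictReader(io.StringIO(first + source.read()), delimiter=delim)
    header = reader.fieldnames or []
    for attr in TableSchema.MANDATORY:
        col = getattr(schema, attr)
        if col not in header:
            raise SchemaError(f"missing mandatory column {col!r}")

    report = ValidationReport()
    records: list[AnimalRecord] = []
    seen: set[str] = set()
    for row in reader:
        report.n_read += 1
        aid = (row.get(schema.animal_id) or "").strip()
        if not aid:
            report.add("", schema.animal_id, "missing animal id")
            continue
        if aid in seen:
            raise IntegrityError(f"duplicate animal id {aid!r}")
        seen.add(aid)
        ok = True

        def bad(column: str, message: str) -> None:
            nonlocal ok
            ok = False
            report.add(aid, column, message)

        sire = (row.get(schema.sire_id) or "").strip() or None
        try:
            gender = Gender((row.get(schema.gender) or "").strip().lower())
        except ValueError:
            bad(schema.gender, f"invalid gender {row.get(schema.gender)!r}")
            gender = None
        ranks = {}
        for attr in ("birth_rank", "rearing_rank"):
            col = getattr(schema, attr)
            try:
                ranks[attr] = Rank((row.get(col) or "").strip().lower())
            except ValueError:
                bad(col, f"invalid rank {row.get(col)!r}")
        genos = {}
        for attr, region in (("genotype_prom", Region.PROM_EX1),
                             ("genotype_coding", Region.INT2_EX3)):
            col = getattr(schema, attr)
            text = (row.get(col) or "").strip()
            if not text:
                genos[attr] = None
                continue
            try:
                genos[attr] = RegionGenotype.parse(region, text, registry)
            except ValueError as exc:
                bad(col, str(exc))
        ages = {}
        for attr in ("age_weaning", "age_slaughter"):
            col = getattr(schema, attr)
            try:
                ages[attr] = _parse_float(row.get(col, "") or "")
            except ValueError:
                bad(col, f"invalid number {row.get(col)!r}")
                ages[attr] = None
        pheno = PhenotypeSet()
        for trait, col in schema.phenotypes.items():
            if col not in row:
                continue
            try:
                setattr(pheno, trait, _parse_float(row.get(col) or ""))
            except ValueError:
                bad(col, f"invalid number {row.get(col)!r}")
        if not ok:
            continue
        if pheno.growth_rate is None and pheno.birth_weight is not None \
                and pheno.weaning_weight is not None \
                and ages["age_weaning"] is not None and ages["age_weaning"] > 0:
            pheno.growth_rate = compute_growth_rate(
                pheno.birth_weight, pheno.weaning_weight, ages["age_weaning"])
        records.append(AnimalRecord(
            animal_id=aid, sire_id=sire, gender=gender,
            birth_rank=ranks["birth_rank"], rearing_rank=ranks["rearing_rank"],
            age_weaning=ages["age_weaning"], age_slaughter=ages["age_slaughter"],
            genotype_prom=genos["genotype_prom"],
            genotype_coding=genos["genotype_coding"], phenotypes=pheno))
        report.n_accepted += 1
    return records, report


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(value)


def write_animal_table(records: Iterable[AnimalRecord], stream: TextIO,
                       schema: Optional[TableSchema] = None,
                       delimiter: str = ",") -> None:
    """Write records in the format ``read_animal_table`` accepts (round-trip
    safe: floats use repr so parsing reproduces them bit-exactly)."""
    schema = schema or TableSchema()
    cols = [schema.animal_id, schema.sire_id, schema.gender, schema.birth_rank,
            schema.rearing_rank, schema.age_weaning, schema.age_slaughter,
            schema.genotype_prom, schema.genotype_coding]
    cols += [schema.phenotypes[t] for t in PHENOTYPE_FIELDS]
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(cols)
    for r in records:
        row = [r.animal_id, r.sire_id or "",
               r.gender.value if r.gender else "",
               r.birth_rank.value if r.birth_rank else "",
               r.rearing_rank.value if r.rearing_rank else "",
               _fmt(r.age_weaning), _fmt(r.age_slaughter),
               r.genotype_prom.display() if r.genotype_prom else "",
               r.genotype_coding.display() if r.genotype_coding else ""]
        row += [_fmt(r.phenotypes.get(t)) for t in PHENOTYPE_FIELDS]
        w.writerow(row)
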