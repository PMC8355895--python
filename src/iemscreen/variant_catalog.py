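"""Genotype-table model, HGVS c.-notation parsing and allele accounting.

Confirmed cases carry up to two variant alleles per patient (single-variant
records occur — here the hemizygous/heterozygous OTC cases and one PCCB case
printed with "–" — and are first-class; large deletions, deep intronic or
promoter variants are the usual explanations for the undetected allele).
Variant identity is the *normalized printed string* keyed by gene: no
transcript or reference sequence accompanies the tables, so positional
normalization would be invention.  Known conflicts between the running text
and the tables are kept in :data:`KNOWN_DISCREPANCIES` rather than silently
merged.

The parser covers the coding-DNA (c.) dialects that occur in the fixture:
substitutions, deletions with/without stated bases, duplications, insertions,
deletion-insertions, intronic offsets (plus the legacy ``IVS`` token), and
free-text gross deletions ("2-7exon del", "1076bp del").  Unparseable strings
are retained and counted by string identity; parsing never gates counting.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .epi_stats import round_half_up_fraction
from .panel_model import IemscreenError
from fractions import Fraction


class HgvsParseError(IemscreenError):
    """The variant string does not match any supported c. dialect."""

    def __init__(self, text: str, reason: str = ""):
        self.text = text
        super().__init__(f"cannot parse variant {text!r}" + (f": {reason}" if reason else ""))


def normalize_hgvs(text: str) -> str:
    """Collapse whitespace and spacing around operators (> + _ .) as printed
    strings vary: "c.252 + 1G > A" → "c.252+1G>A"."""
    s = re.sub(r"\s+", " ", text.strip())
    return re.sub(r"\s*([>+_.])\s*", r"\1", s)


@dataclass(frozen=True)
class CPosition:
    """A cDNA coordinate, optionally with an intronic offset (c.252+1)."""

    base: int
    offset: int = 0

    def __str__(self) -> str:
        return f"{self.base}{self.offset:+d}" if self.offset else str(self.base)


@dataclass(frozen=True)
class ParsedVariant:
    """Structured form of one c.-notation variant."""

    kind: str  # substitution | deletion | duplication | insertion | delins | intronic | gross_deletion
    start: CPosition | None = None
    end: CPosition | None = None
    ref: str = ""
    alt: str = ""
    extent: str = ""  # free text for gross deletions / dup lengths / IVS tokens
    separator: str = "_"  # "_" or the printed "-" range dialect


@dataclass(frozen=True)
class Variant:
    """One allele: gene + printed HGVS c. string (the identity key) plus
    optional protein notation and novelty bookkeeping.

    ``novel_abstract`` marks membership in the publication's canonical
    unreported-variant list; ``novel_table`` records the tables' "#" marks,
    which disagree for a few variants — both are kept so the inconsistency is
    auditable.
    """

    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    novel_abstract: bool = False
    novel_table: bool = False
    parsed: ParsedVariant | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_c)


@dataclass(frozen=True)
class GenotypeRecord:
    patient_id: str
    cohort: str  # newborn | high_risk
    disorder: str
    gene: str
    allele1: Variant
    allele2: Variant | None  # None for single-variant records printed "–"
    sex: str = ""
    ethnicity: str = ""

    def __post_init__(self) -> None:
        if self.allele2 is not None and self.allele2.gene != self.allele1.gene:
            raise ValueError(f"{self.patient_id}: alleles on different genes")

    @property
    def homozygous(self) -> bool:
        return self.allele2 is not None and self.allele1.hgvs_c == self.allele2.hgvs_c

    @property
    def alleles(self) -> list[Variant]:
        return [self.allele1] if self.allele2 is None else [self.allele1, self.allele2]


# ---------------------------------------------------------------------------
# Parsing

_POS = r"(\d+)([+-]\d+)?"


def _cpos(base: str, offset: str | None) -> CPosition:
    b = int(base)
    if b < 1:
        raise ValueError("cDNA positions are 1-based")
    return CPosition(b, int(offset) if offset else 0)


def _span(m: re.Match) -> tuple[CPosition, CPosition | None, str]:
    """Positions for del/dup/delins matches (groups 1-5 = pos [sep pos]).

    Handles the printed hyphen-range dialect: a "negative offset" whose
    magnitude exceeds its own base (as in "c.132-134del…") cannot be an
    intronic offset and is read as an ascending span.
    """
    start = _cpos(m.group(1), m.group(2))
    if start.offset < 0 and -start.offset > start.base and m.group(4) is None:
        return CPosition(start.base), CPosition(-start.offset), "-"
    end = _cpos(m.group(4), m.group(5)) if m.group(4) else None
    return start, end, "_"


_SUB = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$")
_DELINS = re.compile(rf"^c\.{_POS}(?:(_){_POS})?del([ACGT]*)ins([ACGT]+)$")
_DEL = re.compile(rf"^c\.{_POS}(?:(_){_POS})?del([ACGT]*)$")
_DUP = re.compile(rf"^c\.{_POS}(?:(_){_POS})?dup(\d*|[ACGT]*)$")
_INS = re.compile(rf"^c\.{_POS}(_){_POS}ins([ACGT]+)$")
_IVS = re.compile(r"^IVS(\d+)([+-]\d+)([ACGT])>([ACGT])$")
_GROSS = re.compile(r"^(\d+-\d+exon|\d+bp) del$")


def parse_hgvs_c(text: str) -> ParsedVariant:
    """Parse one variant string into a :class:`ParsedVariant`.

    Raises :class:`HgvsParseError` for strings outside the supported
    dialects; callers keep such variants with ``parsed=None`` and count them
    by string identity.  Note the printed range dialect "c.132-134del…"
    (hyphen, not underscore): a hyphen separating two bare numbers where the
    second exceeds the first is read as a span, not an intronic offset.
    """
    s = normalize_hgvs(text)
    if not s:
        raise HgvsParseError(text, "empty")
    m = _GROSS.match(s)
    if m:
        return ParsedVariant(kind="gross_deletion", extent=s)
    m = _IVS.match(s)
    if m:
        return ParsedVariant(
            kind="intronic",
            start=CPosition(int(m.group(1)), int(m.group(2))),
            ref=m.group(3),
            alt=m.group(4),
            extent=f"IVS{m.group(1)}",
        )
    try:
        m = _SUB.match(s)
        if m:
            pos = _cpos(m.group(1), m.group(2))
            kind = "intronic" if pos.offset else "substitution"
            return ParsedVariant(kind=kind, start=pos, ref=m.group(3), alt=m.group(4))
        m = _DELINS.match(s)
        if m:
            start, end, sep = _span(m)
            return ParsedVariant(
                kind="delins", start=start, end=end, ref=m.group(6), alt=m.group(7),
                separator=sep,
            )
        m = _INS.match(s)
        if m:
            return ParsedVariant(
                kind="insertion",
                start=_cpos(m.group(1), m.group(2)),
                end=_cpos(m.group(4), m.group(5)),
                alt=m.group(6),
            )
        m = _DUP.match(s)
        if m:
            start, end, sep = _span(m)
            return ParsedVariant(
                kind="duplication", start=start, end=end, extent=m.group(6), separator=sep
            )
        m = _DEL.match(s)
        if m:
            start, end, sep = _span(m)
            return ParsedVariant(
                kind="deletion", start=start, end=end, ref=m.group(6), separator=sep
            )
    except ValueError as exc:
        raise HgvsParseError(text, str(exc)) from exc
    raise HgvsParseError(text)


def format_hgvs(v: ParsedVariant) -> str:
    """Regenerate the printed string from a parsed variant (round-trip)."""
    if v.kind == "gross_deletion":
        return v.extent
    if v.kind == "intronic" and v.extent.startswith("IVS"):
        return f"{v.extent}{v.start.offset:+d}{v.ref}>{v.alt}"  # type: ignore[union-attr]
    if v.kind in ("substitution", "intronic"):
        return f"c.{v.start}{v.ref}>{v.alt}"
    span = f"{v.start}" + (f"{v.separator}{v.end}" if v.end else "")
    if v.kind == "deletion":
        return f"c.{span}del{v.ref}"
    if v.kind == "duplication":
        return f"c.{span}dup{v.extent}"
    if v.kind == "insertion":
        return f"c.{span}ins{v.alt}"
    if v.kind == "delins":
        return f"c.{span}del{v.ref}ins{v.alt}"
    raise ValueError(f"unknown kind {v.kind!r}")


def _make_variant(gene: str, hgvs_c: str, hgvs_p: str, novel_abstract: bool, novel_table: bool) -> Variant:
    s = normalize_hgvs(hgvs_c)
    try:
        parsed = parse_hgvs_c(s)
    except HgvsParseError:
        parsed = None
    return Variant(
        gene=gene,
        hgvs_c=s,
        hgvs_p=normalize_hgvs(hgvs_p) if hgvs_p else "",
        novel_abstract=novel_abstract,
        novel_table=novel_table,
        parsed=parsed,
    )


# ---------------------------------------------------------------------------
# Fixture I/O

def load_genotypes(path: str | Path | None = None) -> list[GenotypeRecord]:
    """Load genotype records (default: the packaged 49-patient fixture)."""
    if path is None:
        text = resources.files("iemscreen.data").joinpath("genotypes.csv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    records = []
    for row in csv.DictReader(text.splitlines()):
        a1 = _make_variant(
            row["gene"], row["allele1_c"], row.get("allele1_p", ""),
            row.get("novel1_abstract", "0") == "1", row.get("novel1_table", "0") == "1",
        )
        a2 = None
        if row.get("allele2_c", "").strip() not in ("", "-", "–"):
            a2 = _make_variant(
                row["gene"], row["allele2_c"], row.get("allele2_p", ""),
                row.get("novel2_abstract", "0") == "1", row.get("novel2_table", "0") == "1",
            )
        records.append(
            GenotypeRecord(
                patient_id=row["patient_id"],
                cohort=row["cohort"],
                disorder=row["disorder"],
                gene=row["gene"],
                allele1=a1,
                allele2=a2,
                sex=row.get("sex", ""),
                ethnicity=row.get("ethnicity", ""),
            )
        )
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise IemscreenError("duplicate patient ids in genotype fixture")
    return records


def write_genotypes(records: Sequence[GenotypeRecord], path: str | Path) -> None:
    """Write records back to the fixture CSV layout (normalized strings)."""
    fieldnames = [
        "patient_id", "cohort", "disorder", "gene", "sex", "ethnicity",
        "allele1_c", "allele1_p", "allele2_c", "allele2_p",
        "novel1_abstract", "novel1_table", "novel2_abstract", "novel2_table",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fieldnames)
        w.writeheader()
        for r in records:
            a2 = r.allele2
            w.writerow({
                "patient_id": r.patient_id, "cohort": r.cohort, "disorder": r.disorder,
                "gene": r.gene, "sex": r.sex, "ethnicity": r.ethnicity,
                "allele1_c": r.allele1.hgvs_c, "allele1_p": r.allele1.hgvs_p,
                "allele2_c": a2.hgvs_c if a2 else "", "allele2_p": a2.hgvs_p if a2 else "",
                "novel1_abstract": int(r.allele1.novel_abstract),
                "novel1_table": int(r.allele1.novel_table),
                "novel2_abstract": int(a2.novel_abstract) if a2 else 0,
                "novel2_table": int(a2.novel_table) if a2 else 0,
            })


# ---------------------------------------------------------------------------
# Counting

@dataclass
class AlleleCountReport:
    """Per-variant allele occurrence counts within a scope.

    Every non-null allele contributes one occurrence (homozygotes contribute
    two to their variant; single-variant records contribute one to the
    total), so frequencies over a closed scope sum to 100% up to rounding.
    """

    scope: str
    counts: dict[str, int]
    total_alleles: int
    n_patients: int

    def frequency_percent(self, variant: str, precision: int = 1) -> float:
        if self.total_alleles == 0:
            return 0.0
        pct = round_half_up_fraction(
            Fraction(100 * self.counts.get(variant, 0), self.total_alleles), precision
        )
        return float(pct)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)


def allele_counts(
    records: Iterable[GenotypeRecord],
    *,
    gene: str | None = None,
    disorder: str | None = None,
    cohort: str | None = None,
) -> AlleleCountReport:
    """Count allele occurrences, optionally filtered by gene/disorder/cohort."""
    counts: dict[str, int] = {}
    total = 0
    patients = set()
    for r in records:
        if gene is not None and r.gene != gene:
            continue
        if disorder is not None and r.disorder != disorder:
            continue
        if cohort is not None and r.cohort != cohort:
            continue
        patients.add(r.patient_id)
        for allele in r.alleles:
            counts[allele.hgvs_c] = counts.get(allele.hgvs_c, 0) + 1
            total += 1
    scope = ", ".join(
        f"{k}={v}" for k, v in (("gene", gene), ("disorder", disorder), ("cohort", cohort))
        if v is not None
    ) or "all records"
    return AlleleCountReport(
        scope=scope, counts=counts, total_alleles=total, n_patients=len(patients)
    )


def hotspot_rank(report: AlleleCountReport, min_count: int = 1) -> list[tuple[str, int]]:
    """Variants ordered by occurrence count (desc), ties lexicographic."""
    items = [(v, c) for v, c in report.counts.items() if c >= min_count]
    items.sort(key=lambda vc: (-vc[1], vc[0]))
    return items


def cohort_gene_summary(
    records: Iterable[GenotypeRecord],
) -> tuple[int, int, int, int]:
    """(n_patients, n_genes, n_distinct_variants, n_novel) over the records.

    Distinctness is by (gene, normalized hgvs_c) string identity; novel
    counts distinct variants on the publication's unreported list.
    """
    patients, genes, variants, novel = set(), set(), set(), set()
    for r in records:
        patients.add(r.patient_id)
        genes.add(r.gene)
        for a in r.alleles:
            variants.add(a.key)
            if a.novel_abstract:
                novel.add(a.key)
    return len(patients), len(genes), len(variants), len(novel)


def carrier_frequency(
    carrier_counts: Mapping[str, int],
    n_carriers: int,
    *,
    integer_percent: bool = False,
) -> dict[str, float]:
    """Per-variant share of carriers, as percentages.

    ``integer_percent`` rounds half-up to whole percent (the convention used
    for carrier-screening summaries); otherwise one decimal.
    """
    if n_carriers <= 0:
        raise ValueError("n_carriers must be positive")
    precision = 0 if integer_percent else 1
    return {
        v: float(round_half_up_fraction(Fraction(100 * c, n_carriers), precision))
        for v, c in carrier_counts.items()
    }


#: text-vs-table conflicts in the source report, kept auditable rather than resolved
KNOWN_DISCREPANCIES: tuple[str, ...] = (
    "SLC22A5: running text says '11 kinds of 26 mutation sites', but the genotype "
    "tables give 14 PCD patients x 2 alleles = 28 occurrences, and the quoted "
    "c.51C>G frequency (~28.6%) equals 8/28 — the table-derived total is 28.",
    "IVD: text lists c.158G>A and omits c.149G>A/c.1199A>G; the tables print "
    "c.149G>A and c.1199A>G and give c.1208A>G three occurrences, not four — "
    "tables transcribed verbatim, counts keyed to the tables.",
    "PAH: text variant list has c.28G>A where the tables print c.728G>A (twice).",
    "ACADS: text says 'six kinds' then lists seven variants; the tables give "
    "seven distinct variants over eight alleles.",
    "ACADM: the MCADD genotype is printed 'c.580A >' with no alternate base; "
    "retained verbatim (unparseable, counted by string identity).",
    "Novelty marks: HPD c.93+1delG is '#'-marked in the tables but absent from "
    "the unreported-variant list; HPD c.941T>C is on the list but not '#'-marked; "
    "SLC22A5 c.976C>T and c.919delG are '#'-marked but not on the list.",
    "CTLN2 labelling: the single newborn citrullinemia case is called 'type l "
    "(CTLN2)' in the text; the tables' CTLN2 label is used throughout.",
)
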