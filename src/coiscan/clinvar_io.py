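"""Readers and writers for ClinVar-style inputs.

This module owns the external formats the pipeline consumes and produces:

* ClinVar-dialect VCF releases carrying the ``CLNSIG``, ``CLNSIGCONF``,
  ``GENEINFO`` and ``ALLELEID`` INFO keys;
* gene whitelists (one symbol per line, ``#`` comments);
* GMT gene-set collections (MSigDB layout);
* the gene-property and variant-annotation TSV tables.

The central vocabulary is :class:`SignificanceClass`: the five ACMG tiers
(P, LP, VUS, LB, B) plus COI — ClinVar's aggregate "conflicting
interpretations of pathogenicity" status, which is a first-class state in
the VCF, not a combination of the tiers — and OTHER for everything else
(drug response, risk factors, ...).
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import zlib

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceClass",
    "ConflictBreakdown",
    "ClassificationRecord",
    "ReleaseSnapshot",
    "VariantKey",
    "MalformedRecordError",
    "VcfFormatError",
    "parse_clnsig",
    "parse_clnsigconf",
    "parse_release",
    "write_release",
    "read_whitelist",
    "read_gmt",
]


class MalformedRecordError(ValueError):
    """A single VCF record or INFO token could not be interpreted."""


class VcfFormatError(ValueError):
    """A release file violates the expected ClinVar VCF dialect."""


class SignificanceClass(str, Enum):
    """Five ACMG tiers, the COI aggregate state, and a catch-all."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    COI = "COI"
    OTHER = "OTHER"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


#: Five-tier classes, i.e. everything a resolved variant can become.
FIVE_TIER = frozenset(
    {
        SignificanceClass.P,
        SignificanceClass.LP,
        SignificanceClass.VUS,
        SignificanceClass.LB,
        SignificanceClass.B,
    }
)

# CLNSIG term -> class.  Slash dialects ("Pathogenic/Likely_pathogenic")
# resolve to the stronger / plain term; both the pre-2024 and the renamed
# 2024 conflict terms map to COI.  Matching is case-insensitive.
_CLNSIG_TABLE: dict[str, SignificanceClass] = {
    "pathogenic": SignificanceClass.P,
    "likely_pathogenic": SignificanceClass.LP,
    "pathogenic/likely_pathogenic": SignificanceClass.P,
    "uncertain_significance": SignificanceClass.VUS,
    "likely_benign": SignificanceClass.LB,
    "benign": SignificanceClass.B,
    "benign/likely_benign": SignificanceClass.B,
    "conflicting_interpretations_of_pathogenicity": SignificanceClass.COI,
    "conflicting_classifications_of_pathogenicity": SignificanceClass.COI,
}

# Class -> canonical CLNSIG term, used by the writer.
CLNSIG_TERM: dict[SignificanceClass, str] = {
    SignificanceClass.P: "Pathogenic",
    SignificanceClass.LP: "Likely_pathogenic",
    SignificanceClass.VUS: "Uncertain_significance",
    SignificanceClass.LB: "Likely_benign",
    SignificanceClass.B: "Benign",
    SignificanceClass.COI: "Conflicting_interpretations_of_pathogenicity",
    SignificanceClass.OTHER: "other",
}


def parse_clnsig(raw: str) -> SignificanceClass:
    """Map a CLNSIG INFO value to a :class:`SignificanceClass`.

    The mapping is total: any term not in the known vocabulary yields
    ``OTHER``.  Comma-joined multi-values resolve to COI if any component
    is a conflict term, otherwise to the first five-tier component, and to
    ``OTHER`` only when no component is recognised.

    Raises
    ------
    MalformedRecordError
        If *raw* is empty.
    """
    if not raw:
        raise MalformedRecordError("empty CLNSIG value")
    terms = [t.strip().lower() for t in raw.split(",") if t.strip()]
    if not terms:  # separators/whitespace only: unknown, not empty
        return SignificanceClass.OTHER
    mapped = [_CLNSIG_TABLE.get(t, SignificanceClass.OTHER) for t in terms]
    if SignificanceClass.COI in mapped:
        return SignificanceClass.COI
    for cls in mapped:
        if cls in FIVE_TIER:
            return cls
    return SignificanceClass.OTHER


@dataclass(frozen=True, slots=True)
class ConflictBreakdown:
    """Per-class submission counts behind a conflict (from CLNSIGCONF)."""

    counts: Mapping[SignificanceClass, int]

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative submission count for {cls}")

    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, cls: SignificanceClass) -> int:
        return self.counts.get(cls, 0)

    def to_string(self) -> str:
        """Render back to the ClinVar ``Term(count)|...`` grammar."""
        order = [
            SignificanceClass.P,
            SignificanceClass.LP,
            SignificanceClass.VUS,
            SignificanceClass.LB,
            SignificanceClass.B,
            SignificanceClass.OTHER,
        ]
        parts = [
            f"{CLNSIG_TERM[c]}({self.counts[c]})" for c in order if c in self.counts
        ]
        return "|".join(parts)


_CONF_TOKEN = re.compile(r"^(?P<term>.+?)\((?P<count>\d+)\)$")


def parse_clnsigconf(raw: str) -> ConflictBreakdown:
    """Parse a CLNSIGCONF value (``Term(count)`` joined by ``|``).

    Terms outside the five-tier vocabulary are retained under ``OTHER``.
    Counts for terms mapping to the same class are summed.
    """
    if not raw:
        raise MalformedRecordError("empty CLNSIGCONF value")
    counts: dict[SignificanceClass, int] = {}
    for token in raw.split("|"):
        token = token.strip()
        if not token:
            continue
        m = _CONF_TOKEN.match(token)
        if m is None:
            raise MalformedRecordError(f"unparseable CLNSIGCONF token {token!r}")
        term = m.group("term").strip().lower()
        cls = _CLNSIG_TABLE.get(term, SignificanceClass.OTHER)
        if cls is SignificanceClass.COI:
            # a conflict term inside the breakdown makes no sense
            raise MalformedRecordError(f"conflict term inside CLNSIGCONF: {token!r}")
        counts[cls] = counts.get(cls, 0) + int(m.group("count"))
    if not counts:
        raise MalformedRecordError(f"CLNSIGCONF value {raw!r} contains no tokens")
    return ConflictBreakdown(counts)


#: (contig without "chr", 1-based position, ref, alt)
VariantKey = tuple[str, int, str, str]


def normalize_variant_key(contig: str, pos: int, ref: str, alt: str) -> VariantKey:
    contig = contig[3:] if contig.lower().startswith("chr") else contig
    return (contig, int(pos), ref.upper(), alt.upper())


def format_variant_key(key: VariantKey) -> str:
    return "{}:{}:{}:{}".format(*key)


@dataclass(slots=True)
class ClassificationRecord:
    """One variant's classification state in one release."""

    variant_key: VariantKey
    genes: frozenset[str]
    clnsig_raw: str
    significance: SignificanceClass
    allele_id: int | None = None
    breakdown: ConflictBreakdown | None = None

    def __post_init__(self) -> None:
        if self.variant_key[2] == self.variant_key[3]:
            raise ValueError(f"ref equals alt for {self.variant_key}")
        if self.breakdown is not None and self.significance is not SignificanceClass.COI:
            raise ValueError("breakdown only allowed on COI records")


@dataclass(slots=True)
class ReleaseSnapshot:
    """All whitelisted classification records of one dated release."""

    release_date: _dt.date
    records: dict[VariantKey, ClassificationRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def read_whitelist(path: str | Path) -> set[str]:
    """Read a gene whitelist: one symbol per line, '#' starts a comment."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line)
    return symbols


def _parse_geneinfo(raw: str) -> set[str]:
    """GENEINFO 'SYM1:ID1|SYM2:ID2' -> {'SYM1', 'SYM2'}."""
    genes = set()
    for part in raw.split("|"):
        sym = part.split(":", 1)[0].strip()
        if sym:
            genes.add(sym)
    return genes


def parse_release(
    vcf_path: str | Path,
    release_date: _dt.date | str,
    gene_whitelist: Iterable[str],
) -> ReleaseSnapshot:
    """Parse one ClinVar-style VCF release into a :class:`ReleaseSnapshot`.

    Only variants whose GENEINFO intersects *gene_whitelist* are kept, and
    the kept record's gene set is the intersection.  Multi-allelic sites are
    split into one record per alt allele.  Duplicate variant keys within a
    file are resolved last-wins with a logged warning.

    Raises
    ------
    VcfFormatError
        If the header does not declare CLNSIG.
    """
    if isinstance(release_date, str):
        release_date = _dt.date.fromisoformat(release_date)
    whitelist = set(gene_whitelist)
    if not whitelist:
        raise ValueError("gene whitelist is empty")

    vcf = pysam.VariantFile(str(vcf_path))
    if "CLNSIG" not in vcf.header.info:
        raise VcfFormatError(f"{vcf_path}: header does not define INFO/CLNSIG")
    has_conf = "CLNSIGCONF" in vcf.header.info

    snapshot = ReleaseSnapshot(release_date=release_date)
    for rec in vcf:
        info = rec.info
        if "GENEINFO" not in info or "CLNSIG" not in info:
            continue
        genes = _parse_geneinfo(_info_str(info["GENEINFO"]))
        genes &= whitelist
        if not genes:
            continue
        clnsig_raw = _info_str(info["CLNSIG"])
        significance = parse_clnsig(clnsig_raw)
        breakdown = None
        if significance is SignificanceClass.COI and has_conf and "CLNSIGCONF" in info:
            breakdown = parse_clnsigconf(_info_str(info["CLNSIGCONF"]))
        allele_id = info.get("ALLELEID")
        if isinstance(allele_id, tuple):
            allele_id = allele_id[0]
        for alt in rec.alts or ():
            key = normalize_variant_key(rec.chrom, rec.pos, rec.ref, alt)
            if key in snapshot.records:
                logger.warning(
                    "%s: duplicate variant %s, keeping last record",
                    vcf_path,
                    format_variant_key(key),
                )
            snapshot.records[key] = ClassificationRecord(
                variant_key=key,
                genes=frozenset(genes),
                clnsig_raw=clnsig_raw,
                significance=significance,
                allele_id=None if allele_id is None else int(allele_id),
                breakdown=breakdown,
            )
    return snapshot


def _info_str(value: object) -> str:
    """pysam returns String INFO fields as str or tuple of str."""
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    return str(value)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##fileDate={date}
##INFO=<ID=ALLELEID,Number=1,Type=Integer,Description="ClinVar allele ID">
##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Aggregate clinical significance">
##INFO=<ID=CLNSIGCONF,Number=.,Type=String,Description="Conflicting clinical significance counts">
##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene symbol:gene id pairs, | separated">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_release(snapshot: ReleaseSnapshot, path: str | Path) -> None:
    """Write a snapshot as an uncompressed VCF 4.2 file.

    Emits only the INFO keys this pipeline consumes; records are sorted by
    variant key so output is bit-stable for a given snapshot.
    """
    path = Path(path)
    contigs = sorted({k[0] for k in snapshot.records},
                     key=lambda c: (not c.isdigit(),
                                    int(c) if c.isdigit() else c))
    lines = [_VCF_HEADER.format(
        date=snapshot.release_date.strftime("%Y%m%d"),
        contigs="".join(f"##contig=<ID={c}>\n" for c in contigs))]
    gene_id = {}
    for key in sorted(snapshot.records, key=_sort_key):
        rec = snapshot.records[key]
        contig, pos, ref, alt = rec.variant_key
        info_parts = []
        if rec.allele_id is not None:
            info_parts.append(f"ALLELEID={rec.allele_id}")
        info_parts.append(f"CLNSIG={rec.clnsig_raw}")
        if rec.breakdown is not None:
            info_parts.append(f"CLNSIGCONF={rec.breakdown.to_string()}")
        geneinfo = "|".join(
            f"{g}:{gene_id.setdefault(g, 1000 + zlib.crc32(g.encode()) % 100000)}"
            for g in sorted(rec.genes)
        )
        info_parts.append(f"GENEINFO={geneinfo}")
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{';'.join(info_parts)}\n"
        )
    path.write_text("".join(lines))


def _sort_key(key: VariantKey):
    contig, pos, ref, alt = key
    return (contig.rjust(4, "0") if contig.isdigit() else contig, pos, ref, alt)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members.

    Duplicate members collapse (set semantics); an empty set or a line with
    fewer than three fields is a format error.
    """
    collections: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise VcfFormatError(f"{path}:{i}: GMT line has fewer than 3 fields")
        name = fields[0]
        members = {g.strip() for g in fields[2:] if g.strip()}
        if not members:
            raise VcfFormatError(f"{path}:{i}: gene set {name!r} is empty")
        collections[name] = members
    return collections
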