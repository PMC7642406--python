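"""Variant records, VCF I/O and GATK-style hard filtration.

A :class:`VariantRecord` is one called variant for one individual: position,
alleles, a genotype class (0/1, 1/1 or 1/2 in VCF notation), the INFO quality
metrics the hard filters evaluate, and the set of named filters it failed
(empty = PASS). Multi-allelic records are kept intact rather than split,
because the 1/2 genotype class (heterozygous with two non-reference alleles)
is a first-class category in this analysis.

The hard filters mirror the classic GATK VariantFiltration recipe for
resequencing data: low coverage, quality-by-depth, mapping-quality rank sum,
Fisher strand bias (with a relaxed bound for InDels), haplotype score and
read-position rank sum (again relaxed for InDels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "VariantRecord",
    "FilterThresholds",
    "GENOTYPE_CLASSES",
    "classify_genotype",
    "variant_kind",
    "is_transition",
    "apply_hard_filters",
    "read_vcf",
    "write_vcf",
]

GENOTYPE_CLASSES = ("hom_ref", "het_ref_alt", "hom_alt", "het_alt_alt")

#: INFO keys the filters evaluate, in the order the filter names refer to them
INFO_KEYS = ("DP", "QD", "MQRankSum", "FS", "HaplotypeScore", "ReadPosRankSum")

_BASES = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotype_class: str
    kind: str  # "snp" | "indel"
    info: dict[str, float] = field(default_factory=dict)
    filter_status: set[str] = field(default_factory=set)
    not_evaluated: set[str] = field(default_factory=set)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype class {self.genotype_class!r}")

    @property
    def passes(self) -> bool:
        return not self.filter_status

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)


def variant_kind(ref: str, alts: Sequence[str]) -> str:
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return "snp"
    return "indel"


def classify_genotype(gt: Sequence[int | None], n_alts: int) -> tuple[str, list[str]]:
    """Map a GT allele-index tuple to a genotype class.

    Returns ``(class, flags)``; inconsistencies (missing alleles, allele index
    beyond the listed ALTs) are flagged rather than raised, so malformed rows
    are carried through visibly instead of dropped.
    """
    flags: list[str] = []
    if any(a is None for a in gt) or len(gt) != 2:
        return "hom_ref", ["malformed_gt"]
    a, b = sorted(gt)  # type: ignore[type-var]
    if b > n_alts:
        flags.append("gt_allele_out_of_range")
    if a == b == 0:
        cls = "hom_ref"
    elif a == 0:
        cls = "het_ref_alt"
    elif a == b:
        cls = "hom_alt"
    else:
        cls = "het_alt_alt"
    if cls == "het_alt_alt" and n_alts < 2:
        flags.append("gt_allele_out_of_range")
    return cls, flags


def is_transition(ref: str, alt: str) -> bool:
    """True iff the substitution is a purine↔purine or pyrimidine↔pyrimidine
    change, i.e. {ref, alt} is {A, G} or {C, T}."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"alleles must be A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return frozenset((ref, alt)) in _TRANSITIONS


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter bounds (fail conditions shown in comments)."""

    low_cov: float = 20.0          # DP <= low_cov
    qd_min: float = 2.0            # QD < qd_min
    mq_rank_min: float = -12.5     # MQRankSum < mq_rank_min
    fs_max_snp: float = 60.0       # FS > fs_max_snp (SNPs)
    fs_max_indel: float = 200.0    # FS > fs_max_indel (InDels)
    haplotype_max: float = 13.0    # HaplotypeScore > haplotype_max
    readpos_min_snp: float = -8.0  # ReadPosRankSum < readpos_min_snp (SNPs)
    readpos_min_indel: float = -20.0
    mq_rank_key: str = "MQRankSum"


def _filter_rules(rec: VariantRecord, t: FilterThresholds):
    indel = rec.kind == "indel"
    fs_max = t.fs_max_indel if indel else t.fs_max_snp
    rp_min = t.readpos_min_indel if indel else t.readpos_min_snp
    return (
        ("LowCovFilter", "DP", lambda v: v <= t.low_cov),
        ("QDFilter", "QD", lambda v: v < t.qd_min),
        ("MQFilter", t.mq_rank_key, lambda v: v < t.mq_rank_min),
        ("FSFilter", "FS", lambda v: v > fs_max),
        ("HaplotypeFilter", "HaplotypeScore", lambda v: v > t.haplotype_max),
        ("ReadPosFilter", "ReadPosRankSum", lambda v: v < rp_min),
    )


def apply_hard_filters(
    record: VariantRecord,
    thresholds: FilterThresholds | None = None,
    strict: bool = False,
) -> VariantRecord:
    """Evaluate every hard filter and return a copy with ``filter_status`` set.

    A metric missing from INFO leaves the corresponding filter unevaluated
    (recorded in ``not_evaluated``); with ``strict=True`` it raises instead.
    Idempotent: statuses are recomputed, never accumulated.
    """
    t = thresholds or FilterThresholds()
    failed: set[str] = set()
    missing: set[str] = set()
    for name, key, fails in _filter_rules(record, t):
        value = record.info.get(key)
        if value is None:
            if strict:
                raise KeyError(f"INFO key {key!r} required by {name} is missing")
            missing.add(name)
        elif fails(float(value)):
            failed.add(name)
    return replace(record, filter_status=failed, not_evaluated=missing)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

_INFO_META = {
    "DP": ("1", "Integer", "Approximate read depth"),
    "QD": ("1", "Float", "Variant confidence by depth"),
    "MQRankSum": ("1", "Float", "Mapping-quality rank sum"),
    "FS": ("1", "Float", "Fisher strand bias (phred)"),
    "HaplotypeScore": ("1", "Float", "Haplotype consistency score"),
    "ReadPosRankSum": ("1", "Float", "Read-position rank sum"),
}


def _header(contigs: Mapping[str, int], sample: str) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    for key, (num, typ, desc) in _INFO_META.items():
        h.info.add(key, num, typ, desc)
    h.formats.add("GT", "1", "String", "Genotype")
    for flt in (
        "LowCovFilter",
        "QDFilter",
        "MQFilter",
        "FSFilter",
        "HaplotypeFilter",
        "ReadPosFilter",
    ):
        h.filters.add(flt, None, None, f"Failed {flt}")
    h.add_sample(sample)
    return h


_GT_BY_CLASS = {
    "hom_ref": (0, 0),
    "het_ref_alt": (0, 1),
    "hom_alt": (1, 1),
    "het_alt_alt": (1, 2),
}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str,
    contigs: Mapping[str, int],
    sample: str = "sample",
) -> None:
    """Write records as an uncompressed single-sample VCF 4.2 file."""
    header = _header(contigs, sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            for key, value in rec.info.items():
                if key in _INFO_META:
                    row.info[key] = int(value) if key == "DP" else float(value)
            if rec.filter_status:
                for name in sorted(rec.filter_status):
                    row.filter.add(name)
            else:
                row.filter.add("PASS")
            row.samples[sample]["GT"] = _GT_BY_CLASS[rec.genotype_class]
            row.samples[sample].phased = False
            out.write(row)


def read_vcf(path: str) -> Iterator[VariantRecord]:
    """Yield one :class:`VariantRecord` per VCF line (multi-allelics intact)."""
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for row in vf:
            alts = tuple(row.alts or ())
            flags: list[str] = []
            if samples:
                gt = row.samples[samples[0]].get("GT", (None, None))
                cls, flags = classify_genotype(gt, len(alts))
            else:
                cls = "hom_ref"
                flags = ["no_sample"]
            info: dict[str, float] = {}
            for key in INFO_KEYS:
                if key in row.info:
                    val = row.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            status = {f for f in row.filter.keys() if f != "PASS"}
            yield VariantRecord(
                chrom=row.chrom,
                pos=row.pos,
                ref=row.ref,
                alts=alts,
                genotype_class=cls,
                kind=variant_kind(row.ref, alts) if alts else "snp",
                info=info,
                filter_status=status,
                flags=flags,
            )
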