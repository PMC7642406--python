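"""Read-mapping, read-retention, coverage and de novo assembly summaries.

Mapping categories (unique / non-unique / singletons / cross-contigs) are
taken as input counts from a flagstat-like table; percentages are relative to
total mapped reads. Expected fold-coverage uses the ceiling convention
ceil(n_reads × read_length / genome_size). Assembly metrics follow the usual
conventions: contigs below a minimum length are dropped before computing N50
(shortest contig among the largest contigs jointly covering ≥ 50% of total
assembly length) and %GC (C+G over total length, ambiguous bases counted in
the denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MappingSummary",
    "AssemblyMetrics",
    "mapping_summary",
    "retention_percent",
    "coverage_estimate",
    "filter_contigs",
    "n50",
    "gc_percent",
    "assembly_metrics",
]


@dataclass(frozen=True)
class MappingSummary:
    total_mapped: int
    unique: int
    non_unique: int
    singletons: int
    cross_contigs: int

    def percent(self, count: int) -> float:
        return round(100.0 * count / self.total_mapped, 2)

    @property
    def unique_percent(self) -> float:
        return self.percent(self.unique)

    @property
    def non_unique_percent(self) -> float:
        return self.percent(self.non_unique)

    @property
    def singletons_percent(self) -> float:
        return self.percent(self.singletons)

    @property
    def cross_contigs_percent(self) -> float:
        return self.percent(self.cross_contigs)

    def as_dict(self) -> dict[str, float | int]:
        return {
            "total_mapped": self.total_mapped,
            "unique": self.unique,
            "unique_percent": self.unique_percent,
            "non_unique": self.non_unique,
            "non_unique_percent": self.non_unique_percent,
            "singletons": self.singletons,
            "singletons_percent": self.singletons_percent,
            "cross_contigs": self.cross_contigs,
            "cross_contigs_percent": self.cross_contigs_percent,
        }


def mapping_summary(
    total_mapped: int,
    unique: int,
    non_unique: int,
    singletons: int = 0,
    cross_contigs: int = 0,
) -> MappingSummary:
    """Build a mapping summary from category counts (unique + non-unique must
    equal total mapped)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if min(unique, non_unique, singletons, cross_contigs) < 0:
        raise ValueError("category counts must be non-negative")
    if unique + non_unique != total_mapped:
        raise ValueError("unique + non_unique must equal total_mapped")
    return MappingSummary(total_mapped, unique, non_unique, singletons, cross_contigs)


def retention_percent(reads_kept: int, reads_total: int) -> float:
    """Percent of reads retained after quality filtering, to 1 d.p."""
    if reads_total <= 0:
        raise ValueError("reads_total must be positive")
    if not 0 <= reads_kept <= reads_total:
        raise ValueError("reads_kept must be in [0, reads_total]")
    return round(100.0 * reads_kept / reads_total, 1)


def coverage_estimate(n_reads: int, read_length: int, genome_size: int) -> int:
    """Expected fold coverage, ceil(n_reads × read_length / genome_size)."""
    if min(n_reads, read_length, genome_size) <= 0:
        raise ValueError("all inputs must be positive")
    return math.ceil(n_reads * read_length / genome_size)


def filter_contigs(contigs: Iterable[str], min_len: int = 1000) -> list[str]:
    """Drop contigs shorter than ``min_len`` (order preserved)."""
    return [c for c in contigs if len(c) >= min_len]


def n50(lengths: Sequence[int]) -> int:
    """Length of the shortest contig at which the descending cumulative sum
    first reaches half the total assembly length."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def gc_percent(contigs: Iterable[str]) -> float:
    """100 × (#C + #G) / total length; ambiguous bases stay in the denominator."""
    gc = total = 0
    for c in contigs:
        seq = c.upper()
        gc += seq.count("G") + seq.count("C")
        total += len(seq)
    if total == 0:
        raise ValueError("gc_percent of an empty sequence set is undefined")
    return 100.0 * gc / total


@dataclass(frozen=True)
class AssemblyMetrics:
    n_contigs: int
    total_size: int
    n50: int
    gc_percent: float

    def as_dict(self) -> dict[str, float | int]:
        return {
            "n_contigs": self.n_contigs,
            "total_size": self.total_size,
            "n50": self.n50,
            "gc_percent_rounded": round(self.gc_percent),
            "gc_percent": self.gc_percent,
        }


def assembly_metrics(contigs: Iterable[str], min_len: int = 1000) -> AssemblyMetrics:
    """Full assembly report after the minimum-length contig filter."""
    kept = filter_contigs(contigs, min_len)
    if not kept:
        raise ValueError("no contigs remain after length filtering")
    lengths = [len(c) for c in kept]
    return AssemblyMetrics(
        n_contigs=len(kept),
        total_size=sum(lengths),
        n50=n50(lengths),
        gc_percent=gc_percent(kept),
    )
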