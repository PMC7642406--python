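"""Genome-landscape summaries of a re-sequencing variant set.

Covers the descriptive statistics this kind of two-individual re-sequencing
comparison reports: transition/transversion ratios grouped by genomic context,
per-chromosome event frequencies with Tukey outlier fences, shared/exclusive
variant sets between individuals, zygosity tallies with het/hom and
het/non-reference-hom ratios, percentage of each genomic context affected, and
binned densities along chromosomes for heatmaps.

"Virtual" chromosomes (unplaced-sequence bins such as "Un" or "*_random")
are excluded from per-chromosome statistics when flagged, since their event
frequencies reflect assembly artefacts rather than biology.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantRecord, is_transition

__all__ = [
    "ChromosomeFrequency",
    "titv_ratio",
    "titv_by_group",
    "chromosome_frequencies",
    "tukey_fences",
    "shared_exclusive",
    "zygosity_summary",
    "het_hom_ratio",
    "context_percentages",
    "context_sizes_from_genes",
    "density_bins",
    "is_virtual_chromosome",
]

#: default name patterns flagging unplaced-sequence bins
VIRTUAL_PATTERNS = ("Un", "*Un", "*_random")

HET_CLASSES = ("het_ref_alt", "het_alt_alt")  # 0/1 and 1/2 both count as het


def is_virtual_chromosome(
    name: str, patterns: Sequence[str] = VIRTUAL_PATTERNS
) -> bool:
    return any(fnmatch.fnmatch(name, p) for p in patterns)


# ---------------------------------------------------------------------------
# Ti/Tv
# ---------------------------------------------------------------------------


def _allele_pairs(variants: Iterable[VariantRecord | tuple[str, str]]):
    for v in variants:
        if isinstance(v, tuple):
            yield v
        else:
            if v.kind != "snp":
                continue
            for alt in v.alts:
                yield (v.ref, alt)


def titv_ratio(variants: Iterable[VariantRecord | tuple[str, str]]) -> float | None:
    """Transitions over transversions; ``None`` when there are no transversions.

    Accepts variant records (SNPs only; every ALT allele of a multi-allelic
    record counts once) or raw ``(ref, alt)`` base pairs.
    """
    ti = tv = 0
    for ref, alt in _allele_pairs(variants):
        if is_transition(ref, alt):
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


def titv_by_group(
    variants: Iterable[VariantRecord], labels: Iterable[Hashable]
) -> dict[Hashable, float | None]:
    """Ti/Tv per group, for variants zipped with group labels (e.g. contexts)."""
    grouped: dict[Hashable, list[VariantRecord]] = {}
    for v, lab in zip(variants, labels):
        grouped.setdefault(lab, []).append(v)
    return {lab: titv_ratio(vs) for lab, vs in grouped.items()}


# ---------------------------------------------------------------------------
# per-chromosome frequencies and outlier fences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeFrequency:
    chrom: str
    event_count: int
    chrom_length: int
    frequency: float
    percent: float


def chromosome_frequencies(
    variants: Iterable[VariantRecord],
    chrom_lengths: Mapping[str, int],
    exclude_virtual: bool = True,
    virtual_patterns: Sequence[str] = VIRTUAL_PATTERNS,
) -> list[ChromosomeFrequency]:
    """Event count / chromosome length, one entry per (kept) chromosome."""
    counts: dict[str, int] = {c: 0 for c in chrom_lengths}
    for v in variants:
        if v.chrom not in chrom_lengths:
            raise KeyError(f"no length for chromosome {v.chrom!r}")
        counts[v.chrom] += 1
    out = []
    for chrom, length in chrom_lengths.items():
        if exclude_virtual and is_virtual_chromosome(chrom, virtual_patterns):
            continue
        freq = counts[chrom] / length
        out.append(
            ChromosomeFrequency(chrom, counts[chrom], length, freq, 100.0 * freq)
        )
    return out


def tukey_fences(
    values: Sequence[float], k: float = 1.5, method: str = "linear"
) -> tuple[float, float, np.ndarray]:
    """Tukey's outlier fences Q1 − k·IQR and Q3 + k·IQR.

    ``method`` is the quartile interpolation convention, passed straight to
    :func:`numpy.percentile` ("linear" is R's default type 7). Flags mark
    values strictly outside the fences. Requires at least 4 values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("tukey_fences needs at least 4 values")
    q1, q3 = np.percentile(arr, [25, 75], method=method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = (arr < lo) | (arr > hi)
    return float(lo), float(hi), flags


# ---------------------------------------------------------------------------
# shared / exclusive sets
# ---------------------------------------------------------------------------


def shared_exclusive(
    a: Iterable[Hashable], b: Iterable[Hashable]
) -> tuple[int, int, int]:
    """Venn counts ``(|A∩B|, |A\\B|, |B\\A|)`` over variant keys."""
    sa, sb = set(a), set(b)
    inter = sa & sb
    return len(inter), len(sa - inter), len(sb - inter)


# ---------------------------------------------------------------------------
# zygosity
# ---------------------------------------------------------------------------


def het_hom_ratio(n_het: int, n_hom: int) -> float | None:
    """Heterozygous over non-reference-homozygous ratio; None when hom = 0."""
    if n_hom == 0:
        return None
    return n_het / n_hom


def zygosity_summary(
    variants_by_individual: Mapping[str, Iterable[VariantRecord]],
    contexts: Mapping[str, Sequence[Hashable]] | None = None,
) -> pd.DataFrame:
    """Tally genotype classes per individual and variant kind.

    Returns a tidy frame with columns ``individual, kind, group, het_ref_alt,
    het_alt_alt, hom_alt, het, nonref_hom, het_hom_ratio``; het is 0/1 + 1/2
    counts, nonref_hom is 1/1. When ``contexts`` supplies a per-variant group
    label sequence for an individual, rows are additionally split by group
    (an "all" row is always present).
    """
    rows = []
    for ind, variants in variants_by_individual.items():
        vs = list(variants)
        labs = contexts.get(ind) if contexts else None
        groups: dict[Hashable, list[VariantRecord]] = {"all": vs}
        if labs is not None:
            if len(labs) != len(vs):
                raise ValueError("context labels must align with variants")
            for v, lab in zip(vs, labs):
                groups.setdefault(lab, []).append(v)
        for group, members in groups.items():
            for kind in ("snp", "indel"):
                sub = [v for v in members if v.kind == kind]
                c = {
                    cls: sum(v.genotype_class == cls for v in sub)
                    for cls in ("het_ref_alt", "het_alt_alt", "hom_alt")
                }
                het = c["het_ref_alt"] + c["het_alt_alt"]
                hom = c["hom_alt"]
                rows.append(
                    {
                        "individual": ind,
                        "kind": kind,
                        "group": group,
                        **c,
                        "het": het,
                        "nonref_hom": hom,
                        "het_hom_ratio": het_hom_ratio(het, hom),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# context percentages
# ---------------------------------------------------------------------------


def context_percentages(
    context_counts: Mapping[str, int], context_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Percent of each context's bp affected: 100 × events / context bp."""
    out = {}
    for ctx, n in context_counts.items():
        if ctx not in context_sizes:
            raise KeyError(f"no size supplied for context {ctx!r}")
        out[ctx] = 100.0 * n / context_sizes[ctx]
    return out


def context_sizes_from_genes(
    genes,
    chrom_lengths: Mapping[str, int],
    window: int = 5000,
) -> dict[str, int]:
    """Total bp per context class, partitioning the genome by precedence.

    Every base gets exactly one label under the same precedence order as
    variant context assignment (cds > utr > intron > upstream > downstream >
    intergenic), so the sizes sum to the genome length.
    """
    # label codes by ascending precedence so later assignment never overwrites
    order = ["intergenic", "downstream", "upstream", "intron", "utr3", "utr5", "cds"]
    code = {c: i for i, c in enumerate(order)}
    labels = {c: np.zeros(l, dtype=np.int8) for c, l in chrom_lengths.items()}

    def paint(chrom: str, start: int, end: int, ctx: str) -> None:
        arr = labels[chrom]
        lo = max(start - 1, 0)
        hi = min(end, len(arr))
        if lo >= hi:
            return
        sel = arr[lo:hi]
        sel[sel < code[ctx]] = code[ctx]
        arr[lo:hi] = sel

    for g in genes:
        if g.strand == "+":
            paint(g.chrom, g.start - window, g.start - 1, "upstream")
            paint(g.chrom, g.end + 1, g.end + window, "downstream")
        else:
            paint(g.chrom, g.end + 1, g.end + window, "upstream")
            paint(g.chrom, g.start - window, g.start - 1, "downstream")
        paint(g.chrom, g.start, g.end, "intron")
        for s, e in g.utr3:
            paint(g.chrom, s, e, "utr3")
        for s, e in g.utr5:
            paint(g.chrom, s, e, "utr5")
        for s, e in g.cds:
            paint(g.chrom, s, e, "cds")

    sizes = {c: 0 for c in order}
    for arr in labels.values():
        counts = np.bincount(arr, minlength=len(order))
        for ctx, i in code.items():
            sizes[ctx] += int(counts[i])
    return sizes


# ---------------------------------------------------------------------------
# density bins
# ---------------------------------------------------------------------------


def density_bins(
    variants: Iterable[VariantRecord],
    chrom_lengths: Mapping[str, int],
    bin_size: int,
) -> pd.DataFrame:
    """Per-chromosome binned variant counts (rows: chrom, cols: bin start bp)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = {c: (l + bin_size - 1) // bin_size for c, l in chrom_lengths.items()}
    width = max(n_bins.values(), default=0)
    mat = {c: np.zeros(width, dtype=int) for c in chrom_lengths}
    for v in variants:
        mat[v.chrom][(v.pos - 1) // bin_size] += 1
    df = pd.DataFrame.from_dict(mat, orient="index")
    df.columns = [i * bin_size for i in range(width)]
    df.index.name = "chrom"
    return df
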