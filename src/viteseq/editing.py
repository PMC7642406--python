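"""RNA-editing detection from matched DNA-seq and RNA-seq allele pileups.

An editing site is a position where a nucleotide observed in the transcriptome
is unsupported by the individual's genomic allele profile. The cascade has
three layers:

1. a transcriptome-side SNP prefilter (sequence-end distance, reference
   ambiguity, flanking copy number, allele quality/support, variant frequency
   and coverage) applied to RNA variant calls before any DNA comparison;
2. site-level gates on the matched pileups: ≥ 5× coverage in DNA and RNA
   simultaneously, the gene expressed with RPKM ≥ 1 in all six samples
   (two individuals × three developmental stages), and no insertion/deletion
   evidence at the site;
3. the allele comparison itself: alleles supported by ≥ 10% of covering reads
   are retained, a locus is homozygous when its top allele frequency is
   ≥ 0.90, and an RNA-retained base absent from the DNA profile is an editing
   call — "two_variant" when the genomic base is still seen in the RNA,
   "full_edit" when only the edited form remains.

Edits are reported in the DNA alphabet (T-to-A, not U-to-A). Expression is in
RPKM: 10^9 × gene reads / (exon-model length × total mapped reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import ContextLabel, GeneModel, assign_context, classify_snp_effect

__all__ = [
    "SitePileup",
    "AlleleProfile",
    "EditingCall",
    "RnaCallMetadata",
    "PrefilterThresholds",
    "rpkm",
    "expression_table",
    "rna_variant_prefilter",
    "allele_profile",
    "site_passes_filters",
    "call_editing",
    "detect_editing",
    "annotate_and_summarize",
]

BASES = ("A", "C", "G", "T")

#: chromosome-2 window this analysis centres on (sex-determining region);
#: any window may be supplied instead
DEFAULT_REGION = ("chr2", 4_907_434, 5_050_616)


@dataclass(frozen=True)
class SitePileup:
    """Per-site nucleotide read counts for one sample (DNA or RNA)."""

    chrom: str
    pos: int
    sample: str
    counts: Mapping[str, int]  # A/C/G/T
    deletions: int = 0
    insertions: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()) or min(self.deletions, self.insertions) < 0:
            raise ValueError("pileup counts must be non-negative")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES) + self.deletions

    @property
    def has_indel_evidence(self) -> bool:
        return self.deletions > 0 or self.insertions > 0


@dataclass(frozen=True)
class AlleleProfile:
    """Alleles surviving the read-support filter, with their frequencies."""

    alleles: Mapping[str, float]  # base -> frequency among covering reads
    zygosity: str  # "homozygous" | "heterozygous"

    @property
    def dominant(self) -> str:
        return max(self.alleles, key=lambda b: (self.alleles[b], b))

    def supports(self, base: str) -> bool:
        return base in self.alleles


@dataclass(frozen=True)
class EditingCall:
    chrom: str
    pos: int
    sample: str
    from_base: str
    to_base: str | None
    mode: str  # "none" | "two_variant" | "full_edit"
    rna_fraction: float = 0.0
    context: str | None = None
    gene_id: str | None = None
    impact: str | None = None


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def rpkm(gene_reads: int, exon_model_length: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_model_length <= 0 or total_mapped_reads <= 0:
        raise ValueError("exon model length and total mapped reads must be positive")
    return 1e9 * gene_reads / (exon_model_length * total_mapped_reads)


def expression_table(
    gene_counts: pd.DataFrame,
    exon_lengths: Mapping[str, int],
    totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """RPKM per gene × sample from a tidy (gene_id, sample, reads) frame.

    ``totals`` gives total mapped reads per sample; when omitted, the per-sample
    sum of the count table is used.
    """
    df = gene_counts.copy()
    if totals is None:
        totals = df.groupby("sample")["reads"].sum().to_dict()
    df["rpkm"] = [
        rpkm(int(r.reads), exon_lengths[r.gene_id], int(totals[r.sample]))
        for r in df.itertuples()
    ]
    return df


# ---------------------------------------------------------------------------
# transcriptome-side prefilter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RnaCallMetadata:
    """Per-call metadata the transcriptome SNP prefilter evaluates."""

    distance_to_sequence_end: int
    reference_ambiguous_within_60: bool
    flanking_copy_number: float
    min_allele_quality: float
    min_allele_support: int
    variant_frequency: float
    coverage: int


@dataclass(frozen=True)
class PrefilterThresholds:
    end_distance: int = 60
    max_copy_number: float = 2.0
    min_quality: float = 20.0
    min_support: int = 2
    min_frequency: float = 0.15
    min_coverage: int = 4


def rna_variant_prefilter(
    meta: RnaCallMetadata, t: PrefilterThresholds | None = None
) -> tuple[bool, str | None]:
    """Keep/discard an RNA variant call; returns (keep, first failing rule).

    Rules, in order: (1) call within the first/last 60 bases of its sequence;
    (2) ambiguous reference base at or within 60 bases; (3) average flanking
    copy number > 2; (4) either allele's quality < 20; (5) either allele
    supported by < 2 reads; then variant frequency < 15% and coverage < 4.
    """
    t = t or PrefilterThresholds()
    if meta.distance_to_sequence_end < t.end_distance:
        return False, "sequence_end"
    if meta.reference_ambiguous_within_60:
        return False, "ambiguous_reference"
    if meta.flanking_copy_number > t.max_copy_number:
        return False, "copy_number"
    if meta.min_allele_quality < t.min_quality:
        return False, "allele_quality"
    if meta.min_allele_support < t.min_support:
        return False, "allele_support"
    if meta.variant_frequency < t.min_frequency:
        return False, "variant_frequency"
    if meta.coverage < t.min_coverage:
        return False, "coverage"
    return True, None


# ---------------------------------------------------------------------------
# allele profiles and site gates
# ---------------------------------------------------------------------------


def allele_profile(
    pileup: SitePileup, support_frac: float = 0.10, hom_freq: float = 0.90
) -> AlleleProfile:
    """Retain alleles with frequency ≥ ``support_frac``; call zygosity.

    Frequencies are over the site depth (base counts plus deletions). Both
    thresholds are boundary-inclusive: a base at exactly 10% is retained and a
    top allele at exactly 0.90 makes the locus homozygous.
    """
    depth = pileup.depth
    if depth == 0:
        raise ValueError(f"zero-depth pileup at {pileup.chrom}:{pileup.pos}")
    freqs = {
        b: pileup.counts.get(b, 0) / depth
        for b in BASES
        if pileup.counts.get(b, 0) / depth >= support_frac
        and pileup.counts.get(b, 0) > 0
    }
    if not freqs:
        # every base below the support threshold (deep deletion pile):
        # keep the most-supported base so downstream logic has a genotype
        top = max(BASES, key=lambda b: pileup.counts.get(b, 0))
        freqs = {top: pileup.counts.get(top, 0) / depth}
    top_freq = max(freqs.values())
    zyg = "homozygous" if top_freq >= hom_freq else "heterozygous"
    return AlleleProfile(alleles=freqs, zygosity=zyg)


def site_passes_filters(
    dna: SitePileup,
    rna: SitePileup,
    expression: Mapping[str, float],
    is_indel_site: bool | None = None,
    min_coverage: int = 5,
    min_rpkm: float = 1.0,
    n_samples: int = 6,
) -> tuple[bool, list[str]]:
    """Site-level gates before the DNA/RNA allele comparison.

    ``expression`` maps each of the study's samples to the gene's RPKM; all
    samples must be present and ≥ ``min_rpkm``. ``is_indel_site`` defaults to
    the pileups' own insertion/deletion evidence.
    """
    if len(expression) != n_samples:
        raise ValueError(
            f"expression row covers {len(expression)} samples, expected {n_samples}"
        )
    reasons = []
    if dna.depth < min_coverage:
        reasons.append("dna_coverage")
    if rna.depth < min_coverage:
        reasons.append("rna_coverage")
    if min(expression.values()) < min_rpkm:
        reasons.append("expression")
    if is_indel_site is None:
        is_indel_site = dna.has_indel_evidence or rna.has_indel_evidence
    if is_indel_site:
        reasons.append("indel_site")
    return (not reasons), reasons


def call_editing(
    dna_profile: AlleleProfile,
    rna_profile: AlleleProfile,
    chrom: str = "",
    pos: int = 0,
    sample: str = "",
    require_zero_dna_reads: bool = False,
    dna_pileup: SitePileup | None = None,
) -> EditingCall:
    """Compare DNA and RNA allele profiles at one site.

    An RNA-retained base absent from the DNA profile is an editing call; the
    mode is ``two_variant`` when the genomic (dominant DNA) base is also
    retained in the RNA and ``full_edit`` otherwise. With
    ``require_zero_dna_reads`` the stricter optional rule applies: the edited
    base must have zero DNA reads, not merely sub-threshold support.
    """
    from_base = dna_profile.dominant
    unsupported = {
        b: f for b, f in rna_profile.alleles.items() if not dna_profile.supports(b)
    }
    if require_zero_dna_reads and dna_pileup is not None:
        unsupported = {
            b: f for b, f in unsupported.items() if dna_pileup.counts.get(b, 0) == 0
        }
    if not unsupported:
        return EditingCall(chrom, pos, sample, from_base, None, "none")
    to_base = max(unsupported, key=lambda b: (unsupported[b], b))
    mode = "two_variant" if rna_profile.supports(from_base) else "full_edit"
    return EditingCall(
        chrom, pos, sample, from_base, to_base, mode, rna_fraction=unsupported[to_base]
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _individual_of(sample: str) -> str:
    # samples are "<individual>_<stage>", e.g. WF_B
    return sample.rsplit("_", 1)[0]


def detect_editing(
    dna_pileups: Iterable[SitePileup],
    rna_pileups: Iterable[SitePileup],
    rpkm_by_gene: Mapping[str, Mapping[str, float]],
    gene_of_site: Mapping[tuple[str, int], str],
    genes: Sequence[GeneModel] | None = None,
    genome: Mapping[str, str] | None = None,
    support_frac: float = 0.10,
    hom_freq: float = 0.90,
    min_coverage: int = 5,
    min_rpkm: float = 1.0,
    require_zero_dna_reads: bool = False,
) -> pd.DataFrame:
    """Run the editing caller over matched pileups; one row per RNA sample × site.

    ``dna_pileups`` are per individual (sample = individual id); ``rna_pileups``
    per individual × stage (sample = "WF_B" style). ``rpkm_by_gene`` maps
    gene id → {sample: RPKM over all six samples}; ``gene_of_site`` maps
    (chrom, pos) → gene id. When ``genes`` and ``genome`` are given, calls get
    a genomic context and, inside CDS, a synonymous/non-synonymous impact.
    """
    dna_by_key = {(p.chrom, p.pos, p.sample): p for p in dna_pileups}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    genes_by_id: dict[str, GeneModel] = {}
    if genes is not None:
        for g in genes:
            genes_by_chrom.setdefault(g.chrom, []).append(g)
            genes_by_id[g.gene_id] = g
    rows = []
    for rna in rna_pileups:
        ind = _individual_of(rna.sample)
        key = (rna.chrom, rna.pos)
        dna = dna_by_key.get((rna.chrom, rna.pos, ind))
        gene_id = gene_of_site.get(key)
        base = {
            "chrom": rna.chrom,
            "pos": rna.pos,
            "sample": rna.sample,
            "gene_id": gene_id,
        }
        if dna is None:
            rows.append({**base, "mode": "filtered", "reasons": "no_dna_pileup"})
            continue
        if gene_id is None or gene_id not in rpkm_by_gene:
            rows.append({**base, "mode": "filtered", "reasons": "no_expression_data"})
            continue
        ok, reasons = site_passes_filters(
            dna,
            rna,
            rpkm_by_gene[gene_id],
            min_coverage=min_coverage,
            min_rpkm=min_rpkm,
        )
        if not ok:
            rows.append({**base, "mode": "filtered", "reasons": ";".join(reasons)})
            continue
        dprof = allele_profile(dna, support_frac, hom_freq)
        rprof = allele_profile(rna, support_frac, hom_freq)
        call = call_editing(
            dprof,
            rprof,
            rna.chrom,
            rna.pos,
            rna.sample,
            require_zero_dna_reads=require_zero_dna_reads,
            dna_pileup=dna,
        )
        row = {
            **base,
            "mode": call.mode,
            "from_base": call.from_base,
            "to_base": call.to_base,
            "rna_fraction": call.rna_fraction,
            "dna_zygosity": dprof.zygosity,
            "reasons": "",
        }
        if call.mode != "none" and genes is not None and genome is not None:
            label = _context_of(call, gene_id, genes_by_id, genes_by_chrom)
            row["context"] = label.context
            if label.context == "cds" and label.gene_id in genes_by_id:
                row["impact"] = _edit_impact(call, genes_by_id[label.gene_id], genome)
        rows.append(row)
    cols = [
        "chrom", "pos", "sample", "gene_id", "mode", "from_base", "to_base",
        "rna_fraction", "dna_zygosity", "context", "impact", "reasons",
    ]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = None
    return df[cols]


def _context_of(call, gene_id, genes_by_id, genes_by_chrom) -> ContextLabel:
    if gene_id in genes_by_id:
        g = genes_by_id[gene_id]
        feat = g._feature_at(call.pos)
        if feat is not None:
            return ContextLabel(feat, gene_id)
    return assign_context(call, genes_by_chrom)


@dataclass
class _PointVariant:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]


def _edit_impact(call: EditingCall, gene: GeneModel, genome) -> str:
    v = _PointVariant(call.chrom, call.pos, call.from_base, (call.to_base,))
    return classify_snp_effect(v, gene, genome)


def annotate_and_summarize(
    calls: pd.DataFrame,
    region: tuple[str, int, int] = DEFAULT_REGION,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene summary and a region report for a call table.

    The per-gene table counts edited loci (distinct positions with a non-none
    call), split into CDS and non-CDS, per gene. The region report counts
    calls inside/outside the configured genomic window and breaks down
    contexts and impacts.
    """
    edited = calls[~calls["mode"].isin(["none", "filtered"])].copy()
    if edited.empty:
        return (
            pd.DataFrame(
                columns=["gene_id", "n_loci", "n_cds_loci", "n_non_cds_loci", "n_calls"]
            ),
            {"region": list(region), "calls_inside": 0, "calls_outside": 0,
             "genes_with_editing": 0, "impact_breakdown": {}, "context_breakdown": {}},
        )
    rows = []
    for gene_id, sub in edited.groupby("gene_id", dropna=False):
        loci = sub.drop_duplicates(subset=["chrom", "pos"])
        n_cds = int((loci["context"] == "cds").sum())
        rows.append(
            {
                "gene_id": gene_id,
                "n_loci": len(loci),
                "n_cds_loci": n_cds,
                "n_non_cds_loci": len(loci) - n_cds,
                "n_calls": len(sub),
            }
        )
    per_gene = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
    chrom, lo, hi = region
    inside = (
        (edited["chrom"] == chrom) & (edited["pos"] >= lo) & (edited["pos"] <= hi)
    )
    report = {
        "region": [chrom, lo, hi],
        "calls_inside": int(inside.sum()),
        "calls_outside": int((~inside).sum()),
        "genes_with_editing": int(per_gene["gene_id"].nunique()),
        "context_breakdown": edited["context"].value_counts(dropna=True).to_dict(),
        "impact_breakdown": edited["impact"].value_counts(dropna=True).to_dict(),
        "mode_breakdown": edited["mode"].value_counts().to_dict(),
    }
    return per_gene, report
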