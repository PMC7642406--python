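"""Gene-context and protein-impact annotation of variants.

Re-implements the snpEff-style logic this kind of re-sequencing analysis relies
on: every variant gets exactly one genomic context relative to a set of gene
models (``cds > utr5/utr3 > intron > upstream > downstream > intergenic``, with
upstream/downstream taken over a 5 kbp strand-aware window), and variants that
land in coding sequence additionally get a protein-level impact class obtained
by rebuilding the codon (SNPs) or the coding sequence (InDels) on the coding
strand and translating with the standard nuclear code.

Coordinates follow the field's conventions: GFF3/VCF interfaces are 1-based
inclusive, internal interval arithmetic is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "ContextLabel",
    "CONTEXTS",
    "SNP_IMPACTS",
    "INDEL_IMPACTS",
    "assign_context",
    "classify_snp_effect",
    "classify_indel_effect",
    "load_gff3",
    "write_gff3",
]

# precedence: lower rank wins when several contexts apply
CONTEXTS = ("cds", "utr5", "utr3", "intron", "upstream", "downstream", "intergenic")
_RANK = {c: i for i, c in enumerate(CONTEXTS)}
# utr5 and utr3 share a precedence tier
_RANK["utr3"] = _RANK["utr5"]

SNP_IMPACTS = ("synonymous", "non_synonymous", "stop_gained", "stop_lost", "start_lost")
INDEL_IMPACTS = (
    "frameshift",
    "codon_insertion",
    "codon_deletion",
    "codon_change_plus_insertion",
    "codon_change_plus_deletion",
)

Interval = tuple[int, int]  # 1-based inclusive


class AnnotationError(ValueError):
    """Raised when a variant and a gene model are mutually inconsistent."""


@dataclass(frozen=True)
class ContextLabel:
    context: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass
class GeneModel:
    """A stranded single-transcript gene with exon/CDS/UTR structure.

    Intervals are 1-based inclusive, stored sorted by genomic start and
    non-overlapping within each feature list. Total CDS length must be a
    multiple of 3 (one transcript per gene; no isoforms).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            setattr(self, name, ivs)
            for (a0, a1), (b0, _) in zip(ivs, ivs[1:]):
                if b0 <= a1:
                    raise ValueError(f"{name} intervals overlap in {self.gene_id}")
            for a0, a1 in ivs:
                if a0 < self.start or a1 > self.end:
                    raise ValueError(f"{name} interval outside gene span in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def cds_transcription_order(self) -> list[Interval]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def _feature_at(self, pos: int) -> str | None:
        for name in ("cds", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if s <= pos <= e:
                    return name if name != "cds" else "cds"
        if self.contains(pos):
            for s, e in self.exons:
                if s <= pos <= e:
                    # exon base not covered by CDS/UTR lists (should not occur
                    # for well-formed models); treat as exonic UTR-like → intron
                    # is wrong, fall back to the nearest coding-side label
                    return "utr5"
            return "intron"
        return None

    # ---- coding-coordinate arithmetic -------------------------------------

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the coding sequence."""
        if self.strand == "+":
            off = 0
            for s, e in self.cds:
                if s <= pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        else:
            off = 0
            for s, e in reversed(self.cds):
                if s <= pos <= e:
                    return off + (e - pos)
                off += e - s + 1
        raise AnnotationError(
            f"position {self.chrom}:{pos} not in CDS of {self.gene_id}"
        )

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------


def _candidate(gene: GeneModel, pos: int, window: int) -> ContextLabel | None:
    feat = gene._feature_at(pos)
    if feat is not None:
        return ContextLabel(feat, gene.gene_id)
    # outside the gene body: strand-aware flanks
    if gene.strand == "+":
        five_prime = pos < gene.start
        dist = gene.start - pos if five_prime else pos - gene.end
    else:
        five_prime = pos > gene.end
        dist = pos - gene.end if five_prime else gene.start - pos
    if 0 < dist <= window:
        return ContextLabel("upstream" if five_prime else "downstream", gene.gene_id)
    return None


def assign_context(
    variant,
    genes: Iterable[GeneModel] | Mapping[str, Sequence[GeneModel]],
    window: int = 5000,
) -> ContextLabel:
    """Assign the single most relevant genomic context to a variant.

    ``variant`` needs ``chrom`` and ``pos`` attributes. When several contexts
    apply the highest-precedence one wins (e.g. upstream of gene B beats
    downstream of gene A, mirroring the "most relevant context" doctrine);
    ties are broken by smaller gene span, then lexicographic gene id.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if isinstance(genes, Mapping):
        by_chrom = genes
    else:
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
    if variant.chrom not in by_chrom:
        warnings.warn(
            f"chromosome {variant.chrom!r} absent from annotation; labelling intergenic",
            stacklevel=2,
        )
        return ContextLabel("intergenic")
    best: tuple[int, int, str] | None = None
    best_label: ContextLabel | None = None
    for gene in by_chrom[variant.chrom]:
        cand = _candidate(gene, variant.pos, window)
        if cand is None:
            continue
        key = (_RANK[cand.context], gene.span, gene.gene_id)
        if best is None or key < best:
            best, best_label = key, cand
    return best_label if best_label is not None else ContextLabel("intergenic")


# ---------------------------------------------------------------------------
# protein impact
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _translate(cds: str) -> str:
    # keep '*' characters so stop gain/loss is visible in the diff
    return str(Seq(cds).translate())


def classify_snp_effect(variant, gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Impact class of a coding SNP, from the rebuilt codon on the coding strand."""
    ref, alt = variant.ref, variant.alts[0]
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("classify_snp_effect expects a single-base substitution")
    if not gene.in_cds(variant.pos):
        raise AnnotationError(
            f"SNP {variant.chrom}:{variant.pos} outside CDS of {gene.gene_id}"
        )
    coding = gene.coding_sequence(genome)
    off = gene.cds_offset(variant.pos)
    base_ref, base_alt = ref.upper(), alt.upper()
    if gene.strand == "-":
        base_ref = base_ref.translate(_COMPLEMENT)
        base_alt = base_alt.translate(_COMPLEMENT)
    if coding[off] != base_ref:
        raise AnnotationError(
            f"reference mismatch at {variant.chrom}:{variant.pos} in {gene.gene_id}: "
            f"CDS has {coding[off]}, variant ref implies {base_ref}"
        )
    ci = off // 3
    old_codon = coding[3 * ci : 3 * ci + 3]
    new_codon = old_codon[: off % 3] + base_alt + old_codon[off % 3 + 1 :]
    old_aa = _translate(old_codon)
    new_aa = _translate(new_codon)
    if ci == 0 and new_codon != "ATG":
        return "start_lost"
    if old_aa == "*" and new_aa != "*":
        return "stop_lost"
    if new_aa == "*" and old_aa != "*":
        return "stop_gained"
    return "synonymous" if old_aa == new_aa else "non_synonymous"


def left_normalize(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """VCF-style parsimonious left alignment of an allele pair.

    Trims shared suffix bases, then shared prefix bases (keeping at least one
    base in each allele), returning the adjusted 1-based position.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel_effect(variant, gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Impact class of a coding InDel.

    Frameshift when the net length change is not a multiple of 3. In-frame
    events are classified by diffing the translated coding sequence before and
    after the edit: a pure gain/loss of whole codons is ``codon_insertion`` /
    ``codon_deletion``; anything that additionally changes a flanking codon is
    the corresponding ``codon_change_plus_*`` class.
    """
    pos, ref, alt = left_normalize(variant.pos, variant.ref, variant.alts[0])
    net = len(alt) - len(ref)
    if net == 0:
        raise ValueError("not an indel after normalization")
    if net % 3 != 0:
        return "frameshift"

    coding = gene.coding_sequence(genome)
    if len(ref) > len(alt):  # deletion of ref[1:]
        del_lo, del_hi = pos + 1, pos + len(ref) - len(alt)  # genomic, inclusive
        offs = []
        for p in range(del_lo, del_hi + 1):
            if not gene.in_cds(p):
                raise AnnotationError(
                    f"deleted base {variant.chrom}:{p} outside CDS of {gene.gene_id}"
                )
            offs.append(gene.cds_offset(p))
        lo, hi = min(offs), max(offs) + 1
        mutated = coding[:lo] + coding[hi:]
    else:  # insertion of alt[1:] after the anchor base
        ins = alt[1:]
        if gene.strand == "+":
            if not gene.in_cds(pos):
                raise AnnotationError(
                    f"insertion anchor {variant.chrom}:{pos} outside CDS of {gene.gene_id}"
                )
            point = gene.cds_offset(pos) + 1
            ins_coding = ins
        else:
            if not gene.in_cds(pos):
                raise AnnotationError(
                    f"insertion anchor {variant.chrom}:{pos} outside CDS of {gene.gene_id}"
                )
            point = gene.cds_offset(pos)
            ins_coding = ins.translate(_COMPLEMENT)[::-1]
        mutated = coding[:point] + ins_coding + coding[point:]

    prot_old = _translate(coding)
    prot_new = _translate(mutated)
    k = abs(net) // 3
    if len(prot_new) < len(prot_old):
        short, long_ = prot_new, prot_old
        pure, mixed = "codon_deletion", "codon_change_plus_deletion"
    else:
        short, long_ = prot_old, prot_new
        pure, mixed = "codon_insertion", "codon_change_plus_insertion"
    assert len(long_) - len(short) == k
    p = _common_prefix(short, long_)
    s = _common_prefix(short[::-1], long_[::-1])
    return pure if p + s >= len(short) else mixed


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

_UTR_TYPES = {"five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            row = f"{g.chrom}\tviteseq\t%s\t%d\t%d\t.\t{g.strand}\t%s\t%s\n"
            fh.write(row % ("gene", g.start, g.end, ".", f"ID={gid}"))
            fh.write(row % ("mRNA", g.start, g.end, ".", f"ID={mid};Parent={gid}"))
            for s, e in g.exons:
                fh.write(row % ("exon", s, e, ".", f"Parent={mid}"))
            phase = 0
            for s, e in g.cds_transcription_order():
                fh.write(row % ("CDS", s, e, str(phase), f"Parent={mid}"))
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for s, e in g.utr5:
                fh.write(row % ("five_prime_UTR", s, e, ".", f"Parent={mid}"))
            for s, e in g.utr3:
                fh.write(row % ("three_prime_UTR", s, e, ".", f"Parent={mid}"))


def load_gff3(path: str) -> list[GeneModel]:
    """Read single-transcript gene models from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for grec in db.features_of_type("gene"):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(grec.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype in _UTR_TYPES:
                (utr5 if _UTR_TYPES[child.featuretype] == "utr5" else utr3).append(iv)
        genes.append(
            GeneModel(
                gene_id=grec.id,
                chrom=grec.seqid,
                strand=grec.strand,
                start=grec.start,
                end=grec.end,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes
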