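"""Genomic-context assignment and protein-impact classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from Bio.Seq import Seq

from oracles import indel_impact_oracle, snp_impact_oracle
from viteseq.annotation import (
    AnnotationError,
    GeneModel,
    assign_context,
    classify_indel_effect,
    classify_snp_effect,
    left_normalize,
)


@dataclass
class V:
    chrom: str
    pos: int
    ref: str = "A"
    alts: tuple = ("G",)


# ---------------------------------------------------------------------------
# a hand-built toy chromosome with three genes of known sequence
# ---------------------------------------------------------------------------

CDS_A = "ATGGAATATCCCAAGGGTTGGTAA"  # M E Y P K G W *
CDS_B = "ATGCATGAAGGTCCCTTTTGGTAG"  # M H E G P F W *


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(99)
    seq = list("".join(rng.choice(list("ACGT"), size=45_000)))

    def put(pos: int, s: str) -> None:
        seq[pos - 1 : pos - 1 + len(s)] = list(s)

    # gene A: + strand, single exon, 10 bp UTRs around a 24 bp CDS
    utr = "ACGTACGTAC"
    put(15_001, utr + CDS_A + utr)
    gene_a = GeneModel(
        "geneA", "c", "+", 15_001, 15_044,
        exons=[(15_001, 15_044)], cds=[(15_011, 15_034)],
        utr5=[(15_001, 15_010)], utr3=[(15_035, 15_044)],
    )
    # gene C: + strand, 7 kb after gene A
    put(22_045, utr + CDS_A + utr)
    gene_c = GeneModel(
        "geneC", "c", "+", 22_045, 22_088,
        exons=[(22_045, 22_088)], cds=[(22_055, 22_078)],
        utr5=[(22_045, 22_054)], utr3=[(22_079, 22_088)],
    )
    # gene B: − strand; genomic segment is the reverse complement of
    # utr5 + CDS + utr3, so the genomic-top end is the transcript 5' side
    transcript = utr + CDS_B + utr
    put(30_001, str(Seq(transcript).reverse_complement()))
    gene_b = GeneModel(
        "geneB", "c", "-", 30_001, 30_044,
        exons=[(30_001, 30_044)], cds=[(30_011, 30_034)],
        utr5=[(30_035, 30_044)], utr3=[(30_001, 30_010)],
    )
    genome = {"c": "".join(seq)}
    return genome, {"geneA": gene_a, "geneB": gene_b, "geneC": gene_c}


class TestContext:
    @pytest.mark.parametrize(
        "pos,expected,gene",
        [
            (13_001, "upstream", "geneA"),     # 2 kb 5' of a + strand gene
            (15_016, "cds", "geneA"),
            (15_005, "utr5", "geneA"),
            (15_040, "utr3", "geneA"),
            (15_144, "downstream", "geneA"),   # 100 bp past the 3' end
            (18_044, "upstream", "geneC"),     # 3 kb down of A but 4 kb up of C
            (30_100, "upstream", "geneB"),     # − strand: upstream is right of end
            (29_950, "downstream", "geneB"),
            (44_000, "intergenic", None),      # > 10 kb from every gene
        ],
    )
    def test_labels(self, toy, pos, expected, gene):
        _, genes = toy
        label = assign_context(V("c", pos), genes.values())
        assert label.context == expected
        assert label.gene_id == gene

    def test_unknown_chromosome_warns_intergenic(self, toy):
        _, genes = toy
        with pytest.warns(UserWarning):
            label = assign_context(V("chrZ", 100), genes.values())
        assert label.context == "intergenic"

    def test_window_zero_disables_flanks(self, toy):
        _, genes = toy
        assert assign_context(V("c", 13_001), genes.values(), window=0).context == "intergenic"

    def test_partition_every_variant_gets_one_label(self, cohort):
        recs = cohort.variants["WF"][:2000]
        by_chrom: dict[str, list] = {c: [] for c in cohort.genome}
        for g in cohort.genes:
            by_chrom[g.chrom].append(g)
        labels = [assign_context(r, by_chrom) for r in recs]
        assert len(labels) == len(recs)
        from collections import Counter

        counts = Counter(l.context for l in labels)
        assert sum(counts.values()) == len(recs)


class TestSnpImpact:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (15_016, "A", "G", "synonymous"),    # GAA -> GAG (Glu)
            (15_019, "T", "A", "stop_gained"),   # TAT -> TAA
            (15_015, "A", "T", "non_synonymous"),  # GAA -> GTA
            (15_012, "T", "C", "start_lost"),    # ATG -> ACG
            (15_033, "A", "C", "stop_lost"),     # TAA -> TCA? no: pos 33 is mid-stop
        ],
    )
    def test_plus_strand_examples(self, toy, pos, ref, alt, expected):
        genome, genes = toy
        v = V("c", pos, ref, (alt,))
        assert classify_snp_effect(v, genes["geneA"], genome) == expected

    def test_minus_strand_synonymous(self, toy):
        # coding CAT -> CAC (His): genomic base at offset 5 from the top end
        genome, genes = toy
        v = V("c", 30_029, "A", ("G",))
        assert classify_snp_effect(v, genes["geneB"], genome) == "synonymous"

    def test_reference_mismatch_raises(self, toy):
        genome, genes = toy
        actual = genome["c"][15_015]
        wrong = "A" if actual != "A" else "C"
        with pytest.raises(AnnotationError):
            classify_snp_effect(V("c", 15_016, wrong, ("G",)), genes["geneA"], genome)

    def test_outside_cds_raises(self, toy):
        genome, genes = toy
        with pytest.raises(AnnotationError):
            classify_snp_effect(V("c", 15_005), genes["geneA"], genome)

    def test_oracle_equivalence_500_random_snps(self, genome_genes):
        """Codon-local classification equals full-protein re-translation."""
        genome, genes = genome_genes
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 500:
            gene = genes[int(rng.integers(0, len(genes)))]
            s, e = gene.cds[int(rng.integers(0, len(gene.cds)))]
            pos = int(rng.integers(s, e + 1))
            ref = genome[gene.chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v = V(gene.chrom, pos, ref, (alt,))
            assert classify_snp_effect(v, gene, genome) == snp_impact_oracle(
                gene, genome, pos, ref, alt
            )
            checked += 1

    def test_strand_symmetry(self, genome_genes):
        """Reverse-complementing the genome and flipping strands leaves
        impact labels unchanged."""
        genome, genes = genome_genes
        rng = np.random.default_rng(13)
        for gene in genes[:4]:
            L = len(genome[gene.chrom])
            flipped_seq = str(Seq(genome[gene.chrom]).reverse_complement())
            mirror = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
            flipped = GeneModel(
                gene.gene_id, gene.chrom, "-" if gene.strand == "+" else "+",
                L - gene.end + 1, L - gene.start + 1,
                exons=[mirror(iv) for iv in gene.exons],
                cds=[mirror(iv) for iv in gene.cds],
                utr5=[mirror(iv) for iv in gene.utr5],
                utr3=[mirror(iv) for iv in gene.utr3],
            )
            fgenome = {gene.chrom: flipped_seq}
            comp = str.maketrans("ACGT", "TGCA")
            for _ in range(25):
                s, e = gene.cds[int(rng.integers(0, len(gene.cds)))]
                pos = int(rng.integers(s, e + 1))
                ref = genome[gene.chrom][pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                direct = classify_snp_effect(V(gene.chrom, pos, ref, (alt,)), gene, genome)
                mpos = L - pos + 1
                mv = V(gene.chrom, mpos, ref.translate(comp), (alt.translate(comp),))
                assert classify_snp_effect(mv, flipped, fgenome) == direct


class TestIndelImpact:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (15_019, "TC", "T", "frameshift"),        # 1 bp deletion
            (15_019, "TCCC", "T", "codon_deletion"),  # removes the CCC codon
            (15_020, "CCCA", "C", "codon_change_plus_deletion"),  # spans 2 codons
            (15_019, "T", "TAAA", "codon_insertion"),  # at a codon boundary
            (15_020, "C", "CTTT", "codon_change_plus_insertion"),
            (15_012, "TGGAATATC", "T", "frameshift"),  # 8 bp CDS deletion
        ],
    )
    def test_examples(self, toy, pos, ref, alt, expected):
        genome, genes = toy
        assert classify_indel_effect(V("c", pos, ref, (alt,)), genes["geneA"], genome) == expected

    def test_eight_bp_deletion_truncates_protein(self, toy):
        """The frameshifted translation ends prematurely relative to the
        original protein (premature stop)."""
        genome, genes = toy
        gene = genes["geneA"]
        mutated = dict(genome)
        s = mutated["c"]
        mutated["c"] = s[:15_012] + s[15_020:]  # drop 8 CDS bases
        cds = gene.coding_sequence(genome)
        broken = gene.coding_sequence(mutated)[: len(cds) - 8]
        frame = broken[: 3 * (len(broken) // 3)]
        prot = str(Seq(frame).translate())
        assert "*" in prot[:-1] or len(prot) < len(cds) // 3

    def test_oracle_equivalence_random_indels(self, genome_genes):
        genome, genes = genome_genes
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 150:
            gene = genes[int(rng.integers(0, len(genes)))]
            s, e = gene.cds[int(rng.integers(0, len(gene.cds)))]
            if e - s < 14:
                continue
            pos = int(rng.integers(s, e - 11))
            if rng.random() < 0.5:
                dlen = int(rng.integers(1, 10))
                ref = genome[gene.chrom][pos - 1 : pos + dlen]
                alt = ref[0]
            else:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 10))))
                ref = genome[gene.chrom][pos - 1]
                alt = ref + ins
            v = V(gene.chrom, pos, ref, (alt,))
            assert classify_indel_effect(v, gene, genome) == indel_impact_oracle(
                gene, genome, pos, ref, alt
            )
            checked += 1


def test_left_normalize():
    assert left_normalize(10, "ATT", "A") == (10, "ATT", "A")
    assert left_normalize(10, "CAT", "CT") == (10, "CA", "C")  # shared suffix T
    assert left_normalize(10, "GCC", "GC") == (10, "GC", "G")  # trims trailing C
    assert left_normalize(10, "TACA", "TAA") == (11, "AC", "A")  # suffix then prefix
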