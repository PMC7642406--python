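# viteseq

Downstream analysis of diploid re-sequencing studies at small-genome scale:
the kind of comparison made when two wild grapevine individuals (one male,
one female) are re-sequenced against a domesticated reference genome and
their transcriptomes are screened for RNA editing in the sex-determining
region. The package provides tested, reusable implementations of every
post-alignment step of such a study, together with a synthetic-cohort
generator that plants known truth so the whole pipeline can be validated
end to end.

## What it computes

**Variant hard filtration** — the classic GATK-style recipe over INFO
metrics, per record: fail when DP ≤ 20, QD < 2.0, MQRankSum < −12.5,
FS > 60.0 (SNPs) / 200.0 (InDels), HaplotypeScore > 13.0, or
ReadPosRankSum < −8.0 (SNPs) / −20.0 (InDels). Records keep the full set of
named filters they failed; multi-allelic records stay intact because the
1/2 genotype class (both alleles non-reference) is first-class here.

**Effect annotation** — each variant gets exactly one genomic context by
precedence (`cds > utr5/utr3 > intron > upstream > downstream > intergenic`,
5 kbp strand-aware flanking windows), and coding variants get a protein
impact by rebuilding the codon (SNPs) or the coding sequence (InDels) on the
coding strand: synonymous / non-synonymous / stop gained / stop lost /
start lost, and frameshift / codon insertion / codon deletion /
codon change + insertion / codon change + deletion.

**Landscape statistics** — transition/transversion ratio Ti/Tv = #(A↔G, C↔T)
/ #(A↔C, A↔T, C↔G, G↔T) overall or per context group (the uniform-
substitution null is 0.5, two transition types against four transversion
types); per-chromosome event frequencies (count / chromosome bp) with
Tukey outlier fences Q1 − k·IQR, Q3 + k·IQR at k = 1.5; shared/exclusive
variant sets between two individuals (Venn counts); zygosity tallies with
het/hom ratio where het = #(0/1) + #(1/2) and hom = #(1/1); percentage of
each context's bp affected; and binned densities for heatmaps. Virtual
chromosomes ("Un", "*_random" unplaced-sequence bins) are excluded from
per-chromosome statistics.

**Sequencing and assembly metrics** — mapping-category percentages of total
mapped reads, read-retention percentages, expected fold coverage
ceil(n_reads × read_length / genome_size), and assembly metrics after a
≥ 1 kb contig filter: N50 (shortest contig among the largest contigs jointly
covering ≥ 50% of assembly length) and %GC over total length.

**RNA editing detection** — sites where a transcriptome nucleotide is not
supported by the individual's genomic allele profile. Gates: ≥ 5× coverage
in DNA-seq and RNA-seq simultaneously, gene expressed at RPKM ≥ 1 in all
six samples (2 individuals × developmental stages B, D, H), no indel
evidence; alleles retained at ≥ 10% read support; a locus is homozygous at
top-allele frequency ≥ 0.90. A call is *two_variant* when edited and
unedited transcripts co-occur, *full_edit* when only the edited form is
seen; RPKM = 10⁹ × gene reads / (exon-model bp × total mapped reads).
Calls are placed in genomic context and, inside CDS, classified
synonymous/non-synonymous; summaries report per-gene edited loci and counts
inside/outside a configurable window (default: the chromosome-2
sex-determining region, chr2:4,907,434–5,050,616).

**Synthetic cohort** — a multi-chromosome genome with single-transcript gene
models (CDS always starts ATG, ends on a stop, length divisible by 3), two
individuals with configurable SNP/InDel rates, target Ti/Tv, heterozygosity
mix (0/1 : 1/1 : 1/2 = 60 : 35 : 5 by default) and shared fraction, matched
DNA/RNA pileups with planted editing events, per-gene counts and contig
sets — all byte-deterministic in the seed, with a JSON truth ledger.

## Worked example

```
viteseq simulate --seed 7 --out demo
viteseq editing --dna-pileups demo/dna_pileups.tsv --rna-pileups demo/rna_pileups.tsv \
    --gene-counts demo/gene_counts.tsv --site-genes demo/site_genes.tsv \
    --gff demo/genes.gff3 --fasta demo/reference.fa --out demo/ed
```

prints `17 editing calls written to demo/ed` — every one of the 17 planted
events in `demo/truth.json`, and nothing else. The two-variant calls in
`demo/ed/editing_calls.tsv` include:

```
chrom  pos    sample  gene_id  mode         from  to  rna_fraction  dna_zygosity  context  impact
chr1   6746   WF_D    gene001  two_variant  C     T   0.561         homozygous    cds      synonymous
chr1   34368  WF_B    gene007  two_variant  C     G   0.444         homozygous    cds      non_synonymous
chr1   34368  WF_D    gene007  two_variant  C     G   0.484         homozygous    cds      non_synonymous
```

i.e. in gene007 the genome is homozygous C but about 44–48% of WF
transcripts at stages B and D carry a G — the signature of a partially
edited ("mRNA two-variants") site, here with a non-synonymous effect on the
protein. `demo/ed/region_report.json` then counts calls inside versus
outside the configured window and breaks down contexts (here 9 in 5′ UTR,
8 in CDS) and impacts (7 non-synonymous, 1 synonymous).

The same library surface is importable directly (`viteseq.landscape`,
`viteseq.editing`, ...) — for instance
`landscape.titv_ratio(snps)` on the simulated female individual returns
≈ 1.9–2.1 against the planted target of 2.0.

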