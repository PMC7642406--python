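# Methods

## Scope and model

viteseq implements the post-alignment, post-calling stages of a
two-individual diploid re-sequencing comparison: hard filtration of called
variants, gene-context and protein-impact annotation, genome-landscape
summaries, sequencing/assembly metrics, and DNA-vs-RNA editing detection.
Read mapping, duplicate marking, realignment/recalibration, the variant
calling itself and de novo assembly are treated as upstream producers whose
outputs (VCF, pileup tables, category counts, contig FASTA) are this
package's inputs.

## Hard filters

Filters are named, independent predicates on INFO metrics; a record's
FILTER status is the set of predicates it fails, so filtration is idempotent
and order-free. Defaults (fail conditions): DP ≤ 20; QD < 2.0;
MQRankSum < −12.5; FS > 60.0 for SNPs and > 200.0 for InDels;
HaplotypeScore > 13.0; ReadPosRankSum < −8.0 for SNPs and −20.0 for InDels.
Two interpretive choices are worth stating. The low-coverage bound is read
literally as "fail when DP ≤ 20" and left configurable, since 5× minima are
also common in this kind of analysis. The mapping-quality filter is treated
as a rank-sum-style metric (negative values meaningful) read from a
configurable INFO key, default `MQRankSum`; only one such filter is applied.
A missing metric leaves its filter recorded as not-evaluated rather than
silently passed; strict mode raises instead.

## Coordinates and gene models

VCF and GFF3 interfaces are 1-based inclusive; internal interval arithmetic
is 0-based half-open. Gene models are single-transcript (one mRNA per gene):
sorted non-overlapping exon/CDS/UTR intervals inside the gene span, total
CDS length divisible by 3. Only the standard nuclear genetic code is
supported.

## Context and impact

Context assignment gives every variant exactly one label under the
precedence `cds > utr5/utr3 > intron > upstream > downstream > intergenic`.
Upstream/downstream are strand-aware 5 kbp windows by default (upstream =
the 5′ side of the gene on its own strand); when a position is, e.g., 3 kbp
downstream of one gene and 4 kbp upstream of the next, the
higher-precedence label wins (upstream), matching snpEff's "most relevant
context" doctrine. Ties between genes offering the same context class are
broken by smaller gene span, then lexicographic gene id. A variant on a
chromosome absent from the annotation is labelled intergenic with a
warning.

SNP impacts rebuild the affected codon on the coding strand
(reverse-complementing for − strand genes) and translate: synonymous,
non_synonymous, stop_gained, stop_lost, or start_lost (any change of the
initial ATG). InDels are left-normalized (VCF parsimony) first; a net
length change not divisible by 3 is a frameshift. In-frame events are
classified *sequence-aware*: the coding sequence is rebuilt in transcript
space with the edit applied and both translations are diffed by common
prefix/suffix — a pure gain or loss of whole codons is codon_insertion /
codon_deletion, anything that additionally changes a flanking codon is
codon_change_plus_insertion / codon_change_plus_deletion. Pure
codon-boundary arithmetic would mislabel in-frame deletions that are not
codon-aligned yet still remove exactly one codon's worth of protein
(e.g. deleting 3 bp starting mid-codon inside a homopolymer run), which is
why the translation diff is the implementation, not just the test oracle.
The test oracle takes an independent route: it edits the whole chromosome
string, shifts every annotation interval past the edit, re-extracts and
re-translates the complete protein.

## Landscape statistics

Ti/Tv counts every ALT allele of a record once (the 1/2 class contributes
two observed nucleotides); a group with zero transversions reports an
undefined sentinel (`None`), never a silent infinity. Per-chromosome
frequencies are event counts divided by chromosome length; unplaced-sequence
bins matching the configurable patterns `Un` / `*_random` are excluded.
Tukey fences use linear-interpolation quartiles (R's default type 7, the
convention of the R-based analysis this mirrors); the convention is
pluggable via numpy's `method` argument, and flags mark values strictly
outside the fences. Zygosity ratios count 0/1 + 1/2 as heterozygous and 1/1
as non-reference homozygous; 0/0 records are excluded. Context-percentage
denominators are computed by partitioning every genomic base under the same
precedence order as variant labelling, so the sizes sum exactly to the
genome length; published analyses of this kind do not state their
denominators, so these percentages are comparable qualitatively, not as
printed values.

## Sequencing and assembly metrics

Mapping categories are taken as input counts (flagstat-like), with
percentages over total mapped reads at two decimals; retention percentages
at one decimal. Expected coverage uses the ceiling convention
`ceil(n_reads × read_length / genome_size)`: with 125 bp reads over a
486 Mbp genome this is the unique convention that reproduces all four
printed coverages of the motivating study (56×/72× from quality-filtered
read counts, 58×/74× from assembly-input read counts), so it is adopted as
the package default. Contigs under 1 kb are dropped before assembly
metrics; N50 is the length at which the descending cumulative sum first
reaches half the total; %GC keeps ambiguous bases in the denominator.

## RNA-editing caller

Two filter layers precede the allele comparison. The transcriptome-side
prefilter discards RNA variant calls near sequence ends (< 60 bases),
with ambiguous reference context (at or within 60 bases), flanking copy
number > 2, allele quality < 20, allele support < 2 reads, variant
frequency < 15%, or coverage < 4 — thresholds configurable with these
defaults; the first failing rule is reported. The flanking copy number has
no standard computation and is accepted as supplied metadata. Site-level
gates then require ≥ 5× DNA and RNA coverage simultaneously, RPKM ≥ 1 in
all six samples, and no indel evidence.

Allele profiles retain bases at ≥ 10% of covering reads (boundary
inclusive; frequencies over base counts plus deletions) and call a locus
homozygous when the top allele is at ≥ 0.90 (boundary inclusive). "Not
supported by the genomic information" is operationalized as: the RNA base
is absent from the DNA profile after the 10% support filter. This knowingly
admits the edge case where the edited base rides at just under 10% of
genome reads; a stricter optional mode (`require_zero_dna_reads`) demands
zero DNA reads of the edited base. The RNA side reuses the same 10% support
filter. Editing is called per RNA sample; modes are two_variant (genomic
base still present in RNA) and full_edit (only the edited base remains).
Edits are reported in the DNA alphabet (T-to-A, not U-to-A). Region
summaries default to the chromosome-2 sex-determining-region window
(chr2:4,907,434–5,050,616) but accept any window.

## Synthetic cohort generator

The generator emulates the study design at desk scale: two individuals
(WF, WM), three developmental stages (B, D, H) of RNA per individual, a
reference with real chromosomes plus one virtual bin (`chrUn`). Default
dimensions — 3 chromosomes of 120/120/80 kb plus a 20 kb virtual bin, 12
genes — keep a full cohort under ten seconds while leaving every statistic
estimable; rates are scaled from the study's genome-wide figures: SNPs at
0.012/bp and InDels at 0.0024/bp per individual (≈ 6.4 M and 1.16 M over
486 Mbp), shared fraction 0.5 of the union ("shared half of the
occurrences"), target Ti/Tv 2.0 (the observed 1.4–2.2 context range),
genotype mix 0/1 : 1/1 : 1/2 = 60 : 35 : 5 (heterozygous fraction 0.65).

Placement is uniform over the genome with SNP and InDel positions disjoint.
Alleles and genotype class are drawn once per union site and reused by both
carriers, so a shared variant is byte-identical in both VCFs and the
realized shared/union fraction is binomially distributed around the target;
zygosity may in reality differ between carriers of a shared variant, a
simplification accepted for exact sharing semantics. A 1/2 site carries the
transition partner plus one transversion; because that pins its allele-level
Ti fraction at 1/2, the Ti probability of single-alt draws is analytically
adjusted (p = (T(1+r) − r)/(1 − r), with T the target Ti fraction and r the
1/2 record share) so the cohort-level Ti/Tv is unbiased — verified
empirically to within sampling error over seeds.

Genes are laid out with ≥ 12 kb spacing so 5 kb context windows never
overlap; CDS sequences start ATG, end on a stop, contain no internal stop,
and may be split across exons at arbitrary (not codon-aligned) boundaries.
Editing events are placed only at exonic transcript offsets that carry no
planted DNA variant (auto-placed events re-draw on collision; explicit
collisions raise). RNA depth is Gamma-Poisson (shape 8, mean 80, floor 30);
edited-read counts are binomial at the planted fraction, with two-variant
fractions defaulting to 0.3–0.6 so a planted edit essentially never falls
below the 10% support threshold at these depths. DNA pileups contain only
the genomic allele. Expression counts are chosen so expressed genes sit
between the RPKM floor (5) and ceiling (60) against a nominal library of
10⁶ mapped reads; one gene is left unexpressed (0 reads) to exercise the
expression gate. Contig sets are random sequence at 34% GC.

What the generator does **not** model: read-level errors (pileups are
exact multinomial draws, no sequencing-error leakage), linkage or
recombination structure, somatic mosaicism, overlapping genes or isoforms,
strand bias, and mapping artefacts. Passing recovery tests therefore show
the *logic* of the pipeline is correct under its stated assumptions, not
that the thresholds are well-calibrated for noisy real data.

## Problem sizes and numerics

The test suite and the acceptance script run cohorts of roughly 10,000
variants per individual for parameter recovery (3-standard-error checks on
Ti/Tv, heterozygous fraction and shared fraction), 500 random coding SNPs
and 150 coding InDels for oracle equivalence, and ≥ 200 pileup sites
(48 planted events, 160 control sites) for editing recovery, where clean
simulation yields sensitivity 1.0 and false-positive rate 0 exactly. These
sizes were chosen as the smallest at which the binomial error bars are
meaningfully tight. Ratios with empty denominators (Ti/Tv without
transversions, het/hom without homozygous records) return `None` rather
than infinity; quartile ties and constant vectors give zero-width fences
and no outliers; rounding for reported percentages follows the conventions
above (2 d.p. mapping, 1 d.p. retention, integer GC).

## Known limitations

Single-transcript gene models only (no isoform-aware annotation, no
splice-site impact classes); the editing caller assumes pileups are already
produced by a competent aligner and does not inspect alignments; the
prefilter's copy-number rule is metadata-driven; BAM parsing is out of
scope (category counts are inputs). The published genome-wide variant
counts of the motivating study depend on its raw sequencing data and are
not reproduced at desk scale; the package reproduces the study's
arithmetic, conventions and detection logic, and validates them on planted
truth instead.
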