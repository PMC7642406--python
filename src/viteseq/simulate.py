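"""Synthetic diploid re-sequencing cohort with planted truth.

Emulates, at desk scale, the data a two-individual wild-grapevine
re-sequencing study feeds into its downstream analysis: a small
multi-chromosome reference genome with single-transcript gene models (plus an
optional "virtual" unplaced-sequence chromosome), two unrelated diploid
individuals whose variant sets have controlled transition/transversion ratio,
heterozygosity structure and sharing, matched DNA/RNA allele pileups with
planted editing events (partial "two-variant" edits and full edits) for two
individuals × three developmental stages, per-gene RNA-seq read counts, and a
contig set for assembly metrics.

Everything is driven by one :class:`SimulationConfig`; identical configs
(including the seed) give byte-identical outputs. A :class:`PlantedTruth`
ledger records every planted variant and editing event so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .editing import SitePileup
from .variants import VariantRecord, variant_kind

__all__ = [
    "SimulationConfig",
    "GeneStructure",
    "EditingSiteSpec",
    "PlantedTruth",
    "PlacementError",
    "EditingPlacementError",
    "generate_genome",
    "generate_individuals",
    "generate_rna_pileups",
    "generate_contigs",
    "simulate_cohort",
    "SyntheticCohort",
    "transcript_to_genomic",
    "write_fasta",
    "write_pileups",
    "write_gene_counts",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


class PlacementError(ValueError):
    """Genes cannot be placed under the configured genome geometry."""


class EditingPlacementError(ValueError):
    """An editing event falls outside the exonic transcript."""


@dataclass(frozen=True)
class GeneStructure:
    """Ranges (inclusive) gene features are drawn from, in bp or counts."""

    n_exons: tuple[int, int] = (1, 4)
    n_codons: tuple[int, int] = (60, 180)  # incl. start and stop codons
    intron_len: tuple[int, int] = (100, 400)
    utr5_len: tuple[int, int] = (40, 150)
    utr3_len: tuple[int, int] = (60, 250)

    @property
    def max_span(self) -> int:
        return (
            self.utr5_len[1]
            + self.utr3_len[1]
            + 3 * self.n_codons[1]
            + (self.n_exons[1] - 1) * self.intron_len[1]
        )


@dataclass(frozen=True)
class EditingSiteSpec:
    """One planted editing event: a gene, an offset into its spliced
    transcript, the edited-to base (transcript alphabet, DNA letters) and the
    edited fraction per RNA sample (samples absent from the map are
    unedited). ``from_base`` may be supplied as a cross-check against the
    reference; fraction 1.0 is a full edit, anything lower a two-variant
    event."""

    gene_id: str
    transcript_offset: int
    to_base: str
    fractions: Mapping[str, float]
    from_base: str | None = None

    @property
    def mode(self) -> str:
        return "full_edit" if all(f >= 1.0 for f in self.fractions.values()) else "two_variant"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (120_000, 120_000, 80_000)
    virtual_chrom_length: int = 20_000  # 0 disables the "chrUn" bin
    n_genes: int = 12
    gene_structure: GeneStructure = field(default_factory=GeneStructure)
    min_gene_spacing: int = 12_000
    snp_rate: float = 0.012  # events per bp per individual
    indel_rate: float = 0.0024
    max_indel_len: int = 6
    target_titv: float = 2.0
    het_fraction: float = 0.65  # genotype mix 0/1:1/1:1/2 = 60:35:5 at default
    het_alt_alt_share: float = 1 / 13  # 1/2 share within het (5 of 65)
    shared_fraction: float = 0.5  # of the union, planted in both individuals
    low_quality_fraction: float = 0.0  # records planted to fail a hard filter
    individuals: tuple[str, ...] = ("WF", "WM")
    stages: tuple[str, ...] = ("B", "D", "H")
    editing_sites: tuple[EditingSiteSpec, ...] | None = None  # None → auto
    n_auto_editing_events: int = 8
    edit_fraction_range: tuple[float, float] = (0.3, 0.6)
    n_control_sites: int = 60
    rna_depth_mean: float = 80.0
    rna_depth_shape: float = 8.0  # Gamma-Poisson dispersion
    rna_depth_min: int = 30
    dna_depth_mean: float = 40.0
    rpkm_floor: float = 5.0
    rpkm_ceiling: float = 60.0
    n_unexpressed_genes: int = 1
    library_size: int = 1_000_000  # total mapped reads per RNA sample

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(f"{i}_{s}" for i in self.individuals for s in self.stages)

    def validate(self) -> None:
        for name in ("snp_rate", "indel_rate", "het_fraction", "shared_fraction",
                     "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.target_titv < 0:
            raise ValueError("target_titv must be non-negative")
        if min(self.chromosome_lengths, default=0) < 10 * self.gene_structure.max_span:
            raise ValueError(
                "every chromosome must be at least 10x the longest possible gene "
                f"({10 * self.gene_structure.max_span} bp)"
            )
        if self.editing_sites:
            for spec in self.editing_sites:
                for f in spec.fractions.values():
                    if not 0.0 < f <= 1.0:
                        raise ValueError("edit fractions must be in (0, 1]")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class PlantedTruth:
    """Ledger of planted variants and editing events for recovery scoring."""

    variants: list[dict] = field(default_factory=list)
    editing_events: list[dict] = field(default_factory=list)

    def variant_keys(self, individual: str) -> set[tuple]:
        return {
            (v["chrom"], v["pos"], v["ref"], tuple(v["alts"]))
            for v in self.variants
            if v["individual"] == individual
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"variants": self.variants, "editing_events": self.editing_events},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(variants=d["variants"], editing_events=d["editing_events"])


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + internal-stop-free codons + one stop codon."""
    codons = []
    while len(codons) < n_codons - 2:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + _STOPS[rng.integers(0, 3)]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, strand: str, offset: int,
    structure: GeneStructure,
) -> tuple[GeneModel, str]:
    """Lay out one gene; returns the model (1-based genomic intervals from
    ``offset``) and its genomic-strand sequence segment."""
    st = structure
    n_ex = int(rng.integers(st.n_exons[0], st.n_exons[1] + 1))
    n_cod = int(rng.integers(st.n_codons[0], st.n_codons[1] + 1))
    u5 = int(rng.integers(st.utr5_len[0], st.utr5_len[1] + 1))
    u3 = int(rng.integers(st.utr3_len[0], st.utr3_len[1] + 1))
    cds_seq = _random_cds(rng, n_cod)
    utr5_seq = _random_seq(rng, u5)
    utr3_seq = _random_seq(rng, u3)

    if n_ex > 1:
        cuts = sorted(
            rng.choice(np.arange(1, len(cds_seq)), size=n_ex - 1, replace=False)
        )
    else:
        cuts = []
    chunks = [cds_seq[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds_seq)])]

    # transcript-orientation layout: [utr5+chunk1] intron [chunk2] ... [chunkN+utr3]
    pieces: list[tuple[str, str]] = []  # (kind, seq): kinds exon-part/intron
    rel: dict[str, list[tuple[int, int]]] = {"exons": [], "cds": [], "utr5": [], "utr3": []}
    cursor = 0

    def add(kind: str, seq: str) -> None:
        nonlocal cursor
        if seq:
            rel.setdefault(kind, []).append((cursor, cursor + len(seq)))
        cursor += len(seq)
        pieces.append((kind, seq))

    for i, chunk in enumerate(chunks):
        exon_start = cursor
        if i == 0:
            add("utr5", utr5_seq)
        add("cds", chunk)
        if i == len(chunks) - 1:
            add("utr3", utr3_seq)
        rel["exons"].append((exon_start, cursor))
        if i < len(chunks) - 1:
            ilen = int(rng.integers(st.intron_len[0], st.intron_len[1] + 1))
            add("intron", "GT" + _random_seq(rng, max(ilen - 4, 0)) + "AG")

    segment = "".join(seq for _, seq in pieces)
    length = len(segment)
    if strand == "-":
        segment = _revcomp(segment)
        rel = {
            k: sorted((length - e, length - s) for s, e in v) for k, v in rel.items()
        }

    def absolute(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        return [(offset + s + 1, offset + e) for s, e in sorted(ivs)]

    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=offset + 1,
        end=offset + length,
        exons=absolute(rel["exons"]),
        cds=absolute(rel["cds"]),
        utr5=absolute(rel["utr5"]),
        utr3=absolute(rel["utr3"]),
    )
    return model, segment


def chromosome_names(config: SimulationConfig) -> dict[str, int]:
    names = {
        f"chr{i + 1}": l for i, l in enumerate(config.chromosome_lengths)
    }
    if config.virtual_chrom_length > 0:
        names["chrUn"] = config.virtual_chrom_length
    return names


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Reference sequences plus gene models; deterministic in the config."""
    config.validate()
    rng = config.rng(1)
    lengths = chromosome_names(config)
    real = [c for c in lengths if c != "chrUn"]

    # round-robin gene placement with the configured spacing
    placements: list[tuple[str, int]] = []  # (chrom, 0-based offset)
    cursors = {c: config.min_gene_spacing // 2 for c in real}
    max_span = config.gene_structure.max_span
    for _ in range(config.n_genes):
        target = min(real, key=lambda c: cursors[c] / lengths[c])
        if cursors[target] + max_span + config.min_gene_spacing // 2 > lengths[target]:
            raise PlacementError(
                f"cannot place {config.n_genes} genes with spacing "
                f"{config.min_gene_spacing} on the configured chromosomes"
            )
        placements.append((target, cursors[target]))
        cursors[target] += max_span + config.min_gene_spacing

    genome: dict[str, list[str]] = {
        c: list(_random_seq(rng, l)) for c, l in lengths.items()
    }
    genes: list[GeneModel] = []
    for idx, (chrom, offset) in enumerate(placements):
        strand = "+" if rng.random() < 0.5 else "-"
        model, segment = _build_gene(
            rng, f"gene{idx + 1:03d}", chrom, strand, offset, config.gene_structure
        )
        genome[chrom][offset : offset + len(segment)] = list(segment)
        genes.append(model)
    return {c: "".join(s) for c, s in genome.items()}, genes


def transcript_to_genomic(gene: GeneModel, offset: int) -> int:
    """Genomic 1-based position of a 0-based spliced-transcript offset."""
    if offset < 0:
        raise EditingPlacementError(f"negative transcript offset {offset}")
    exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    for s, e in exons:
        n = e - s + 1
        if offset < n:
            return s + offset if gene.strand == "+" else e - offset
        offset -= n
    raise EditingPlacementError(
        f"transcript offset beyond the exons of {gene.gene_id}"
    )


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------


def _draw_alt(rng: np.random.Generator, ref: str, p_ti: float) -> str:
    if rng.random() < p_ti:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(0, 2)]


def _genotype(rng: np.random.Generator, config: SimulationConfig) -> str:
    u = rng.random()
    h = config.het_fraction
    if u < h * (1 - config.het_alt_alt_share):
        return "het_ref_alt"
    if u < h:
        return "het_alt_alt"
    return "hom_alt"


def _info(rng: np.random.Generator, config: SimulationConfig) -> dict[str, float]:
    info = {
        "DP": float(max(21, rng.poisson(config.dna_depth_mean))),
        "QD": float(np.round(rng.uniform(5.0, 30.0), 2)),
        "MQRankSum": float(np.round(rng.normal(0.0, 2.0), 2)),
        "FS": float(np.round(abs(rng.normal(0.0, 8.0)), 2)),
        "HaplotypeScore": float(np.round(rng.uniform(0.0, 8.0), 2)),
        "ReadPosRankSum": float(np.round(rng.normal(0.0, 2.0), 2)),
    }
    if rng.random() < config.low_quality_fraction:
        which = rng.integers(0, 4)
        if which == 0:
            info["DP"] = float(rng.integers(1, 21))
        elif which == 1:
            info["QD"] = float(np.round(rng.uniform(0.0, 1.9), 2))
        elif which == 2:
            info["FS"] = float(np.round(rng.uniform(201.0, 400.0), 2))
        else:
            info["ReadPosRankSum"] = float(np.round(rng.uniform(-30.0, -21.0), 2))
    return info


def generate_individuals(
    genome: Mapping[str, str], config: SimulationConfig
) -> tuple[dict[str, list[VariantRecord]], PlantedTruth]:
    """Plant SNPs and InDels for the two individuals.

    The union of planted positions is drawn uniformly over the genome
    (SNP and InDel positions never collide); each union variant is shared by
    both individuals with probability ``shared_fraction`` and otherwise
    assigned to one of them, so the expected shared/union fraction equals the
    config target. Genotype classes and alternate alleles follow the
    configured heterozygosity mix and Ti/Tv target.
    """
    config.validate()
    rng = config.rng(2)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms])
    starts = np.concatenate([[0], np.cumsum(lengths)])
    total = int(starts[-1])

    n_snp_ind = int(round(config.snp_rate * total))
    n_indel_ind = int(round(config.indel_rate * total))
    per_union = config.shared_fraction + (1 - config.shared_fraction) / 2
    u_snp = int(round(n_snp_ind / per_union)) if n_snp_ind else 0
    u_indel = int(round(n_indel_ind / per_union)) if n_indel_ind else 0

    # choice without replacement returns the sites in random order, so the
    # first u_snp are an unbiased SNP subset
    flat = rng.choice(total, size=u_snp + u_indel, replace=False)

    # Alleles and genotype class are drawn once per union site and reused by
    # every carrier, so a shared variant is byte-identical in both VCFs. A 1/2
    # site carries the transition partner plus one transversion; the Ti
    # probability of the remaining (single-alt) draws is adjusted so the
    # overall planted Ti/Tv still hits the target.
    t_frac = config.target_titv / (1.0 + config.target_titv)
    r12 = config.het_fraction * config.het_alt_alt_share
    p_ti = (t_frac * (1 + r12) - r12) / (1 - r12) if r12 < 1 else 0.0
    p_ti = min(max(p_ti, 0.0), 1.0)

    records: dict[str, list[VariantRecord]] = {i: [] for i in config.individuals}
    truth = PlantedTruth()

    for i, fpos in enumerate(flat):
        ci = int(np.searchsorted(starts, fpos, side="right") - 1)
        chrom = chroms[ci]
        pos = int(fpos - starts[ci]) + 1
        is_snp = i < u_snp
        seq = genome[chrom]
        if not is_snp and pos + config.max_indel_len + 1 > len(seq):
            continue  # indel would run off the chromosome; drop this site
        ref_base = seq[pos - 1]

        gclass = _genotype(rng, config)
        if is_snp:
            if gclass == "het_alt_alt":
                pair = [_TRANSITION[ref_base], _TRANSVERSIONS[ref_base][rng.integers(0, 2)]]
                if rng.random() < 0.5:
                    pair.reverse()
                ref, alts = ref_base, tuple(pair)
            else:
                ref, alts = ref_base, (_draw_alt(rng, ref_base, p_ti),)
        else:
            if gclass == "het_alt_alt":
                gclass = "het_ref_alt"  # indels stay bi-allelic
            if rng.random() < 0.5:  # insertion
                ins = _random_seq(rng, int(rng.integers(1, config.max_indel_len + 1)))
                ref, alts = ref_base, (ref_base + ins,)
            else:  # deletion
                dlen = int(rng.integers(1, config.max_indel_len + 1))
                ref = seq[pos - 1 : pos + dlen]
                alts = (ref_base,)

        shared = rng.random() < config.shared_fraction
        carriers = (
            list(config.individuals)
            if shared
            else [config.individuals[int(rng.integers(0, len(config.individuals)))]]
        )
        for ind in carriers:
            rec = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                genotype_class=gclass,
                kind=variant_kind(ref, alts),
                info=_info(rng, config),
            )
            records[ind].append(rec)
            truth.variants.append(
                {
                    "individual": ind,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alts": list(alts),
                    "genotype_class": gclass,
                    "kind": rec.kind,
                    "shared": shared,
                }
            )
    return records, truth


# ---------------------------------------------------------------------------
# RNA pileups, expression, editing events
# ---------------------------------------------------------------------------


def _resolve_editing_sites(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    expressed: Sequence[str],
    rng: np.random.Generator,
) -> list[EditingSiteSpec]:
    if config.editing_sites is not None:
        return list(config.editing_sites)
    by_id = {g.gene_id: g for g in genes}
    specs: list[EditingSiteSpec] = []
    pool = [g for g in expressed if g in by_id]
    if not pool:
        return specs
    for k in range(config.n_auto_editing_events):
        gid = pool[k % len(pool)]
        gene = by_id[gid]
        tlen = sum(e - s + 1 for s, e in gene.exons)
        off = int(rng.integers(3, tlen))  # skip the start codon's first bases
        to = str(rng.choice([b for b in "ACGT"]))
        full = k % 2 == 1
        frac = 1.0 if full else float(
            np.round(rng.uniform(*config.edit_fraction_range), 3)
        )
        ind = config.individuals[k % len(config.individuals)]
        n_stages = int(rng.integers(1, len(config.stages) + 1))
        chosen = rng.choice(len(config.stages), size=n_stages, replace=False)
        fractions = {f"{ind}_{config.stages[s]}": frac for s in sorted(chosen)}
        specs.append(EditingSiteSpec(gid, off, to, fractions))
    return specs


def _depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    lam = rng.gamma(config.rna_depth_shape, config.rna_depth_mean / config.rna_depth_shape)
    return max(config.rna_depth_min, int(rng.poisson(lam)))


def generate_rna_pileups(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    truth: PlantedTruth,
    config: SimulationConfig,
) -> tuple[list[SitePileup], list[SitePileup], pd.DataFrame, dict[tuple[str, int], str]]:
    """DNA/RNA pileups at edited plus control sites, and per-gene read counts.

    Editing events are placed only at exonic positions that carry no planted
    DNA variant (re-drawn on collision for auto-generated events; an explicit
    collision in a user-supplied spec raises). Returns
    ``(rna_pileups, dna_pileups, gene_counts, gene_of_site)`` and appends the
    realized events to ``truth.editing_events``.
    """
    config.validate()
    rng = config.rng(3)
    by_id = {g.gene_id: g for g in genes}
    variant_positions = {(v["chrom"], v["pos"]) for v in truth.variants}

    n_unexpr = min(config.n_unexpressed_genes, max(len(genes) - 1, 0))
    expressed = [g.gene_id for g in genes[: len(genes) - n_unexpr]]
    unexpressed = [g.gene_id for g in genes[len(genes) - n_unexpr :]]

    # --- expression ------------------------------------------------------
    exon_len = {
        g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in genes
    }
    count_rows = []
    for gid in expressed:
        for sample in config.samples:
            target = rng.uniform(config.rpkm_floor, config.rpkm_ceiling)
            reads = math.ceil(target * exon_len[gid] * config.library_size / 1e9)
            count_rows.append({"gene_id": gid, "sample": sample, "reads": reads})
    for gid in unexpressed:
        for sample in config.samples:
            count_rows.append({"gene_id": gid, "sample": sample, "reads": 0})
    gene_counts = pd.DataFrame(count_rows)

    # --- editing events --------------------------------------------------
    specs = _resolve_editing_sites(config, genes, expressed, rng)
    events: list[dict] = []
    used_positions: set[tuple[str, int]] = set()
    for spec in specs:
        if spec.gene_id not in by_id:
            raise EditingPlacementError(f"unknown gene {spec.gene_id!r}")
        gene = by_id[spec.gene_id]
        off = spec.transcript_offset
        pos = transcript_to_genomic(gene, off)
        auto = config.editing_sites is None
        tries = 0
        while auto and (
            (gene.chrom, pos) in variant_positions or (gene.chrom, pos) in used_positions
        ):
            tlen = sum(e - s + 1 for s, e in gene.exons)
            off = int(rng.integers(3, tlen))
            pos = transcript_to_genomic(gene, off)
            tries += 1
            if tries > 200:
                raise EditingPlacementError(
                    f"no variant-free exonic position found in {spec.gene_id}"
                )
        if not auto and (gene.chrom, pos) in variant_positions:
            raise EditingPlacementError(
                f"editing site {gene.chrom}:{pos} collides with a planted DNA variant"
            )
        g_from = genome[gene.chrom][pos - 1]
        t_from = g_from if gene.strand == "+" else g_from.translate(_COMPLEMENT)
        if spec.from_base is not None and spec.from_base != t_from:
            raise EditingPlacementError(
                f"from_base {spec.from_base} does not match the reference "
                f"({t_from}) at transcript offset {off} of {spec.gene_id}"
            )
        t_to = spec.to_base
        if t_to == t_from:
            t_to = _TRANSITION[t_from]  # auto-drawn to-base may equal ref; nudge
        g_to = t_to if gene.strand == "+" else t_to.translate(_COMPLEMENT)
        used_positions.add((gene.chrom, pos))
        for sample, frac in spec.fractions.items():
            events.append(
                {
                    "chrom": gene.chrom,
                    "pos": pos,
                    "sample": sample,
                    "gene_id": spec.gene_id,
                    "from_base": g_from,
                    "to_base": g_to,
                    "fraction": float(frac),
                    "mode": "full_edit" if frac >= 1.0 else "two_variant",
                }
            )
    truth.editing_events.extend(events)

    # --- control (non-edited) sites --------------------------------------
    sites: dict[tuple[str, int], str] = {
        (e["chrom"], e["pos"]): e["gene_id"] for e in events
    }
    pool = expressed or [g.gene_id for g in genes]
    tries = 0
    while len(sites) < len({(e["chrom"], e["pos"]) for e in events}) + config.n_control_sites:
        if not pool:
            break
        gid = pool[int(rng.integers(0, len(pool)))]
        gene = by_id[gid]
        tlen = sum(e - s + 1 for s, e in gene.exons)
        pos = transcript_to_genomic(gene, int(rng.integers(0, tlen)))
        key = (gene.chrom, pos)
        tries += 1
        if key in sites or key in variant_positions:
            if tries > 100 * config.n_control_sites:
                break
            continue
        sites[key] = gid

    edited_at: dict[tuple[str, int, str], dict] = {
        (e["chrom"], e["pos"], e["sample"]): e for e in events
    }

    dna_pileups: list[SitePileup] = []
    rna_pileups: list[SitePileup] = []
    for (chrom, pos), gid in sorted(sites.items()):
        ref = genome[chrom][pos - 1]
        for ind in config.individuals:
            d = max(5, int(rng.poisson(config.dna_depth_mean)))
            dna_pileups.append(
                SitePileup(chrom, pos, ind, {b: (d if b == ref else 0) for b in "ACGT"})
            )
        for sample in config.samples:
            d = _depth(rng, config)
            ev = edited_at.get((chrom, pos, sample))
            counts = dict.fromkeys("ACGT", 0)
            if ev is None:
                counts[ref] = d
            else:
                k = int(rng.binomial(d, ev["fraction"])) if ev["fraction"] < 1.0 else d
                counts[ev["to_base"]] = k
                counts[ev["from_base"]] += d - k
            rna_pileups.append(SitePileup(chrom, pos, sample, counts))
    return rna_pileups, dna_pileups, gene_counts, dict(sites)


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------


def generate_contigs(
    config: SimulationConfig,
    n: int = 200,
    length_range: tuple[int, int] = (300, 8000),
    gc: float = 0.34,
) -> list[str]:
    """Random contig set with a configurable GC content, for assembly metrics."""
    rng = config.rng(4)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for _ in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append("".join(_BASES[rng.choice(4, size=length, p=probs)]))
    return out


# ---------------------------------------------------------------------------
# bundle + file output
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    variants: dict[str, list[VariantRecord]]
    truth: PlantedTruth
    rna_pileups: list[SitePileup]
    dna_pileups: list[SitePileup]
    gene_counts: pd.DataFrame
    gene_of_site: dict[tuple[str, int], str]
    contigs: list[str]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run the whole generator under one config."""
    genome, genes = generate_genome(config)
    variants, truth = generate_individuals(genome, config)
    rna, dna, counts, site_genes = generate_rna_pileups(genome, genes, truth, config)
    contigs = generate_contigs(config)
    return SyntheticCohort(
        config, genome, genes, variants, truth, rna, dna, counts, site_genes, contigs
    )


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_pileups(pileups: Sequence[SitePileup], path: str) -> None:
    rows = [
        {
            "chrom": p.chrom,
            "pos": p.pos,
            "sample": p.sample,
            **{b: p.counts.get(b, 0) for b in "ACGT"},
            "del": p.deletions,
            "ins": p.insertions,
        }
        for p in pileups
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pileups(path: str) -> list[SitePileup]:
    df = pd.read_csv(path, sep="\t")
    return [
        SitePileup(
            r["chrom"],
            int(r["pos"]),
            r["sample"],
            {b: int(r[b]) for b in "ACGT"},
            deletions=int(r["del"]),
            insertions=int(r["ins"]),
        )
        for _, r in df.iterrows()
    ]


def write_gene_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("editing_sites") is not None:
        d["editing_sites"] = [dataclasses.asdict(s) for s in config.editing_sites]
    return d
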