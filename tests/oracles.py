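"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths: protein impacts are
obtained by editing the whole chromosome string, shifting annotation
intervals and re-translating the complete protein; quartiles are computed by
hand from the sorted vector; N50 by scanning every prefix of the sorted
lengths.
"""

from __future__ import annotations

import copy

from Bio.Seq import Seq


def apply_variant_to_chromosome(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def shift_gene(gene, pos: int, net: int):
    """Shift all gene intervals right of an edit by its net length change."""
    g = copy.deepcopy(gene)

    def sh(x: int) -> int:
        return x + net if x > pos else x

    g.end = sh(g.end)
    for name in ("exons", "cds", "utr5", "utr3"):
        setattr(g, name, [(sh(a), sh(b)) for a, b in getattr(g, name)])
    return g


def _protein(gene, genome) -> str:
    return str(Seq(gene.coding_sequence(genome)).translate())


def snp_impact_oracle(gene, genome, pos: int, ref: str, alt: str) -> str:
    """Full-protein diff after editing the chromosome string."""
    mutated = dict(genome)
    mutated[gene.chrom] = apply_variant_to_chromosome(mutated[gene.chrom], pos, ref, alt)
    p_old = _protein(gene, genome)
    p_new = _protein(gene, mutated)
    if p_old == p_new:
        return "synonymous"
    i = next(k for k, (a, b) in enumerate(zip(p_old, p_new)) if a != b)
    if i == 0 and p_new[0] != "M":
        return "start_lost"
    if p_new[i] == "*":
        return "stop_gained"
    if p_old[i] == "*":
        return "stop_lost"
    return "non_synonymous"


def indel_impact_oracle(gene, genome, pos: int, ref: str, alt: str) -> str:
    net = len(alt) - len(ref)
    mutated = dict(genome)
    mutated[gene.chrom] = apply_variant_to_chromosome(mutated[gene.chrom], pos, ref, alt)
    g2 = shift_gene(gene, pos, net)
    cds_old = gene.coding_sequence(genome)
    cds_new = g2.coding_sequence(mutated)
    if (len(cds_new) - len(cds_old)) % 3 != 0:
        return "frameshift"
    p_old = str(Seq(cds_old).translate())
    p_new = str(Seq(cds_new).translate())
    if len(p_new) < len(p_old):
        short, long_ = p_new, p_old
        pure, mixed = "codon_deletion", "codon_change_plus_deletion"
    else:
        short, long_ = p_old, p_new
        pure, mixed = "codon_insertion", "codon_change_plus_insertion"
    p = 0
    while p < len(short) and short[p] == long_[p]:
        p += 1
    s = 0
    while s < len(short) - p and short[-1 - s] == long_[-1 - s]:
        s += 1
    return pure if p + s >= len(short) else mixed


def quartiles_oracle(values) -> tuple[float, float]:
    """Type-7 (linear interpolation) quartiles from the sorted vector."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.75)


def n50_oracle(lengths) -> int:
    xs = sorted(lengths, reverse=True)
    total = sum(xs)
    for i in range(len(xs)):
        if 2 * sum(xs[: i + 1]) >= total:
            return xs[i]
    raise AssertionError
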