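"""DNA-vs-RNA editing caller: filters, allele profiles, calls, recovery."""

from __future__ import annotations

import pandas as pd
import pytest

from viteseq.editing import (
    AlleleProfile,
    RnaCallMetadata,
    SitePileup,
    allele_profile,
    annotate_and_summarize,
    call_editing,
    detect_editing,
    expression_table,
    rna_variant_prefilter,
    rpkm,
    site_passes_filters,
)

SIX = {f"{i}_{s}": 10.0 for i in ("WF", "WM") for s in ("B", "D", "H")}


def pile(counts, sample="WF_B", pos=100, **kw):
    return SitePileup("chr1", pos, sample, counts, **kw)


class TestRpkm:
    @pytest.mark.parametrize(
        "reads,length,total,expected",
        [(1, 1000, 1_000_000, 1.0), (0, 1000, 10**6, 0.0), (250, 2000, 5 * 10**6, 25.0)],
    )
    def test_formula(self, reads, length, total, expected):
        assert rpkm(reads, length, total) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            rpkm(1, 1000, 0)


class TestPrefilter:
    def nominal(self, **kw):
        d = dict(
            distance_to_sequence_end=500,
            reference_ambiguous_within_60=False,
            flanking_copy_number=1.0,
            min_allele_quality=30.0,
            min_allele_support=5,
            variant_frequency=0.2,
            coverage=10,
        )
        d.update(kw)
        return RnaCallMetadata(**d)

    @pytest.mark.parametrize(
        "kw,reason",
        [
            ({"distance_to_sequence_end": 30}, "sequence_end"),
            ({"reference_ambiguous_within_60": True}, "ambiguous_reference"),
            ({"flanking_copy_number": 2.5}, "copy_number"),
            ({"min_allele_quality": 19.0}, "allele_quality"),
            ({"min_allele_support": 1}, "allele_support"),
            ({"variant_frequency": 0.10}, "variant_frequency"),
            ({"coverage": 3}, "coverage"),
        ],
    )
    def test_each_rule_discards(self, kw, reason):
        keep, why = rna_variant_prefilter(self.nominal(**kw))
        assert not keep and why == reason

    def test_boundary_coverage_and_frequency_kept(self):
        keep, why = rna_variant_prefilter(self.nominal(coverage=4, variant_frequency=0.15))
        assert keep and why is None

    def test_first_failing_rule_reported(self):
        keep, why = rna_variant_prefilter(
            self.nominal(distance_to_sequence_end=10, coverage=1)
        )
        assert why == "sequence_end"


class TestAlleleProfile:
    def test_ten_percent_boundary_retained_and_homozygous(self):
        prof = allele_profile(pile({"A": 9, "G": 1, "C": 0, "T": 0}))
        assert set(prof.alleles) == {"A", "G"}
        assert prof.zygosity == "homozygous"  # A at exactly 0.90

    def test_below_support_discarded(self):
        prof = allele_profile(pile({"A": 95, "G": 5, "C": 0, "T": 0}))
        assert set(prof.alleles) == {"A"}
        assert prof.zygosity == "homozygous"

    def test_even_split_heterozygous(self):
        prof = allele_profile(pile({"A": 50, "G": 50, "C": 0, "T": 0}))
        assert set(prof.alleles) == {"A", "G"}
        assert prof.zygosity == "heterozygous"

    def test_just_below_hom_threshold_is_heterozygous(self):
        prof = allele_profile(pile({"A": 89, "G": 11, "C": 0, "T": 0}))
        assert prof.zygosity == "heterozygous"

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError):
            allele_profile(pile({"A": 0, "C": 0, "G": 0, "T": 0}))

    def test_deletions_count_toward_depth(self):
        prof = allele_profile(pile({"A": 9, "G": 0, "C": 0, "T": 0}, deletions=1))
        assert prof.alleles["A"] == pytest.approx(0.9)


class TestSiteFilters:
    def test_low_dna_coverage_fails(self):
        ok, reasons = site_passes_filters(
            pile({"A": 4, "C": 0, "G": 0, "T": 0}, sample="WF"),
            pile({"A": 50, "C": 0, "G": 0, "T": 0}),
            SIX,
        )
        assert not ok and reasons == ["dna_coverage"]

    def test_low_rpkm_in_one_sample_fails(self):
        expr = dict(SIX, WM_H=0.5)
        ok, reasons = site_passes_filters(
            pile({"A": 30, "C": 0, "G": 0, "T": 0}, sample="WF"),
            pile({"A": 30, "C": 0, "G": 0, "T": 0}),
            expr,
        )
        assert not ok and "expression" in reasons

    def test_indel_evidence_fails(self):
        ok, reasons = site_passes_filters(
            pile({"A": 30, "C": 0, "G": 0, "T": 0}, sample="WF"),
            pile({"A": 30, "C": 0, "G": 0, "T": 0}, insertions=2),
            SIX,
        )
        assert not ok and "indel_site" in reasons

    def test_incomplete_expression_row_raises(self):
        with pytest.raises(ValueError):
            site_passes_filters(
                pile({"A": 30, "C": 0, "G": 0, "T": 0}, sample="WF"),
                pile({"A": 30, "C": 0, "G": 0, "T": 0}),
                {"WF_B": 5.0},
            )

    def test_nominal_site_passes(self):
        ok, reasons = site_passes_filters(
            pile({"A": 5, "C": 0, "G": 0, "T": 0}, sample="WF"),
            pile({"A": 5, "C": 0, "G": 0, "T": 0}),
            SIX,
        )
        assert ok and reasons == []


class TestCallEditing:
    def test_two_variant_t_to_a(self):
        dna = AlleleProfile({"T": 1.0}, "homozygous")
        rna = AlleleProfile({"T": 0.6, "A": 0.4}, "heterozygous")
        call = call_editing(dna, rna)
        assert (call.mode, call.from_base, call.to_base) == ("two_variant", "T", "A")

    def test_full_edit(self):
        dna = AlleleProfile({"C": 1.0}, "homozygous")
        rna = AlleleProfile({"T": 1.0}, "homozygous")
        call = call_editing(dna, rna)
        assert (call.mode, call.from_base, call.to_base) == ("full_edit", "C", "T")

    def test_genome_supported_allele_is_not_editing(self):
        dna = AlleleProfile({"A": 0.5, "G": 0.5}, "heterozygous")
        rna = AlleleProfile({"G": 1.0}, "homozygous")
        assert call_editing(dna, rna).mode == "none"

    def test_strict_mode_requires_zero_dna_reads(self):
        dna_pile = pile({"T": 92, "A": 8, "C": 0, "G": 0}, sample="WF")
        dna = allele_profile(dna_pile)  # A at 8% -> dropped from profile
        rna = AlleleProfile({"T": 0.5, "A": 0.5}, "heterozygous")
        assert call_editing(dna, rna).mode == "two_variant"
        strict = call_editing(dna, rna, require_zero_dna_reads=True, dna_pileup=dna_pile)
        assert strict.mode == "none"


@pytest.fixture(scope="module")
def calls(editing_cohort):
    c = editing_cohort
    exon_len = {g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in c.genes}
    totals = {s: c.config.library_size for s in c.config.samples}
    expr = expression_table(c.gene_counts, exon_len, totals)
    rpkm_by_gene = {
        gid: dict(zip(sub["sample"], sub["rpkm"]))
        for gid, sub in expr.groupby("gene_id")
    }
    return detect_editing(
        c.dna_pileups, c.rna_pileups, rpkm_by_gene, c.gene_of_site,
        genes=c.genes, genome=c.genome,
    )


class TestPipeline:

    def test_planted_truth_recovered_exactly(self, editing_cohort, calls):
        """Sensitivity 1.0 and false-positive rate 0 under clean simulation."""
        truth = {
            (e["chrom"], e["pos"], e["sample"])
            for e in editing_cohort.truth.editing_events
        }
        hits = calls[~calls["mode"].isin(["none", "filtered"])]
        called = set(zip(hits["chrom"], hits["pos"], hits["sample"]))
        assert called == truth
        n_sites = len({(p.chrom, p.pos) for p in editing_cohort.rna_pileups})
        assert n_sites >= 200

    def test_modes_and_bases_match_truth(self, editing_cohort, calls):
        by_key = {
            (e["chrom"], e["pos"], e["sample"]): e
            for e in editing_cohort.truth.editing_events
        }
        hits = calls[~calls["mode"].isin(["none", "filtered"])]
        for r in hits.itertuples():
            ev = by_key[(r.chrom, r.pos, r.sample)]
            assert r.to_base == ev["to_base"]
            assert r.from_base == ev["from_base"]
            if ev["mode"] == "full_edit":
                assert r.mode == "full_edit"

    def test_every_row_accounted_for(self, editing_cohort, calls):
        assert len(calls) == len(editing_cohort.rna_pileups)
        filtered = calls[calls["mode"] == "filtered"]
        assert (filtered["reasons"].str.len() > 0).all()

    def test_support_threshold_monotonicity(self, editing_cohort):
        c = editing_cohort
        exon_len = {g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in c.genes}
        totals = {s: c.config.library_size for s in c.config.samples}
        expr = expression_table(c.gene_counts, exon_len, totals)
        rpkm_by_gene = {
            gid: dict(zip(sub["sample"], sub["rpkm"]))
            for gid, sub in expr.groupby("gene_id")
        }
        counts = []
        for frac in (0.05, 0.10, 0.25, 0.50):
            df = detect_editing(
                c.dna_pileups, c.rna_pileups, rpkm_by_gene, c.gene_of_site,
                support_frac=frac,
            )
            counts.append(int((~df["mode"].isin(["none", "filtered"])).sum()))
        assert counts == sorted(counts, reverse=True)


class TestSummaries:
    def test_expression_floor_and_unexpressed_gene(self, cohort):
        c = cohort
        exon_len = {g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in c.genes}
        totals = {s: c.config.library_size for s in c.config.samples}
        expr = expression_table(c.gene_counts, exon_len, totals)
        expressed = expr[expr["reads"] > 0]
        assert (expressed["rpkm"] >= c.config.rpkm_floor).all()
        silent = expr[expr["reads"] == 0]
        assert not silent.empty and (silent["rpkm"] < 1).all()

    def test_per_gene_summary_counts_cds_split(self):
        rows = []
        for i in range(7):
            rows.append(
                {
                    "chrom": "chr2", "pos": 4_950_000 + i, "sample": "WM_D",
                    "gene_id": "gX", "mode": "two_variant",
                    "context": "cds" if i < 5 else "utr3", "impact": None,
                }
            )
        per_gene, report = annotate_and_summarize(pd.DataFrame(rows))
        row = per_gene.iloc[0]
        assert row["n_loci"] == 7
        assert row["n_cds_loci"] == 5
        assert row["n_non_cds_loci"] == 2
        assert report["calls_inside"] == 7

    def test_empty_call_set(self):
        per_gene, report = annotate_and_summarize(
            pd.DataFrame(columns=["chrom", "pos", "sample", "gene_id", "mode", "context", "impact"])
        )
        assert per_gene.empty
        assert report["calls_inside"] == 0
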