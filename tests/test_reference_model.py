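"""Gene geometry, OTFR membership and alternative-reference construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regsnp_scout.io_formats import Interval
from regsnp_scout.reference_model import (GeneModel, OtfrIndex,
                                          classify_position, in_otfr,
                                          make_alternative_reference,
                                          promoter_region, read_gene_models)


def _gene(gene_id="G1", chrom="chr1", strand="+", g0=4000):
    """A two-exon gene starting at 0-based g0 with 100 bp terminal UTRs."""
    exons = [Interval(chrom, g0, g0 + 500), Interval(chrom, g0 + 900, g0 + 1400)]
    utr_left = [Interval(chrom, g0, g0 + 100)]
    utr_right = [Interval(chrom, g0 + 1300, g0 + 1400)]
    utr5, utr3 = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
    cds = [Interval(chrom, g0 + 100, g0 + 500), Interval(chrom, g0 + 900, g0 + 1300)]
    return GeneModel(gene_id, chrom, strand, exons, cds, utr5, utr3)


class TestPromoterRegion:
    def test_symmetric_span_around_tss(self):
        gene = _gene(g0=4999)               # plus strand, TSS = 5000 (1-based)
        iv = promoter_region(gene, 1800)
        assert (iv.start, iv.end) == (3199, 6800)      # 1-based 3200..6800
        assert iv.contains_pos("chr1", 3200) and iv.contains_pos("chr1", 6800)
        assert not iv.contains_pos("chr1", 3199)
        assert not iv.contains_pos("chr1", 6801)

    def test_strand_invariant(self):
        plus = promoter_region(_gene(strand="+", g0=4999), 1800)
        minus_gene = _gene(strand="-", g0=4999 - 1399)  # TSS also 5000
        assert minus_gene.tss == 5000
        minus = promoter_region(minus_gene, 1800)
        assert (plus.start, plus.end) == (minus.start, minus.end)
        assert len(plus) == 2 * 1800 + 1

    def test_clamped_at_chromosome_start(self):
        gene = _gene(g0=999)                 # TSS = 1000
        iv = promoter_region(gene, 1800)
        assert (iv.start, iv.end) == (0, 2800)          # 1-based 1..2800

    def test_zero_flank_is_error(self):
        with pytest.raises(ValueError):
            promoter_region(_gene(), 0)

    def test_tss_outside_chromosome_is_error(self):
        with pytest.raises(ValueError):
            promoter_region(_gene(g0=4000), 1800, chrom_length=3000)


class TestClassifyPosition:
    def test_intron_membership(self):
        gene = _gene(g0=4000)
        hits = classify_position("chr1", 4601, [gene], 10)  # 0-based 4600: intron
        assert hits == {("G1", "intron")}

    def test_tss_is_in_promoter(self):
        gene = _gene(g0=4000)
        hits = classify_position("chr1", gene.tss, [gene], 50)
        assert ("G1", "promoter") in hits

    def test_cds_only_position_yields_empty_set(self):
        gene = _gene(g0=4000)
        # 0-based 4300 is CDS exon; use tiny flank so promoter misses it
        assert classify_position("chr1", 4301, [gene], 10) == set()

    def test_overlapping_genes_give_multiple_entries(self):
        g1 = _gene("G1", g0=4000)
        g2 = _gene("G2", strand="-", g0=2700)  # G2 utr5 at right end 4000..4100
        hits = classify_position("chr1", 4050, [g1, g2], 1800)
        assert ("G1", "promoter") in hits
        assert ("G2", "utr5") in hits

    def test_matches_brute_force_on_random_models(self):
        rng = np.random.default_rng(11)
        genes = []
        for i in range(40):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_gene(f"G{i}", strand=strand,
                               g0=int(rng.integers(2000, 60_000))))
        flank = 300

        def oracle(pos):
            hits = set()
            coord = pos - 1
            for g in genes:
                lo, hi = max(1, g.tss - flank), g.tss + flank
                if lo <= pos <= hi:
                    hits.add((g.gene_id, "promoter"))
                for name, ivs in (("intron", g.introns), ("utr5", g.utr5),
                                  ("utr3", g.utr3)):
                    for iv in ivs:
                        if iv.start <= coord < iv.end:
                            hits.add((g.gene_id, name))
            return hits

        for pos in rng.integers(1, 62_000, size=300):
            pos = int(pos)
            assert classify_position("chr1", pos, genes, flank) == oracle(pos)


class TestOtfrMembership:
    def test_half_open_boundary_semantics(self):
        otfrs = [Interval("chr1", 10, 20)]
        # 1-based positions: 10 -> 0-based 9 (outside); 11..20 inside; 21 out
        expected = {pos: (11 <= pos <= 20) for pos in range(9, 23)}
        for pos, want in expected.items():
            assert in_otfr("chr1", pos, otfrs) is want, pos

    def test_index_agrees_with_linear_scan_on_overlapping_intervals(self):
        rng = np.random.default_rng(3)
        ivs = []
        for _ in range(60):
            s = int(rng.integers(0, 5000))
            ivs.append(Interval("chr1", s, s + int(rng.integers(1, 400))))
        index = OtfrIndex(ivs)
        for pos in range(1, 5500, 7):
            linear = any(iv.contains_pos("chr1", pos) for iv in ivs)
            assert index.contains("chr1", pos) is linear

    def test_unknown_chromosome_is_false(self):
        assert not in_otfr("chr9", 5, [Interval("chr1", 0, 10)])


class TestAlternativeReference:
    def test_single_substitution(self):
        out = make_alternative_reference({"c": "ACGTA"}, [("c", 3, "G", "C")])
        assert out == {"c": "ACCTA"}

    def test_involution_with_swapped_alleles(self):
        snps = [("c", 1, "A", "T"), ("c", 4, "T", "G")]
        fwd = make_alternative_reference({"c": "ACGTA"}, snps)
        back = make_alternative_reference(fwd, [(c, p, alt, ref)
                                                for c, p, ref, alt in snps])
        assert back == {"c": "ACGTA"}

    def test_ref_mismatch_lists_offending_site(self):
        with pytest.raises(ValueError, match="c:3"):
            make_alternative_reference({"c": "ACGTA"}, [("c", 3, "T", "C")])

    def test_lengths_always_preserved(self):
        out = make_alternative_reference({"c": "ACGTACGT"},
                                         [("c", 2, "C", "G"), ("c", 8, "T", "A")])
        assert len(out["c"]) == 8

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_involution_property_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        positions = rng.choice(200, size=20, replace=False) + 1
        snps = []
        for pos in sorted(int(p) for p in positions):
            ref = seq[pos - 1]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            snps.append(("c", pos, ref, alt))
        fwd = make_alternative_reference({"c": seq}, snps)
        assert sum(a != b for a, b in zip(seq, fwd["c"])) == len(snps)
        back = make_alternative_reference(fwd, [(c, p, a, r)
                                                for c, p, r, a in snps])
        assert back["c"] == seq


class TestReadGeneModels:
    def test_geometry_from_gtf(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        attrs = 'gene_id "GX"; transcript_id "GX.t1";'
        lines = [
            f"chr1\tsrc\texon\t101\t200\t.\t+\t.\t{attrs}",
            f"chr1\tsrc\texon\t301\t400\t.\t+\t.\t{attrs}",
            f"chr1\tsrc\tCDS\t121\t200\t.\t+\t.\t{attrs}",
            f"chr1\tsrc\tfive_prime_utr\t101\t120\t.\t+\t.\t{attrs}",
            f"chr1\tsrc\tthree_prime_utr\t381\t400\t.\t+\t.\t{attrs}",
        ]
        gtf.write_text("\n".join(lines) + "\n")
        (gene,) = read_gene_models(gtf)
        assert gene.gene_id == "GX" and gene.tss == 101
        assert [(iv.start, iv.end) for iv in gene.exons] == [(100, 200), (300, 400)]
        assert [(iv.start, iv.end) for iv in gene.introns] == [(200, 300)]
        assert [(iv.start, iv.end) for iv in gene.utr5] == [(100, 120)]

    def test_longest_transcript_is_canonical(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        a1 = 'gene_id "GY"; transcript_id "short";'
        a2 = 'gene_id "GY"; transcript_id "long";'
        gtf.write_text(
            f"chr1\ts\texon\t101\t150\t.\t-\t.\t{a1}\n"
            f"chr1\ts\texon\t101\t400\t.\t-\t.\t{a2}\n")
        (gene,) = read_gene_models(gtf)
        assert gene.exons[0].end - gene.exons[0].start == 300
        assert gene.tss == 400                  # minus strand: rightmost end
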