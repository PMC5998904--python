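"""Target-gene assignment: proximal membership and ChIA-PET distal links."""

import math

import numpy as np
import pandas as pd
import pytest

from regsnp_scout.config import RunConfig
from regsnp_scout.io_formats import ChiaPetContact, Interval
from regsnp_scout.reference_model import GeneModel
from regsnp_scout.target_assignment import (assign_distal_targets,
                                            assign_nearby_targets,
                                            assign_targets,
                                            build_contact_matrix,
                                            contact_significance,
                                            effective_genome_size,
                                            filter_contacts)


def _gene(gene_id, chrom="chr1", g0=50_000, strand="+"):
    exons = [Interval(chrom, g0, g0 + 500), Interval(chrom, g0 + 900, g0 + 1400)]
    return GeneModel(gene_id, chrom, strand, exons,
                     cds=[Interval(chrom, g0 + 100, g0 + 500),
                          Interval(chrom, g0 + 900, g0 + 1300)],
                     utr5=[Interval(chrom, g0, g0 + 100)],
                     utr3=[Interval(chrom, g0 + 1300, g0 + 1400)])


def _snps(*positions, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom] * len(positions),
                         "pos": list(positions)})


class TestNearbyTargets:
    def test_intron_snp_assigned(self):
        df = assign_nearby_targets(_snps(50_700), [_gene("G1")],
                                   RunConfig(promoter_flank_bp=100))
        assert [(r.gene_id, r.relation) for r in df.itertuples(index=False)] \
            == [("G1", "intron")]

    def test_cds_only_snp_has_no_nearby_target(self):
        cfg = RunConfig(promoter_flank_bp=100)
        df = assign_nearby_targets(_snps(50_301), [_gene("G1")], cfg)
        assert df.empty

    def test_promoter_overlap_of_two_genes_gives_two_assignments(self):
        genes = [_gene("G1", g0=50_000), _gene("G2", g0=51_500)]
        df = assign_nearby_targets(_snps(50_950), genes, RunConfig())
        promoter_hits = df[df.relation == "promoter"].gene_id.tolist()
        assert promoter_hits == ["G1", "G2"]


class TestEffectiveGenomeSize:
    def test_merged_overlap_counts_once(self):
        peaks = [[Interval("chr1", 0, 100), Interval("chr1", 50, 200)]]
        assert effective_genome_size(peaks) == 200

    def test_mean_over_datasets(self):
        a = [Interval("chr1", 0, 100)]
        b = [Interval("chr1", 0, 300)]
        assert effective_genome_size([a, b]) == 200

    def test_disjoint_peaks_sum(self):
        assert effective_genome_size([[Interval("c", 0, 10),
                                       Interval("c", 20, 30)]]) == 20

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            effective_genome_size([])


def _contact(total, fwd, rev, chrom2="chr1", a1=(0, 1000), a2=(5000, 6000)):
    return ChiaPetContact(Interval("chr1", *a1), Interval(chrom2, *a2),
                          total, fwd, rev)


class TestFilterContacts:
    def test_passing_contact_kept(self):
        assert filter_contacts([_contact(25, 12, 13)], RunConfig())

    def test_too_few_total_pairs_removed(self):
        assert not filter_contacts([_contact(19, 10, 9)], RunConfig())

    def test_direction_minimum_enforced(self):
        assert not filter_contacts([_contact(25, 18, 7)], RunConfig())

    def test_interchromosomal_removed(self):
        c = ChiaPetContact(Interval("chr1", 0, 1000),
                           Interval("chr2", 0, 1000), 30, 15, 15)
        assert not filter_contacts([c], RunConfig())

    def test_intersecting_anchors_removed(self):
        assert not filter_contacts([_contact(30, 15, 15, a2=(500, 1500))],
                                   RunConfig())


class TestContactSignificance:
    def test_observed_equals_expected_gives_p_one(self):
        assert contact_significance(10, 10.0) == pytest.approx(1.0)

    def test_strong_enrichment_significant(self):
        # X2 = (50-10)^2/10 = 160; 1-df upper tail = erfc(sqrt(160/2))
        p = contact_significance(50, 10.0)
        assert p == pytest.approx(math.erfc(math.sqrt(80)), rel=1e-10)
        assert p < 0.001

    def test_monotone_in_observed_above_expected(self):
        ps = [contact_significance(o, 10.0) for o in range(10, 60, 5)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_nonpositive_expected_is_error(self):
        with pytest.raises(ValueError):
            contact_significance(5, 0.0)


class TestDistalTargets:
    CFG = RunConfig()

    def test_planted_loop_recovered_depletion_and_overlap_excluded(self):
        gene = _gene("G1", g0=50_000)          # promoter around TSS 50,001
        snps = _snps(10_000, 49_500)           # second SNP window hits promoter
        loop = ChiaPetContact(Interval("chr1", 9_500, 10_400),
                              Interval("chr1", 49_700, 50_400), 30, 15, 15)
        df = assign_distal_targets(snps, [gene], [loop], self.CFG,
                                   effective_genome_bp=300_000.0)
        # only the distal SNP is linked; the window-overlapping one is excluded
        assert df.pos.tolist() == [10_000]
        assert df.gene_id.tolist() == ["G1"]
        assert (df.contact_p < self.CFG.contact_alpha).all()
        assert (df.contact_observed > df.contact_expected).all()

    def test_depleted_cell_not_reliable(self):
        gene = _gene("G1", g0=50_000)
        snps = _snps(10_000)
        loop = ChiaPetContact(Interval("chr1", 9_500, 10_400),
                              Interval("chr1", 49_700, 50_400), 30, 15, 15)
        # tiny effective genome -> huge expectation -> O << E
        df = assign_distal_targets(snps, [gene], [loop], self.CFG,
                                   effective_genome_bp=4000.0)
        assert df.empty

    def test_expected_count_formula(self):
        gene = _gene("G1", g0=50_000)
        snps = _snps(10_000)
        loop = ChiaPetContact(Interval("chr1", 9_500, 10_400),
                              Interval("chr1", 49_700, 50_400), 30, 15, 15)
        matrix = build_contact_matrix(snps, [gene], [loop], self.CFG, 300_000.0)
        (cell,) = matrix.counts.items()
        (i, j), observed = cell
        assert observed == 30
        len_i = len(matrix.snp_windows[i])
        len_j = len(matrix.promoters[j])
        assert matrix.expected(i, j) == pytest.approx(
            30 * (len_i / 300_000.0) * (len_j / 300_000.0) * 2)

    def test_zero_effective_genome_is_error(self):
        with pytest.raises(ValueError):
            build_contact_matrix(_snps(10), [_gene("G1")], [], self.CFG, 0.0)


class TestCombinedAssignment:
    def test_dedup_prefers_nearby_evidence(self):
        gene = _gene("G1", g0=50_000)
        snps = _snps(50_700)                   # intron of G1
        # an (artificial) loop linking the same SNP to the same gene
        loop = ChiaPetContact(Interval("chr1", 49_800, 50_500),
                              Interval("chr1", 50_300, 51_900), 30, 15, 15)
        df = assign_targets(snps, [gene], [loop], RunConfig(), 300_000.0)
        sub = df[(df.pos == 50_700) & (df.gene_id == "G1")]
        assert len(sub) == 1 and sub.relation.iloc[0] != "distal_chiapet"

    def test_relations_disjoint_by_construction(self, small_bundle):
        import regsnp_scout.io_formats as io
        from regsnp_scout.reference_model import read_gene_models
        out, manifest = small_bundle
        genes = read_gene_models(out / "genes.gtf")
        contacts = io.read_contacts(out / "chiapet_contacts.bedpe")
        g_eff = effective_genome_size([io.read_intervals(out / "polii_peaks.bed")])
        planted = pd.DataFrame([{"chrom": p.chrom, "pos": p.pos}
                                for p in manifest.planted_asymmetric])
        df = assign_targets(planted, genes, contacts, RunConfig(), g_eff)
        assert not df.duplicated(subset=["chrom", "pos", "gene_id"]).any()
        distal = df[df.relation == "distal_chiapet"]
        assert (distal.contact_p < RunConfig().contact_alpha).all()
        # every planted (site, designated target) link is recovered
        links = {(f"{r.chrom}:{r.pos}", r.gene_id)
                 for r in df.itertuples(index=False)}
        for p in manifest.planted_asymmetric:
            assert (p.site_id, p.target_gene) in links
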