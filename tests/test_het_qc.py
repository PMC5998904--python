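"""Heterozygous-SNP QC: exact binomial test, exclusion filters, calling."""

import numpy as np
import pytest

from regsnp_scout.config import RunConfig
from regsnp_scout.het_qc import (Observation, SiteCounts,
                                 binomial_two_sided,
                                 binomial_two_sided_balanced,
                                 call_het_snps, clustered_site_ids,
                                 filter_blacklist, filter_clustered,
                                 filter_indel_proximity)
from regsnp_scout.io_formats import Interval


def _site(chrom, pos, obs=None, ref="A", alt="G"):
    obs = obs or [Observation("S1", "ref", 5, 6), Observation("S1", "alt", 6, 5),
                  Observation("S2", "ref", 6, 5), Observation("S2", "alt", 5, 6)]
    return SiteCounts(chrom, pos, ref, alt, obs)


class TestBinomialTwoSided:
    def test_modal_symmetric_outcome(self):
        assert binomial_two_sided(5, 10, 0.5) == pytest.approx(1.0)

    def test_extreme_outcome_closed_form(self):
        # 2 * P(X = 10 | n=10, p=0.5) = 2 / 1024
        assert binomial_two_sided(10, 10, 0.5) == pytest.approx(2 / 1024)

    def test_tail_sum_closed_form(self):
        # 2 * P(X >= 7 | n=10) = 2 * (120 + 45 + 10 + 1) / 1024
        assert binomial_two_sided(7, 10, 0.5) == pytest.approx(2 * 176 / 1024)

    def test_symmetry_in_k(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            assert binomial_two_sided(k, n, 0.5) == pytest.approx(
                binomial_two_sided(n - k, n, 0.5))

    def test_vectorized_form_matches_scalar(self):
        rng = np.random.default_rng(6)
        ns = rng.integers(1, 300, size=200)
        ks = (rng.random(200) * (ns + 1)).astype(int)
        vec = binomial_two_sided_balanced(ks, ns)
        for k, n, p in zip(ks, ns, vec):
            assert p == pytest.approx(binomial_two_sided(int(k), int(n), 0.5),
                                      rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_two_sided(0, 0, 0.5)
        with pytest.raises(ValueError):
            binomial_two_sided(5, 3, 0.5)


class TestBlacklistFilter:
    def test_sex_mito_and_repeat_removal(self):
        sites = [_site("chrX", 100), _site("chrM", 50), _site("chr1", 150),
                 _site("chr1", 500)]
        kept = filter_blacklist(sites, [Interval("chr1", 100, 200)])
        assert [(s.chrom, s.pos) for s in kept] == [("chr1", 500)]


class TestIndelProximityFilter:
    # 1-based indel region 103..105 <-> 0-based [102, 105)
    REGION = Interval("chr1", 102, 105)

    @pytest.mark.parametrize("pos,kept", [
        (100, False),   # distance 3 <= 5
        (97, True),     # distance 6
        (104, False),   # inside, distance 0
        (110, False),   # distance 5, boundary inclusive
        (111, True),    # distance 6
    ])
    def test_distance_rule(self, pos, kept):
        out = filter_indel_proximity([_site("chr1", pos)], [self.REGION], 5)
        assert bool(out) is kept

    def test_commutes_with_blacklist(self):
        rng = np.random.default_rng(2)
        sites = [_site("chr1", int(p)) for p in
                 np.sort(rng.choice(10_000, 80, replace=False) + 1)]
        repeats = [Interval("chr1", 500, 900), Interval("chr1", 4000, 4400)]
        indels = [Interval("chr1", 2000, 2004), Interval("chr1", 7000, 7002)]
        a = filter_indel_proximity(filter_blacklist(sites, repeats), indels, 5)
        b = filter_blacklist(filter_indel_proximity(sites, indels, 5), repeats)
        assert [(s.chrom, s.pos) for s in a] == [(s.chrom, s.pos) for s in b]


class TestClusteredFilter:
    def test_triplet_within_window_all_removed(self):
        sites = [_site("chr1", p) for p in (100, 105, 109)]
        assert filter_clustered(sites, 10) == []

    def test_pair_plus_far_site_all_kept(self):
        sites = [_site("chr1", p) for p in (100, 105, 300)]
        assert len(filter_clustered(sites, 10)) == 3

    def test_single_site_kept(self):
        assert len(filter_clustered([_site("chr1", 1)], 10)) == 1

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(2, 300))
            positions = sorted(set(int(p) for p in rng.integers(1, 2000, n)))
            pairs = [("chr1", p) for p in positions]
            got = clustered_site_ids(pairs, 10)
            oracle = set()
            for c, p in pairs:
                neighbours = sum(1 for c2, q in pairs
                                 if q != p and abs(q - p) <= 10)
                if neighbours >= 2:
                    oracle.add((c, p))
            assert got == oracle


class TestCallHetSnps:
    def test_strong_imbalance_eliminated_as_unreliable_het(self):
        # pooled (40, 4): p ~ 2*P(X<=4 | 44) << 0.05 (allele support passes)
        obs = [Observation("S1", "ref", 20, 2), Observation("S1", "alt", 10, 1),
               Observation("S2", "ref", 5, 1), Observation("S2", "alt", 5, 0)]
        kept, removed = call_het_snps([_site("chr1", 10, obs)], RunConfig())
        assert kept == [] and removed["balance"] == 1

    def test_balanced_site_retained_with_metadata(self):
        obs = [Observation("S1", "ref", 3, 3), Observation("S1", "alt", 3, 2),
               Observation("S2", "ref", 0, 0), Observation("S2", "alt", 0, 0)]
        # second sample contributes no reads -> support failure
        kept, removed = call_het_snps([_site("chr1", 10, obs)], RunConfig())
        assert removed["sample_support"] == 1
        obs[2] = Observation("S2", "ref", 2, 2)
        kept, removed = call_het_snps([_site("chr1", 10, obs)], RunConfig())
        (h,) = kept
        assert h.site.pooled_ref_count == 8 and h.site.pooled_alt_count == 7
        assert h.balance_p > 0.05

    def test_low_coverage_eliminated(self):
        obs = [Observation("S1", "ref", 2, 2), Observation("S1", "alt", 2, 2),
               Observation("S2", "ref", 1, 0), Observation("S2", "alt", 0, 0)]
        kept, removed = call_het_snps([_site("chr1", 10, obs)], RunConfig())
        assert removed["coverage"] == 1

    def test_allele_support_rule(self):
        obs = [Observation("S1", "ref", 10, 1), Observation("S1", "alt", 10, 1),
               Observation("S2", "ref", 10, 0), Observation("S2", "alt", 10, 0)]
        kept, removed = call_het_snps([_site("chr1", 10, obs)], RunConfig())
        assert removed["allele_support"] == 1

    def test_each_removal_has_exactly_one_reason(self):
        sites = [_site("chrX", 5), _site("chr1", 100), _site("chr1", 105),
                 _site("chr1", 109), _site("chr1", 500)]
        kept, removed = call_het_snps(sites, RunConfig())
        assert sum(removed.values()) + len(kept) == len(sites)
        assert removed["blacklist"] == 1 and removed["clustered"] == 3

    def test_retained_set_is_subset_of_input(self, small_bundle):
        from regsnp_scout import io_formats as io
        from regsnp_scout.het_qc import assemble_sites
        out, manifest = small_bundle
        variants, indels = io.read_variants(out / "variants.vcf")
        counts = io.read_allele_counts(out / "chip_allele_counts.tsv")
        sites = assemble_sites(variants, counts)
        repeats = io.read_intervals(out / "repeats.bed")
        kept, removed = call_het_snps(sites, RunConfig(), repeats, indels)
        in_ids = {s.site_id for s in sites}
        assert {h.site_id for h in kept} <= in_ids
        assert len(kept) + sum(removed.values()) == len(sites)
        # planted QC-exercise sites are removed for their designed reasons
        for cat, expected_reason in [("blacklist_chrom", "blacklist"),
                                     ("blacklist_repeat", "blacklist"),
                                     ("clustered", "clustered"),
                                     ("indel_proximity", "indel_proximity"),
                                     ("low_coverage", "coverage"),
                                     ("balance_artifact", "balance")]:
            kept_ids = {h.site_id for h in kept}
            for sid in manifest.qc_exercise[cat]:
                assert sid not in kept_ids, (cat, sid)
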