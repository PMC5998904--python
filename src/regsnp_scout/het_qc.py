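"""Heterozygous-SNP calling from allele-count evidence, with QC filters.

The funnel, in fixed order:

1. blacklist    -- drop sites on sex chromosomes, mitochondrial DNA or
                   inside repeat regions;
2. clustered    -- drop sites with >= 2 other sites within 10 bp
                   (evaluated on the pre-filter site set, removals applied
                   simultaneously, never iteratively);
3. indel        -- drop sites within 5 bp of an insertion/deletion region;
4. support      -- pooled coverage >= 10, >= 3 reads per allele, seen in
                   >= 2 samples and under both alignment references;
5. balance      -- drop sites whose pooled ref/alt counts differ
                   significantly from 1:1 (exact binomial, p < 0.05):
                   strong imbalance across all evidence marks an
                   unreliable heterozygote (or a somatic/genotyping
                   artefact), whereas per-experiment imbalance -- the
                   allele-specific binding signal proper -- is tested
                   later on bias-corrected counts.

Every removal carries exactly one reason: the first failing filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .config import RunConfig
from .io_formats import Interval, VariantRecord

log = logging.getLogger("regsnp_scout")

FILTER_ORDER = ("blacklist", "clustered", "indel_proximity",
                "coverage", "allele_support", "sample_support", "balance")

DEFAULT_SEX_CHROMS = ("chrX", "chrY", "X", "Y")
DEFAULT_MITO_NAMES = ("chrM", "chrMT", "M", "MT")


@dataclass(frozen=True)
class Observation:
    sample_id: str
    alignment_ref: str               # 'ref' or 'alt'
    ref_count: int
    alt_count: int


@dataclass
class SiteCounts:
    """Allele-count evidence for one candidate heterozygous site."""
    chrom: str
    pos: int                         # 1-based
    ref_allele: str
    alt_allele: str
    observations: List[Observation]
    rsid: str | None = None

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def pooled_ref_count(self) -> int:
        return sum(o.ref_count for o in self.observations)

    @property
    def pooled_alt_count(self) -> int:
        return sum(o.alt_count for o in self.observations)

    @property
    def n_supporting_samples(self) -> int:
        return len({o.sample_id for o in self.observations
                    if o.ref_count + o.alt_count > 0})

    @property
    def n_supporting_references(self) -> int:
        return len({o.alignment_ref for o in self.observations
                    if o.ref_count + o.alt_count > 0})


@dataclass
class HetSNP:
    """A QC-passed heterozygous site."""
    site: SiteCounts
    balance_p: float
    qc_flags: Set[str] = field(default_factory=set)

    @property
    def site_id(self) -> str:
        return self.site.site_id


def assemble_sites(variants: Sequence[VariantRecord],
                   counts: pd.DataFrame) -> List[SiteCounts]:
    """Join VCF SNVs with the allele-count table into SiteCounts."""
    grouped: Dict[Tuple[str, int], List[Observation]] = {}
    for row in counts.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        grouped.setdefault(key, []).append(
            Observation(str(row.sample_id), str(row.alignment_ref),
                        int(row.ref_count), int(row.alt_count)))
    sites = []
    for v in variants:
        obs = grouped.get((v.chrom, v.pos))
        if obs:
            sites.append(SiteCounts(v.chrom, v.pos, v.ref, v.alt, obs, v.rsid))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method).

    Sum of probabilities of all outcomes whose point probability does not
    exceed that of ``k`` under Binomial(n, p0); for p0 = 0.5 this equals
    2*min(P(X<=k), P(X>=k)) capped at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def binomial_two_sided_balanced(k, n):
    """Vectorized exact two-sided p-values against p0 = 0.5.

    By the symmetry of Binomial(n, 0.5) the minimum-likelihood two-sided p
    equals P(X <= min(k, n-k)) + P(X >= max(k, n-k)), capped at 1; this is
    the array form of :func:`binomial_two_sided` used on hot paths.
    """
    from scipy.stats import binom
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("need n >= 1 and 0 <= k <= n")
    lo = np.minimum(k, n - k)
    hi = np.maximum(k, n - k)
    p = binom.cdf(lo, n, 0.5) + binom.sf(hi - 1, n, 0.5)
    return np.minimum(p, 1.0)


def filter_blacklist(sites: Sequence[SiteCounts],
                     repeat_intervals: Sequence[Interval] = (),
                     sex_chroms: Sequence[str] = DEFAULT_SEX_CHROMS,
                     mito_names: Sequence[str] = DEFAULT_MITO_NAMES,
                     ) -> List[SiteCounts]:
    """Remove sites on sex/mito chromosomes or inside repeat regions."""
    bad_chroms = set(sex_chroms) | set(mito_names)
    from .reference_model import OtfrIndex
    repeats = OtfrIndex(repeat_intervals) if repeat_intervals else None
    kept = []
    for s in sites:
        if s.chrom in bad_chroms:
            continue
        if repeats is not None and repeats.contains(s.chrom, s.pos):
            continue
        kept.append(s)
    return kept


def _blacklist_fails(site: SiteCounts, repeats, bad_chroms: Set[str]) -> bool:
    if site.chrom in bad_chroms:
        return True
    return repeats is not None and repeats.contains(site.chrom, site.pos)


def clustered_site_ids(positions: Sequence[Tuple[str, int]],
                       window_bp: int) -> Set[Tuple[str, int]]:
    """Sites with >= 2 other sites within ``window_bp`` (inclusive, same chrom).

    Evaluated on the full input set; the removal is simultaneous.
    """
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    clustered: Set[Tuple[str, int]] = set()
    for chrom, poss in by_chrom.items():
        poss = sorted(poss)
        import bisect as _b
        for p in poss:
            lo = _b.bisect_left(poss, p - window_bp)
            hi = _b.bisect_right(poss, p + window_bp)
            if hi - lo - 1 >= 2:     # exclude the site itself
                clustered.add((chrom, p))
    return clustered


def filter_clustered(sites: Sequence[SiteCounts], window_bp: int,
                     ) -> List[SiteCounts]:
    bad = clustered_site_ids([(s.chrom, s.pos) for s in sites], window_bp)
    return [s for s in sites if (s.chrom, s.pos) not in bad]


def _distance_to_region(pos: int, region: Interval) -> int:
    """bp distance from a 1-based position to a 0-based half-open region.

    0 means inside; otherwise gap to the nearest covered base.
    """
    coord = pos - 1
    if region.start <= coord < region.end:
        return 0
    if coord < region.start:
        return region.start - coord
    return coord - (region.end - 1)


def filter_indel_proximity(sites: Sequence[SiteCounts],
                           indel_regions: Sequence[Interval],
                           max_bp: int) -> List[SiteCounts]:
    """Remove sites within ``max_bp`` of any insertion/deletion region."""
    if max_bp < 0:
        raise ValueError("max_bp must be >= 0")
    by_chrom: Dict[str, List[Interval]] = {}
    for iv in indel_regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for s in sites:
        near = any(_distance_to_region(s.pos, iv) <= max_bp
                   for iv in by_chrom.get(s.chrom, ()))
        if not near:
            kept.append(s)
    return kept


def _support_failure(site: SiteCounts, config: RunConfig) -> str | None:
    if site.pooled_ref_count + site.pooled_alt_count < config.min_site_coverage:
        return "coverage"
    if min(site.pooled_ref_count, site.pooled_alt_count) < config.min_reads_per_allele:
        return "allele_support"
    if (site.n_supporting_samples < config.min_supporting_samples
            or site.n_supporting_references < 2):
        return "sample_support"
    return None


def call_het_snps(sites: Sequence[SiteCounts], config: RunConfig,
                  repeat_intervals: Sequence[Interval] = (),
                  indel_regions: Sequence[Interval] = (),
                  sex_chroms: Sequence[str] = DEFAULT_SEX_CHROMS,
                  mito_names: Sequence[str] = DEFAULT_MITO_NAMES,
                  ) -> Tuple[List[HetSNP], Counter]:
    """Run the full QC funnel; returns retained HetSNPs and removal reasons.

    Each removed site is counted under its first failing filter in the
    fixed order blacklist -> clustered -> indel -> support -> balance.
    """
    from .reference_model import OtfrIndex
    repeats = OtfrIndex(repeat_intervals) if repeat_intervals else None
    bad_chroms = set(sex_chroms) | set(mito_names)
    clustered = clustered_site_ids([(s.chrom, s.pos) for s in sites],
                                   config.cluster_window_bp)
    indels_by_chrom: Dict[str, List[Interval]] = {}
    for iv in indel_regions:
        indels_by_chrom.setdefault(iv.chrom, []).append(iv)

    removed: Counter = Counter()
    survivors: List[SiteCounts] = []
    for s in sites:
        if _blacklist_fails(s, repeats, bad_chroms):
            removed["blacklist"] += 1
            continue
        if (s.chrom, s.pos) in clustered:
            removed["clustered"] += 1
            continue
        if any(_distance_to_region(s.pos, iv) <= config.indel_exclusion_bp
               for iv in indels_by_chrom.get(s.chrom, ())):
            removed["indel_proximity"] += 1
            continue
        reason = _support_failure(s, config)
        if reason is not None:
            removed[reason] += 1
            continue
        survivors.append(s)

    # balance filter over the whole surviving family (optionally BH-adjusted)
    kept: List[HetSNP] = []
    if survivors:
        ks = np.array([s.pooled_ref_count for s in survivors])
        ns = np.array([s.pooled_ref_count + s.pooled_alt_count
                       for s in survivors])
        raw = binomial_two_sided_balanced(ks, ns)
        if config.het_balance_use_adjusted:
            from .asb_detection import benjamini_hochberg
            decisive = np.array(benjamini_hochberg(list(raw)))
        else:
            decisive = raw
        for s, p_raw, p_dec in zip(survivors, raw, decisive):
            if p_dec < config.het_balance_alpha:
                removed["balance"] += 1
            else:
                kept.append(HetSNP(site=s, balance_p=float(p_raw)))
    for stage in FILTER_ORDER:
        if removed.get(stage):
            log.info("het_qc %s: removed %d of %d", stage, removed[stage], len(sites))
    return kept, removed


def het_snps_to_frame(het_snps: Sequence[HetSNP]) -> pd.DataFrame:
    """Tabular view of retained het SNPs for the stage TSV output."""
    rows = [{
        "chrom": h.site.chrom, "pos": h.site.pos,
        "ref": h.site.ref_allele, "alt": h.site.alt_allele,
        "rsid": h.site.rsid or ".",
        "pooled_ref_count": h.site.pooled_ref_count,
        "pooled_alt_count": h.site.pooled_alt_count,
        "n_samples": h.site.n_supporting_samples,
        "balance_p": h.balance_p,
    } for h in het_snps]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "rsid",
                                       "pooled_ref_count", "pooled_alt_count",
                                       "n_samples", "balance_p"])
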