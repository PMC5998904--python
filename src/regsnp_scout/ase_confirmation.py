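"""Allele-specific expression confirmation: promoting asymmetric SNPs to rSNPs.

A targeted gene's expression imbalance is measured at exonic heterozygous
marker SNPs covered by at least ``min_rna_reads`` RNA-seq reads.  A marker
shows allele-specific expression when its allelic ratio exceeds the fold
threshold (default 1.5, strict, in either direction) AND the ratio differs
significantly from 1:1 -- exact binomial test against 0.5 by default, or
Fisher's exact test of RNA counts against the site's pooled DNA counts.
An asymmetric SNP whose targeted gene has at least one such marker is a
regulatory SNP (rSNP); variants without an rsID are displayed as
``chrN:pos``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import fisher_exact

from .config import RunConfig
from .asb_detection import benjamini_hochberg
from .het_qc import binomial_two_sided
from .reference_model import GeneModel


@dataclass(frozen=True)
class MarkerSNP:
    chrom: str
    pos: int                 # 1-based
    gene_id: str
    rna_ref_count: int
    rna_alt_count: int
    is_self_marker: bool = False   # the asymmetric SNP measuring itself

    @property
    def total(self) -> int:
        return self.rna_ref_count + self.rna_alt_count


def _pool_rna_counts(rna_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum RNA allele counts over samples per (chrom, pos)."""
    return (rna_counts.groupby(["chrom", "pos"], as_index=False)
            [["ref_count", "alt_count"]].sum())


def select_markers(targets: pd.DataFrame, genes: Sequence[GeneModel],
                   rna_counts: pd.DataFrame, config: RunConfig,
                   ) -> List[MarkerSNP]:
    """Choose ASE markers for the targeted genes.

    Two kinds of marker qualify, both needing >= ``min_rna_reads`` total
    RNA reads at the position:

    * heterozygous sites inside a targeted gene's coding (CDS) intervals;
    * the asymmetric SNP itself when its proximal relation is promoter or
      UTR, i.e. it sits in transcribed or promoter-proximal sequence whose
      reads sample its own alleles.
    """
    pooled = _pool_rna_counts(rna_counts)
    lookup: Dict[Tuple[str, int], Tuple[int, int]] = {
        (str(r.chrom), int(r.pos)): (int(r.ref_count), int(r.alt_count))
        for r in pooled.itertuples(index=False)}
    gene_by_id = {g.gene_id: g for g in genes}
    target_gene_ids = sorted(set(targets["gene_id"]))

    markers: List[MarkerSNP] = []
    seen: set = set()
    for gene_id in target_gene_ids:
        gene = gene_by_id.get(gene_id)
        if gene is None:
            continue
        for (chrom, pos), (rc, ac) in lookup.items():
            if chrom != gene.chrom or rc + ac < config.min_rna_reads:
                continue
            coord = pos - 1
            if any(iv.start <= coord < iv.end for iv in gene.cds):
                key = (chrom, pos, gene_id)
                if key not in seen:
                    seen.add(key)
                    markers.append(MarkerSNP(chrom, pos, gene_id, rc, ac))
    # asymmetric SNPs in promoters/UTRs act as their own markers
    self_rel = targets["relation"].isin(["promoter", "utr5", "utr3"])
    for row in targets[self_rel].itertuples(index=False):
        counts = lookup.get((str(row.chrom), int(row.pos)))
        if counts is None or sum(counts) < config.min_rna_reads:
            continue
        key = (str(row.chrom), int(row.pos), str(row.gene_id))
        if key not in seen:
            seen.add(key)
            markers.append(MarkerSNP(str(row.chrom), int(row.pos),
                                     str(row.gene_id), counts[0], counts[1],
                                     is_self_marker=True))
    markers.sort(key=lambda m: (m.chrom, m.pos, m.gene_id))
    return markers


def _raw_p(marker: MarkerSNP, config: RunConfig,
           dna_counts: Optional[Dict[Tuple[str, int], Tuple[int, int]]],
           ) -> float:
    if config.ase_test == "binomial":
        return binomial_two_sided(marker.rna_ref_count, marker.total, 0.5)
    dna = (dna_counts or {}).get((marker.chrom, marker.pos))
    if dna is None:
        raise ValueError(
            f"fisher ASE test needs DNA counts for {marker.chrom}:{marker.pos}")
    table = [[marker.rna_ref_count, marker.rna_alt_count], [dna[0], dna[1]]]
    return float(fisher_exact(table)[1])


def ase_test(markers: Sequence[MarkerSNP], config: RunConfig,
             dna_counts: Optional[Dict[Tuple[str, int], Tuple[int, int]]] = None,
             ) -> pd.DataFrame:
    """Test every marker; BH-adjust across markers; apply ratio and p gates.

    The allelic ratio is ref/alt (infinite when alt is 0, which remains
    flag-eligible).  ``flagged`` requires the ratio strictly outside
    [1/threshold, threshold] and the configured p-value at or below
    ``ase_alpha``.
    """
    rows = []
    for m in markers:
        ratio = (m.rna_ref_count / m.rna_alt_count if m.rna_alt_count
                 else float("inf"))
        rows.append({"chrom": m.chrom, "pos": m.pos, "gene_id": m.gene_id,
                     "rna_ref_count": m.rna_ref_count,
                     "rna_alt_count": m.rna_alt_count,
                     "is_self_marker": m.is_self_marker,
                     "allele_ratio": ratio,
                     "raw_p": _raw_p(m, config, dna_counts)})
    columns = ["chrom", "pos", "gene_id", "rna_ref_count", "rna_alt_count",
               "is_self_marker", "allele_ratio", "raw_p", "adjusted_p",
               "flagged"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["adjusted_p"] = benjamini_hochberg(df["raw_p"].tolist())
    t = config.ase_ratio_threshold
    ratio_gate = (df["allele_ratio"] > t) | (df["allele_ratio"] < 1.0 / t)
    p = df["adjusted_p"] if config.ase_use_adjusted_p else df["raw_p"]
    df["flagged"] = ratio_gate & (p <= config.ase_alpha)
    return df[columns]


def promote_to_rsnp(asnps: pd.DataFrame, targets: pd.DataFrame,
                    ase_results: pd.DataFrame) -> pd.DataFrame:
    """Asymmetric SNPs with >= 1 targeted gene showing flagged ASE.

    Returns one row per confirmed (rSNP, gene) pair with the display_id
    (rsID when annotated, else chrN:pos) and the best supporting marker.
    """
    columns = ["display_id", "chrom", "pos", "rsid", "gene_id",
               "marker_chrom", "marker_pos", "marker_ratio", "marker_raw_p"]
    flagged = ase_results[ase_results["flagged"]]
    if flagged.empty or targets.empty or asnps.empty:
        return pd.DataFrame(columns=columns)
    best_by_gene = (flagged.sort_values(["raw_p", "chrom", "pos"])
                    .groupby("gene_id", as_index=False).first())
    gene_info = {str(r.gene_id): r for r in best_by_gene.itertuples(index=False)}
    rsid_by_site = {(str(r.chrom), int(r.pos)): str(r.rsid)
                    for r in asnps.itertuples(index=False)}
    rows = []
    for t in targets.itertuples(index=False):
        key = (str(t.chrom), int(t.pos))
        if key not in rsid_by_site:
            continue
        m = gene_info.get(str(t.gene_id))
        if m is None:
            continue
        rsid = rsid_by_site[key]
        display = rsid if rsid not in (".", "", "None") else f"{key[0]}:{key[1]}"
        rows.append({"display_id": display, "chrom": key[0], "pos": key[1],
                     "rsid": rsid, "gene_id": str(t.gene_id),
                     "marker_chrom": str(m.chrom), "marker_pos": int(m.pos),
                     "marker_ratio": float(m.allele_ratio),
                     "marker_raw_p": float(m.raw_p)})
    df = pd.DataFrame(rows, columns=columns)
    return (df.drop_duplicates(subset=["chrom", "pos", "gene_id"])
              .sort_values(["chrom", "pos", "gene_id"])
              .reset_index(drop=True))
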