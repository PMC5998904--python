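"""Target-gene assignment for asymmetric SNPs: proximal and ChIA-PET distal.

Proximal targets come from gene-model membership: a SNP inside a gene's
promoter (+/-1.8 kb of the TSS), intron or UTR is assigned to that gene.
Distal targets come from RNA Pol II ChIA-PET contacts: a contact matrix is
built over +/-1 kb windows around the asymmetric SNPs (rows) and gene
promoters (columns); observed pair counts in a cell are compared with a
random-ligation expectation

    E_ij = T * (len_i / G_eff) * (len_j / G_eff) * 2,

where T is the total pair count over retained intrachromosomal contacts
and G_eff the effective genome size (mean merged Pol II peak area).  A
cell is a reliable contact when the 1-df Pearson goodness-of-fit test
gives p below ``contact_alpha`` with enrichment (O > E).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import chi2

from .config import RunConfig
from .io_formats import ChiaPetContact, Interval, total_length
from .reference_model import GeneModel, classify_position, promoter_region


def assign_nearby_targets(asnps: pd.DataFrame, genes: Sequence[GeneModel],
                          config: RunConfig,
                          chrom_lengths: Optional[Dict[str, int]] = None,
                          ) -> pd.DataFrame:
    """Proximal assignments: one row per (SNP, gene, relation) membership."""
    rows = []
    for snp in asnps.itertuples(index=False):
        for gene_id, relation in sorted(
                classify_position(str(snp.chrom), int(snp.pos), genes,
                                  config.promoter_flank_bp, chrom_lengths)):
            rows.append({"chrom": snp.chrom, "pos": snp.pos,
                         "gene_id": gene_id, "relation": relation,
                         "contact_observed": float("nan"),
                         "contact_expected": float("nan"),
                         "contact_p": float("nan")})
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "relation",
                                       "contact_observed", "contact_expected",
                                       "contact_p"])


def effective_genome_size(peak_sets: Sequence[Sequence[Interval]]) -> float:
    """Mean merged Pol II peak length (bp) over datasets."""
    if not peak_sets:
        raise ValueError("at least one Pol II peak set is required")
    return sum(total_length(p) for p in peak_sets) / len(peak_sets)


def filter_contacts(contacts: Sequence[ChiaPetContact], config: RunConfig,
                    ) -> List[ChiaPetContact]:
    """Keep intrachromosomal contacts with disjoint anchors and enough pairs.

    Requires total pairs >= ``chiapet_min_pairs`` and at least
    ``chiapet_min_per_direction`` pairs in each read orientation.
    """
    kept = []
    for c in contacts:
        if not c.intrachromosomal:
            continue
        if c.anchor1.overlaps(c.anchor2):
            continue
        if c.total_pairs < config.chiapet_min_pairs:
            continue
        if min(c.pairs_forward, c.pairs_reverse) < config.chiapet_min_per_direction:
            continue
        kept.append(c)
    return kept


def contact_significance(observed: int, expected: float) -> float:
    """Pearson 1-df goodness-of-fit p for an observed vs expected pair count."""
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    x2 = (observed - expected) ** 2 / expected
    return float(chi2.sf(x2, df=1))


@dataclass
class ContactMatrix:
    """Sparse SNP-window x promoter contact matrix with its null model."""
    snp_windows: List[Interval]              # row regions, named chrom:pos
    promoters: List[Interval]                # column regions, named gene_id
    counts: Dict[Tuple[int, int], int]       # (row, col) -> observed pairs
    total_pairs: int                         # T over retained contacts
    effective_genome_bp: float

    def expected(self, i: int, j: int) -> float:
        li = len(self.snp_windows[i])
        lj = len(self.promoters[j])
        g = self.effective_genome_bp
        return self.total_pairs * (li / g) * (lj / g) * 2.0


def build_contact_matrix(asnps: pd.DataFrame, genes: Sequence[GeneModel],
                         contacts: Sequence[ChiaPetContact],
                         config: RunConfig, effective_genome_bp: float,
                         chrom_lengths: Optional[Dict[str, int]] = None,
                         ) -> ContactMatrix:
    """Accumulate retained contacts into SNP-window x promoter cells.

    A contact contributes its total pair count to cell (i, j) when one
    anchor overlaps SNP window i and the other overlaps promoter j.
    Interchromosomal cells cannot arise (contacts are intrachromosomal
    after filtering); cells whose SNP window intersects the promoter are
    dropped later by the assignment step.
    """
    if effective_genome_bp <= 0:
        raise ValueError("effective genome size must be > 0")
    windows = []
    for snp in asnps.itertuples(index=False):
        pos, w = int(snp.pos), config.snp_window_bp
        windows.append(Interval(str(snp.chrom), max(0, pos - 1 - w), pos + w,
                                f"{snp.chrom}:{pos}"))
    promoters = [promoter_region(g, config.promoter_flank_bp,
                                 (chrom_lengths or {}).get(g.chrom))
                 for g in genes]
    retained = filter_contacts(contacts, config)
    counts: Dict[Tuple[int, int], int] = {}
    total = sum(c.total_pairs for c in retained)
    for c in retained:
        for a, b in ((c.anchor1, c.anchor2), (c.anchor2, c.anchor1)):
            hit_rows = [i for i, wv in enumerate(windows) if wv.overlaps(a)]
            if not hit_rows:
                continue
            hit_cols = [j for j, pv in enumerate(promoters) if pv.overlaps(b)]
            for i in hit_rows:
                for j in hit_cols:
                    counts[(i, j)] = counts.get((i, j), 0) + c.total_pairs
    return ContactMatrix(windows, promoters, counts, total, effective_genome_bp)


def assign_distal_targets(asnps: pd.DataFrame, genes: Sequence[GeneModel],
                          contacts: Sequence[ChiaPetContact],
                          config: RunConfig, effective_genome_bp: float,
                          chrom_lengths: Optional[Dict[str, int]] = None,
                          ) -> pd.DataFrame:
    """Distal assignments from reliable (enriched, significant) cells.

    Cells whose SNP window intersects the gene's promoter are excluded --
    such pairs are proximal by construction and their self-ligation signal
    would be spurious.
    """
    matrix = build_contact_matrix(asnps, genes, contacts, config,
                                  effective_genome_bp, chrom_lengths)
    cells = []
    for (i, j), observed in sorted(matrix.counts.items()):
        window, promoter = matrix.snp_windows[i], matrix.promoters[j]
        if window.overlaps(promoter):
            continue
        expected = matrix.expected(i, j)
        cells.append((i, j, observed, expected,
                      contact_significance(observed, expected)))
    if config.contact_use_adjusted_p and cells:
        from .asb_detection import benjamini_hochberg
        adj = benjamini_hochberg([c[4] for c in cells])
        cells = [(i, j, o, e, p_adj)
                 for (i, j, o, e, _), p_adj in zip(cells, adj)]
    rows = []
    for i, j, observed, expected, p in cells:
        if p < config.contact_alpha and observed > expected:
            window, promoter = matrix.snp_windows[i], matrix.promoters[j]
            chrom, pos = window.name.split(":")
            rows.append({"chrom": chrom, "pos": int(pos),
                         "gene_id": promoter.name, "relation": "distal_chiapet",
                         "contact_observed": observed,
                         "contact_expected": expected, "contact_p": p})
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "relation",
                                       "contact_observed", "contact_expected",
                                       "contact_p"])


def assign_targets(asnps: pd.DataFrame, genes: Sequence[GeneModel],
                   contacts: Sequence[ChiaPetContact], config: RunConfig,
                   effective_genome_bp: Optional[float] = None,
                   chrom_lengths: Optional[Dict[str, int]] = None,
                   ) -> pd.DataFrame:
    """Union of proximal and distal assignments.

    Deduplicated by (SNP, gene): when both kinds of evidence link the same
    pair, the proximal relation is kept (it is the stronger claim).
    """
    nearby = assign_nearby_targets(asnps, genes, config, chrom_lengths)
    if contacts and effective_genome_bp:
        distal = assign_distal_targets(asnps, genes, contacts, config,
                                       effective_genome_bp, chrom_lengths)
    else:
        distal = pd.DataFrame(columns=nearby.columns)
    frames = [f for f in (nearby, distal) if not f.empty]
    if not frames:
        return nearby
    combined = pd.concat(frames, ignore_index=True)
    combined["_distal"] = (combined["relation"] == "distal_chiapet").astype(int)
    combined = (combined.sort_values(["chrom", "pos", "gene_id", "_distal",
                                      "relation"])
                        .drop_duplicates(subset=["chrom", "pos", "gene_id"],
                                         keep="first")
                        .drop(columns="_distal")
                        .reset_index(drop=True))
    return combined
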