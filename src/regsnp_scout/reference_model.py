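"""Gene-model geometry, OTFR membership and alternative-reference building.

One canonical transcript (the longest) represents each gene.  Promoters
span a symmetric window around the TSS (default +/-1.8 kb), introns are
the gaps between consecutive exons, and UTRs come from the annotation.
Point positions are 1-based; stored gene-part intervals are 0-based
half-open (see :mod:`regsnp_scout.io_formats`).

The alternative reference -- the genome with every heterozygous SNP's
alternate allele substituted -- is the standard control for reference
mapping bias: reads are aligned once to each genome and the per-allele
counts are combined downstream.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pyranges as pr

from .io_formats import Interval, PathLike, pos_to_interval_coord

PROXIMAL_RELATIONS = ("promoter", "intron", "utr5", "utr3")


@dataclass
class GeneModel:
    """A gene reduced to its canonical transcript's geometry."""
    gene_id: str
    chrom: str
    strand: str                      # '+' or '-'
    exons: List[Interval]            # sorted, non-overlapping
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model without exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        """1-based transcription start site (strand-appropriate end)."""
        if self.strand == "+":
            return self.exons[0].start + 1
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end,
                        self.gene_id)

    @property
    def introns(self) -> List[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.chrom, a.end, b.start))
        return out


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Load gene models from GTF/GFF, one canonical (longest) transcript each."""
    df = pr.read_gtf(str(path)).df
    if "transcript_id" not in df.columns:
        df["transcript_id"] = df["gene_id"]
    feats = df[df["Feature"].isin(["exon", "CDS", "five_prime_utr",
                                   "three_prime_utr"])].copy()
    genes: List[GeneModel] = []
    for gene_id, gdf in feats.groupby("gene_id", sort=True):
        # canonical transcript: longest exonic span
        best_tx, best_len = None, -1
        for tx, tdf in gdf[gdf["Feature"] == "exon"].groupby("transcript_id"):
            length = int((tdf["End"] - tdf["Start"]).sum())
            if length > best_len or (length == best_len and str(tx) < str(best_tx)):
                best_tx, best_len = tx, length
        tdf = gdf[gdf["transcript_id"] == best_tx]
        chrom = str(tdf["Chromosome"].iloc[0])
        strand = str(tdf["Strand"].iloc[0])

        def ivs(feature: str) -> List[Interval]:
            sub = tdf[tdf["Feature"] == feature]
            return [Interval(chrom, int(s), int(e))
                    for s, e in zip(sub["Start"], sub["End"])]

        genes.append(GeneModel(gene_id=str(gene_id), chrom=chrom, strand=strand,
                               exons=ivs("exon"), cds=ivs("CDS"),
                               utr5=ivs("five_prime_utr"),
                               utr3=ivs("three_prime_utr")))
    return genes


def promoter_region(gene: GeneModel, flank_bp: int,
                    chrom_length: Optional[int] = None) -> Interval:
    """Symmetric promoter window around the TSS, clamped at chromosome bounds.

    Covers 1-based positions [tss - flank_bp, tss + flank_bp] inclusive;
    strand does not change the span.  Returned 0-based half-open.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    if gene.tss < 1 or (chrom_length is not None and gene.tss > chrom_length):
        raise ValueError(f"{gene.gene_id}: TSS {gene.tss} outside chromosome")
    lo_pos = max(1, gene.tss - flank_bp)
    hi_pos = gene.tss + flank_bp
    if chrom_length is not None:
        hi_pos = min(hi_pos, chrom_length)
    return Interval(gene.chrom, lo_pos - 1, hi_pos, gene.gene_id)


def classify_position(chrom: str, pos: int, genes: Sequence[GeneModel],
                      flank_bp: int,
                      chrom_lengths: Optional[Dict[str, int]] = None,
                      ) -> Set[Tuple[str, str]]:
    """All (gene_id, relation) memberships of a 1-based position.

    Relations are promoter / intron / utr5 / utr3; a position may hit
    several genes and several relations.  Positions only inside CDS exons
    (or intergenic) yield the empty set.
    """
    coord = pos_to_interval_coord(pos)
    hits: Set[Tuple[str, str]] = set()
    for gene in genes:
        if gene.chrom != chrom:
            continue
        clen = (chrom_lengths or {}).get(chrom)
        if promoter_region(gene, flank_bp, clen).contains_pos(chrom, pos):
            hits.add((gene.gene_id, "promoter"))
        for iv in gene.introns:
            if iv.start <= coord < iv.end:
                hits.add((gene.gene_id, "intron"))
        for iv in gene.utr5:
            if iv.start <= coord < iv.end:
                hits.add((gene.gene_id, "utr5"))
        for iv in gene.utr3:
            if iv.start <= coord < iv.end:
                hits.add((gene.gene_id, "utr3"))
    return hits


class OtfrIndex:
    """Sorted-interval index for OTFR membership of point positions.

    OTFRs may not overlap each other for the bisect shortcut to be exact;
    overlapping inputs are merged on construction.
    """

    def __init__(self, otfrs: Sequence[Interval]):
        from .io_formats import merge_intervals
        self._by_chrom: Dict[str, Tuple[List[int], List[int]]] = {}
        merged = merge_intervals(otfrs)
        for iv in merged:
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position falls in some OTFR."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        coord = pos_to_interval_coord(pos)
        i = bisect.bisect_right(starts, coord) - 1
        return i >= 0 and coord < ends[i]


def in_otfr(chrom: str, pos: int, otfrs: Sequence[Interval]) -> bool:
    """Convenience wrapper over :class:`OtfrIndex` for a single query."""
    return OtfrIndex(otfrs).contains(chrom, pos)


def make_alternative_reference(sequences: Dict[str, str],
                               snps: Sequence[Tuple[str, int, str, str]],
                               ) -> Dict[str, str]:
    """Substitute alternate alleles into the reference sequences.

    ``snps`` are (chrom, 1-based pos, ref_allele, alt_allele).  Every
    ref_allele must match the base already present; mismatches are
    collected and reported together.  Applying the operation twice with
    ref/alt swapped restores the original sequences.
    """
    out = {name: bytearray(seq.upper(), "ascii") for name, seq in sequences.items()}
    mismatches = []
    for chrom, pos, ref, alt in snps:
        if chrom not in out:
            mismatches.append(f"{chrom}:{pos} unknown chromosome")
            continue
        seq = out[chrom]
        if not 1 <= pos <= len(seq):
            mismatches.append(f"{chrom}:{pos} outside sequence")
            continue
        if len(ref) != 1 or len(alt) != 1:
            mismatches.append(f"{chrom}:{pos} non-SNV alleles {ref}>{alt}")
            continue
        if chr(seq[pos - 1]) != ref.upper():
            mismatches.append(
                f"{chrom}:{pos} expected {ref.upper()} found {chr(seq[pos - 1])}")
            continue
        seq[pos - 1] = ord(alt.upper())
    if mismatches:
        raise ValueError("reference mismatch at: " + "; ".join(mismatches))
    return {name: seq.decode("ascii") for name, seq in out.items()}


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
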