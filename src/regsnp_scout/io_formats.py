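"""Readers and writers for every external format the pipeline touches.

Conventions: point variants (SNPs, markers, GWAS indexes) are 1-based, as
in VCF; genomic intervals (OTFRs, repeats, peaks, anchors, gene parts) are
0-based half-open, as in BED.  ``pos_to_interval_coord`` /
``interval_coord_to_pos`` are the (inverse) converters between the two.

Tables are plain TSV with headers so every stage output is independently
replayable and diffable:

* allele counts: ``sample_id  alignment_ref  chrom  pos  ref_count  alt_count``
* RNA counts:    ``sample_id  chrom  pos  ref_count  alt_count``
* GWAS catalog:  ``rsid  chrom  pos  trait  maf``
* MAF table:     ``rsid  chrom  pos  maf``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
import pysam

log = logging.getLogger("regsnp_scout")

PathLike = Union[str, Path]

ALLELE_COUNT_COLUMNS = ["sample_id", "alignment_ref", "chrom", "pos",
                        "ref_count", "alt_count"]
RNA_COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref_count", "alt_count"]
GWAS_COLUMNS = ["rsid", "chrom", "pos", "trait", "maf"]
MAF_COLUMNS = ["rsid", "chrom", "pos", "maf"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def pos_to_interval_coord(pos: int) -> int:
    """1-based point position -> 0-based coordinate usable in [start, end)."""
    return pos - 1


def interval_coord_to_pos(coord: int) -> int:
    """0-based coordinate -> 1-based point position (inverse of the above)."""
    return coord + 1


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV from a VCF, 1-based."""
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""
    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based point position."""
        return chrom == self.chrom and self.start <= pos_to_interval_coord(pos) < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class ChiaPetContact:
    """A paired-end-tag contact between two anchors, with pair counts.

    ``pairs_forward + pairs_reverse`` partition ``total_pairs`` (the two
    read orientations supporting the contact).  Anchors are stored so that
    ``anchor1 <= anchor2`` by (chrom, start).
    """
    anchor1: Interval
    anchor2: Interval
    total_pairs: int
    pairs_forward: int
    pairs_reverse: int

    def __post_init__(self) -> None:
        if min(self.total_pairs, self.pairs_forward, self.pairs_reverse) < 0:
            raise FormatError("negative ChIA-PET pair count")
        if self.pairs_forward + self.pairs_reverse != self.total_pairs:
            raise FormatError(
                "per-direction pair counts must partition the total "
                f"({self.pairs_forward}+{self.pairs_reverse} != {self.total_pairs})")

    @property
    def intrachromosomal(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(path: PathLike) -> Tuple[List[VariantRecord], List[Interval]]:
    """Parse a VCF into biallelic SNVs plus a side channel of indel regions.

    Returns ``(snvs, excluded_regions)``.  Indel and multiallelic records
    are not variants for this pipeline, but their footprints feed the
    indel-proximity QC filter, so they are returned as 0-based intervals
    covering the REF span.
    """
    snvs: List[VariantRecord] = []
    regions: List[Interval] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if rec.ref is None or rec.alts is None or not rec.alts:
                log.warning("VCF record without REF/ALT at %s:%s rejected",
                            rec.chrom, rec.pos)
                continue
            alts = [a for a in rec.alts if a is not None]
            is_snv = (len(alts) == 1 and len(rec.ref) == 1 and len(alts[0]) == 1
                      and rec.ref != alts[0])
            if is_snv:
                rsid = rec.id if rec.id not in (None, ".") else None
                snvs.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alts[0], rsid))
            else:
                span = max(len(rec.ref), max(len(a) for a in alts))
                regions.append(Interval(rec.chrom, rec.pos - 1, rec.pos - 1 + span))
    return snvs, regions


def write_variants(path: PathLike, snvs: Sequence[VariantRecord],
                   contigs: Optional[dict] = None) -> None:
    """Write biallelic SNVs as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in snvs:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}"
                     "\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: PathLike) -> List[Interval]:
    """Read a BED3+ file into intervals sorted by (chrom, start).

    Zero-length or inverted intervals are format errors naming the line.
    """
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            name = parts[3] if len(parts) > 3 else None
            out.append(Interval(chrom, start, end, name))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(path: PathLike, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"\t{iv.name}" if iv.name is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Union of intervals: overlapping/abutting intervals are merged."""
    merged: List[Interval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# BEDPE with pair counts
# ---------------------------------------------------------------------------

def read_contacts(path: PathLike) -> List[ChiaPetContact]:
    """Read BEDPE+counts: 6 coordinate columns, total pairs, forward, reverse.

    Anchors are normalised so anchor1 <= anchor2 by (chrom, start); the
    forward/reverse counts refer to read orientation and are unaffected by
    the normalisation.
    """
    out: List[ChiaPetContact] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: BEDPE line has <9 columns")
            try:
                a1 = Interval(parts[0], int(parts[1]), int(parts[2]))
                a2 = Interval(parts[3], int(parts[4]), int(parts[5]))
                total, fwd, rev = int(parts[6]), int(parts[7]), int(parts[8])
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if (a2.chrom, a2.start) < (a1.chrom, a1.start):
                a1, a2 = a2, a1
            try:
                out.append(ChiaPetContact(a1, a2, total, fwd, rev))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_contacts(path: PathLike, contacts: Iterable[ChiaPetContact]) -> None:
    with open(path, "w") as fh:
        for c in contacts:
            fh.write("\t".join(map(str, [
                c.anchor1.chrom, c.anchor1.start, c.anchor1.end,
                c.anchor2.chrom, c.anchor2.start, c.anchor2.end,
                c.total_pairs, c.pairs_forward, c.pairs_reverse])) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_table(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str,
                                            "rsid": str})
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df[list(columns)]


def read_allele_counts(path: PathLike) -> pd.DataFrame:
    """Per-site, per-sample, per-alignment-reference ChIP allele counts."""
    df = _read_table(path, ALLELE_COUNT_COLUMNS)
    bad = ~df["alignment_ref"].isin(["ref", "alt"])
    if bad.any():
        raise FormatError(f"{path}: alignment_ref must be 'ref' or 'alt'")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise FormatError(f"{path}: negative allele count")
    return df


def write_allele_counts(path: PathLike, df: pd.DataFrame) -> None:
    df[ALLELE_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_rna_counts(path: PathLike) -> pd.DataFrame:
    df = _read_table(path, RNA_COUNT_COLUMNS)
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise FormatError(f"{path}: negative allele count")
    return df


def write_rna_counts(path: PathLike, df: pd.DataFrame) -> None:
    df[RNA_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas_catalog(path: PathLike) -> pd.DataFrame:
    df = _read_table(path, GWAS_COLUMNS)
    if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
        raise FormatError(f"{path}: MAF outside (0, 0.5]")
    return df


def write_gwas_catalog(path: PathLike, df: pd.DataFrame) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_maf_table(path: PathLike) -> pd.DataFrame:
    df = _read_table(path, MAF_COLUMNS)
    if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
        raise FormatError(f"{path}: MAF outside (0, 0.5]")
    return df


def write_maf_table(path: PathLike, df: pd.DataFrame) -> None:
    df[MAF_COLUMNS].to_csv(path, sep="\t", index=False)
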