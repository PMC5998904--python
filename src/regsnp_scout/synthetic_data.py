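"""Synthetic input bundle with planted ground truth.

``simulate`` emits every file the pipeline consumes -- reference FASTA,
gene models (GTF), OTFRs (BED), heterozygous variants (VCF), per-sample /
per-alignment ChIP allele counts (TSV), Pol II peaks (BED), ChIA-PET
contacts (BEDPE with pair counts), RNA marker counts (TSV), a GWAS
catalog extract and a MAF table -- together with a truth manifest naming
every planted effect, so end-to-end recovery can be scored.

What is planted:

* a fraction of heterozygous sites carry true ChIP allele fraction
  ``asb_allele_fraction`` (direction random); the rest are balanced;
* reference mapping bias is an additive shift of opposite sign in the
  mapped allele fraction under the two alignment references, so the
  dual-alignment average cancels it in expectation;
* each planted site has one designated target gene -- proximal sites sit
  in a promoter/intron/UTR, distal sites are intergenic and joined to
  their target's promoter by a ChIA-PET loop over random-ligation noise;
* a fraction of target genes are regulated: their RNA markers are drawn
  at ``ase_allele_fraction``; planted sites with a regulated target are
  the planted rSNPs;
* GWAS indexes either tag a planted rSNP (window + MAF + trait all
  satisfied) or are decoys violating exactly one linkage criterion;
* a handful of extra sites exercise the QC funnel (sex chromosome,
  repeat, clustered triplet, indel-proximal, low coverage).

The same seed yields a byte-identical bundle.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationSpec
from .io_formats import (ChiaPetContact, Interval, write_allele_counts,
                         write_contacts, write_intervals, write_gwas_catalog,
                         write_maf_table, write_rna_counts, write_variants,
                         VariantRecord)
from .reference_model import GeneModel, write_fasta

GENE_SPAN = 8000
_EXONS = [(0, 700), (2500, 3200), (5000, 5700), (7300, 8000)]
_UTR_LEN = 200
_MATCHING_TRAITS = [
    "Schizophrenia", "Bipolar disorder", "Autism spectrum disorder",
    "Major depressive disorder", "Alzheimer's disease (late onset)",
    "Parkinson's disease", "Cognitive decline (age-related)",
    "Anxiety disorder", "Posttraumatic stress disorder", "Depression (quantitative trait)",
]
_DECOY_TRAITS = ["Height", "Body mass index", "Type 2 diabetes",
                 "Coronary artery disease"]


@dataclass
class PlantedSite:
    chrom: str
    pos: int
    true_fraction: float            # ChIP ref-allele fraction in the effect ChIP
    kind: str                       # 'proximal' | 'distal'
    target_gene: str
    relation: str                   # promoter|intron|utr5|utr3|distal_chiapet
    regulated: bool = False         # target gene shows ASE -> planted rSNP
    effect_sample: str = ""         # the ChIP experiment carrying the effect

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class TruthManifest:
    planted_asymmetric: List[PlantedSite]
    planted_rsnp_ids: List[str]
    regulated_genes: List[str]
    null_site_ids: List[str]        # balanced sites expected to pass QC
    qc_exercise: Dict[str, List[str]]
    true_index_rsids: Dict[str, str]     # index rsid -> tagged rSNP site id
    decoy_indexes: Dict[str, str]        # decoy rsid -> violated criterion
    site_coverage: Dict[str, float]      # mean per-experiment coverage
    rna_marker_coverage: Dict[str, List[int]]  # gene -> marker totals

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        data["planted_asymmetric"] = [PlantedSite(**p)
                                      for p in data["planted_asymmetric"]]
        return cls(**data)


class _Placer:
    """Collision-avoiding position sampler (min pairwise gap per chrom)."""

    def __init__(self, rng: np.random.Generator, min_gap: int = 25):
        self.rng = rng
        self.min_gap = min_gap
        self._occupied: Dict[str, List[int]] = {}

    def is_free(self, chrom: str, pos: int) -> bool:
        occ = self._occupied.setdefault(chrom, [])
        i = bisect_left(occ, pos)
        for j in (i - 1, i):
            if 0 <= j < len(occ) and abs(occ[j] - pos) < self.min_gap:
                return False
        return True

    def claim(self, chrom: str, pos: int) -> None:
        insort(self._occupied.setdefault(chrom, []), pos)

    def place(self, chrom: str, lo: int, hi: int, tries: int = 500) -> int:
        if hi < lo:
            raise ValueError(f"infeasible placement window [{lo}, {hi}]")
        for _ in range(tries):
            pos = int(self.rng.integers(lo, hi + 1))
            if self.is_free(chrom, pos):
                self.claim(chrom, pos)
                return pos
        raise RuntimeError(f"infeasible placement on {chrom}:[{lo},{hi}]")


def _make_genes(spec: SimulationSpec, rng: np.random.Generator,
                ) -> List[GeneModel]:
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    genes: List[GeneModel] = []
    for chrom, n in zip(chroms, per_chrom):
        usable = spec.chrom_length_bp - 20_000
        slot = usable // max(n, 1)
        if slot < GENE_SPAN + 2 * 1800 + 4000:
            raise ValueError("infeasible placement: too many genes for "
                             "chromosome length")
        for i in range(n):
            lo = 10_000 + i * slot + 2000
            hi = 10_000 + i * slot + slot - GENE_SPAN - 2000
            g0 = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [Interval(chrom, g0 + a, g0 + b) for a, b in _EXONS]
            if strand == "+":
                utr5 = [Interval(chrom, g0, g0 + _UTR_LEN)]
                utr3 = [Interval(chrom, g0 + GENE_SPAN - _UTR_LEN, g0 + GENE_SPAN)]
            else:
                utr5 = [Interval(chrom, g0 + GENE_SPAN - _UTR_LEN, g0 + GENE_SPAN)]
                utr3 = [Interval(chrom, g0, g0 + _UTR_LEN)]
            # first/last exon lose their UTR-covered 200 bp (utr5/utr3 swap
            # sides with strand, but the trimmed ends do not)
            cds = []
            for k, (a, b) in enumerate(_EXONS):
                s, e = g0 + a, g0 + b
                if k == 0:
                    s += _UTR_LEN
                if k == len(_EXONS) - 1:
                    e -= _UTR_LEN
                cds.append(Interval(chrom, s, e))
            gene_idx = len(genes) + 1
            genes.append(GeneModel(gene_id=f"GENE{gene_idx:04d}", chrom=chrom,
                                   strand=strand, exons=exons, cds=cds,
                                   utr5=utr5, utr3=utr3))
    return genes


def _write_gtf(path, genes: List[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            span = g.span
            rows = [("gene", span.start, span.end),
                    ("transcript", span.start, span.end)]
            rows += [("exon", iv.start, iv.end) for iv in g.exons]
            rows += [("CDS", iv.start, iv.end) for iv in g.cds]
            rows += [("five_prime_utr", iv.start, iv.end) for iv in g.utr5]
            rows += [("three_prime_utr", iv.start, iv.end) for iv in g.utr3]
            for feature, s, e in rows:
                fh.write(f"{g.chrom}\tsim\t{feature}\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


def _nb_coverage(mean: float, dispersion: float,
                 rng: np.random.Generator) -> int:
    """Negative-binomial coverage around the mean (variance mu + a*mu^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return max(1, int(rng.negative_binomial(r, p)))


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[int(rng.integers(0, 3))]


def simulate(spec: SimulationSpec, out_dir) -> TruthManifest:
    """Generate the full input bundle under ``out_dir``; returns the truth."""
    rng = np.random.default_rng(spec.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chroms = {f"chr{i + 1}": spec.chrom_length_bp for i in range(spec.n_chroms)}
    aux_len = 20_000
    all_chroms = dict(chroms)
    all_chroms["chrX"] = aux_len

    sequences = {name: "".join(rng.choice(list("ACGT"), size=length))
                 for name, length in all_chroms.items()}

    genes = _make_genes(spec, rng)
    _write_gtf(out / "genes.gtf", genes)
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    placer = _Placer(rng)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]

    # ------------------------------------------------------------------ sites
    n_planted = int(round(spec.frac_asymmetric * spec.n_het_sites))
    n_distal = min(spec.n_chiapet_loops, n_planted // 2)
    n_proximal = n_planted - n_distal

    planted: List[PlantedSite] = []
    relations = ["promoter", "intron", "utr5", "utr3"]
    gene_cycle = list(genes)
    for i in range(n_proximal):
        gene = gene_cycle[i % len(gene_cycle)]
        relation = relations[i % len(relations)]
        g0 = gene.span.start
        if relation == "promoter":
            # upstream of the transcript, inside the +/-1.8 kb window
            if gene.strand == "+":
                lo, hi = gene.tss - 1700, gene.tss - 100
            else:
                lo, hi = gene.tss + 100, gene.tss + 1700
        elif relation == "intron":
            lo, hi = g0 + 900, g0 + 2400          # inside intron 1
        elif relation == "utr5":
            iv = gene.utr5[0]
            lo, hi = iv.start + 2, iv.end - 1     # 1-based inside the UTR
        else:
            iv = gene.utr3[0]
            lo, hi = iv.start + 2, iv.end - 1
        pos = placer.place(gene.chrom, lo, hi)
        frac = spec.asb_allele_fraction if rng.random() < 0.5 \
            else 1.0 - spec.asb_allele_fraction
        planted.append(PlantedSite(gene.chrom, pos, frac, "proximal",
                                   gene.gene_id, relation))

    # distal sites: deep intergenic (clear of every promoter window plus the
    # ChIA-PET SNP window), looped to a promoter >10 kb away
    for i in range(n_distal):
        chrom = f"chr{(i % spec.n_chroms) + 1}"
        cg = genes_by_chrom[chrom]
        pos = None
        for _ in range(1000):
            cand = int(rng.integers(2000, chroms[chrom] - 2000))
            if all(cand < g.span.start - 2900 or cand > g.span.end + 2900
                   for g in cg) and placer.is_free(chrom, cand):
                placer.claim(chrom, cand)
                pos = cand
                break
        if pos is None:
            raise RuntimeError("infeasible placement of distal site")
        candidates = [g for g in cg if abs(g.tss - pos) > 10_000]
        target = candidates[int(rng.integers(0, len(candidates)))]
        frac = spec.asb_allele_fraction if rng.random() < 0.5 \
            else 1.0 - spec.asb_allele_fraction
        planted.append(PlantedSite(chrom, pos, frac, "distal",
                                   target.gene_id, "distal_chiapet"))

    # the ChIP experiment whose factor the variant perturbs
    for p in planted:
        p.effect_sample = samples[int(rng.integers(0, spec.n_samples))]

    # regulated targets -> planted rSNPs
    n_regulated = int(round(spec.frac_targets_with_ase * len(planted)))
    order = rng.permutation(len(planted))
    for k in order[:n_regulated]:
        planted[int(k)].regulated = True
    regulated_genes = sorted({p.target_gene for p in planted if p.regulated})
    # a gene regulated through one planted site confirms every planted site
    # targeting it, so membership is recomputed gene-wise
    for p in planted:
        p.regulated = p.target_gene in regulated_genes
    planted_rsnp_ids = sorted({p.site_id for p in planted if p.regulated})

    # null sites
    n_null = spec.n_het_sites - len(planted)
    null_sites: List[Tuple[str, int]] = []
    chrom_names = sorted(chroms)
    for i in range(n_null):
        chrom = chrom_names[i % len(chrom_names)]
        pos = placer.place(chrom, 1000, chroms[chrom] - 1000)
        null_sites.append((chrom, pos))
    null_sites.sort()

    # QC-exercise sites (balanced, except the homozygote-like artifacts)
    qc_sites: Dict[str, List[Tuple[str, int]]] = {
        "blacklist_chrom": [("chrX", 5000), ("chrX", 6000), ("chrX", 7000)],
        "blacklist_repeat": [], "clustered": [], "indel_proximity": [],
        "low_coverage": [], "balance_artifact": [],
    }
    chrom1 = chrom_names[0]
    gap_lo = 2000  # before the first gene slot (genes start at >= 12,000)
    repeat_ivs = [Interval(chrom1, gap_lo + k * 600, gap_lo + k * 600 + 500,
                           f"REP{k}") for k in range(3)]
    for k, iv in enumerate(repeat_ivs):
        pos = placer.place(chrom1, iv.start + 100, iv.end - 100)
        qc_sites["blacklist_repeat"].append((chrom1, pos))
    base = placer.place(chrom1, 4500, 5500)
    for off in (0, 5, 9):                      # triplet: all clustered
        if off:
            placer.claim(chrom1, base + off)
        qc_sites["clustered"].append((chrom1, base + off))
    ipos = placer.place(chrom1, 6000, 7000)
    qc_sites["indel_proximity"].append((chrom1, ipos))
    indel_start_pos = ipos + 3                 # region 1-based [ipos+3, ipos+4]
    lpos = placer.place(chrom1, 7500, 8500)
    qc_sites["low_coverage"].append((chrom1, lpos))
    last_chrom = chrom_names[-1]
    for _ in range(spec.n_balance_artifacts):
        apos = placer.place(last_chrom, 1000, chroms[last_chrom] - 1000)
        qc_sites["balance_artifact"].append((last_chrom, apos))

    # ------------------------------------------------------------------ VCF
    site_list: List[Tuple[str, int, str]] = []   # (chrom, pos, category)
    for p in planted:
        site_list.append((p.chrom, p.pos, "planted"))
    for chrom, pos in null_sites:
        site_list.append((chrom, pos, "null"))
    for cat, sites in sorted(qc_sites.items()):
        for chrom, pos in sites:
            site_list.append((chrom, pos, cat))
    site_list.sort(key=lambda t: (t[0], t[1]))

    frac_by_site = {p.site_id: p.true_fraction for p in planted}
    variants: List[VariantRecord] = []
    rs_counter = 1000
    annotated: Dict[str, str] = {}
    for chrom, pos, cat in site_list:
        ref = sequences[chrom][pos - 1]
        alt = _alt_base(rng, ref)
        rsid = None
        if rng.random() < spec.frac_annotated:
            rsid = f"rs{rs_counter}"
            rs_counter += 1
            annotated[f"{chrom}:{pos}"] = rsid
        variants.append(VariantRecord(chrom, pos, ref, alt, rsid))
    write_variants(out / "variants.vcf", variants, contigs=all_chroms)
    # indel record appended for the proximity filter
    with open(out / "variants.vcf", "a") as fh:
        ic, ip = chrom1, indel_start_pos
        ref2 = sequences[ic][ip - 1: ip + 1]
        fh.write(f"{ic}\t{ip}\t.\t{ref2}\t{ref2[0]}\t.\t.\t.\n")

    # ------------------------------------------------------------------ OTFRs
    otfrs: List[Interval] = []
    null_in_otfr = [null_sites[i] for i in
                    sorted(rng.choice(len(null_sites),
                                      size=min(150, len(null_sites)),
                                      replace=False))]
    centers = [(p.chrom, p.pos) for p in planted] + null_in_otfr
    for chrom, pos in centers:
        half = int(rng.integers(150, 450))
        otfrs.append(Interval(chrom, max(0, pos - 1 - half), pos - 1 + half))
    n_extra = max(0, spec.n_otfrs - len(centers))
    for _ in range(n_extra):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, chroms[chrom] - 1000))
        otfrs.append(Interval(chrom, start, start + int(rng.integers(300, 900))))
    otfrs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    write_intervals(out / "otfrs.bed",
                    [Interval(iv.chrom, iv.start, iv.end, f"OTFR{i:05d}")
                     for i, iv in enumerate(otfrs)])
    write_intervals(out / "repeats.bed", repeat_ivs)

    # ------------------------------------------------------------- ChIP counts
    low_cov = set(qc_sites["low_coverage"])
    artifact = set(qc_sites["balance_artifact"])
    effect_sample_by_site = {p.site_id: p.effect_sample for p in planted}
    rows = []
    cov_by_site: Dict[str, float] = {}
    for chrom, pos, cat in site_list:
        site_id = f"{chrom}:{pos}"
        eff_sample = effect_sample_by_site.get(site_id)
        covs = []
        for sample in samples:
            if (chrom, pos) in artifact:
                f = spec.artifact_fraction      # looks homozygous everywhere
            elif sample == eff_sample:
                f = frac_by_site[site_id]       # the perturbed factor's ChIP
            else:
                f = 0.5
            if (chrom, pos) in low_cov:
                # keep pooled depth below the 10-read site threshold
                n = 1 if sample in samples[:2] else 0
            else:
                mean = spec.coverage_mean
                if sample == eff_sample:
                    mean *= spec.effect_coverage_enrichment
                n = _nb_coverage(mean, spec.coverage_dispersion, rng)
            covs.append(n)
            for aln, sign in (("ref", +1.0), ("alt", -1.0)):
                p_map = min(1.0, max(0.0, f + sign * spec.reference_bias))
                ref_c = int(rng.binomial(n, p_map))
                rows.append({"sample_id": sample, "alignment_ref": aln,
                             "chrom": chrom, "pos": pos,
                             "ref_count": ref_c, "alt_count": n - ref_c})
        cov_by_site[site_id] = float(np.mean(covs))
    write_allele_counts(out / "chip_allele_counts.tsv", pd.DataFrame(rows))

    # ------------------------------------------------------------ Pol II peaks
    peaks = []
    for g in genes:
        tss0 = g.tss - 1
        peaks.append(Interval(g.chrom, max(0, tss0 - 1800), tss0 + 1800))
    for _ in range(100):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, chroms[chrom] - 2000))
        peaks.append(Interval(chrom, start, start + 1000))
    peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    write_intervals(out / "polii_peaks.bed", peaks)

    # --------------------------------------------------------------- ChIA-PET
    gene_by_id = {g.gene_id: g for g in genes}
    contacts: List[ChiaPetContact] = []
    for p in planted:
        if p.kind != "distal":
            continue
        a1 = Interval(p.chrom, p.pos - 1 - 400, p.pos - 1 + 400)
        tss0 = gene_by_id[p.target_gene].tss - 1
        a2 = Interval(p.chrom, max(0, tss0 - 500), tss0 + 500)
        total = 24 + int(rng.poisson(10))
        fwd = total // 2
        contacts.append(ChiaPetContact(*sorted([a1, a2],
                                               key=lambda iv: (iv.chrom, iv.start)),
                                       total, fwd, total - fwd))
    for _ in range(spec.chiapet_noise_pairs):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        s1 = int(rng.integers(0, chroms[chrom] - 600))
        gap = int(rng.integers(5_000, 400_000))
        s2 = min(chroms[chrom] - 600, s1 + gap)
        total = 1 + int(rng.poisson(3.0))
        if rng.random() < 0.03:
            total = 20 + int(rng.poisson(5.0))
        fwd = int(rng.binomial(total, 0.5))
        a1 = Interval(chrom, s1, s1 + 600)
        a2 = Interval(chrom, s2, s2 + 600)
        if a2.start < a1.start:
            a1, a2 = a2, a1
        contacts.append(ChiaPetContact(a1, a2, total, fwd, total - fwd))
    write_contacts(out / "chiapet_contacts.bedpe", contacts)

    # -------------------------------------------------------------- RNA counts
    rna_rows = []
    marker_cov: Dict[str, List[int]] = {}
    for g in genes:
        f_rna = spec.ase_allele_fraction if g.gene_id in regulated_genes else 0.5
        if f_rna != 0.5 and rng.random() < 0.5:
            f_rna = 1.0 - f_rna
        totals = []
        for _ in range(spec.markers_per_gene):
            cds = g.cds[int(rng.integers(0, len(g.cds)))]
            pos = placer.place(g.chrom, cds.start + 1, cds.end)
            n = max(spec.rna_coverage_mean // 10,
                    int(rng.poisson(spec.rna_coverage_mean)))
            ref_c = int(rng.binomial(n, f_rna))
            rna_rows.append({"sample_id": "RNA1", "chrom": g.chrom, "pos": pos,
                             "ref_count": ref_c, "alt_count": int(n) - ref_c})
            totals.append(int(n))
        marker_cov[g.gene_id] = totals
    write_rna_counts(out / "rna_allele_counts.tsv", pd.DataFrame(rna_rows))

    # ---------------------------------------------------------------- MAF table
    maf_rows = []
    maf_by_site: Dict[str, float] = {}
    for chrom, pos, cat in site_list:
        maf = float(np.round(rng.uniform(spec.maf_low, spec.maf_high), 4))
        site_id = f"{chrom}:{pos}"
        maf_by_site[site_id] = maf
        maf_rows.append({"rsid": annotated.get(site_id, "."), "chrom": chrom,
                         "pos": pos, "maf": maf})
    write_maf_table(out / "snp_mafs.tsv", pd.DataFrame(maf_rows))

    # ------------------------------------------------------------ GWAS catalog
    planted_positions = [(p.chrom, p.pos) for p in planted]

    def _near_planted(chrom: str, pos: int, window: int = 10_000) -> List[int]:
        return [i for i, (c, q) in enumerate(planted_positions)
                if c == chrom and abs(q - pos) <= window]

    rsnp_sites = [p for p in planted if p.regulated]
    n_true = min(int(round(spec.n_gwas_indexes * spec.frac_indexes_near_rsnps)),
                 len(rsnp_sites))
    picks = sorted(rng.choice(len(rsnp_sites), size=n_true, replace=False))
    gwas_rows = []
    true_index: Dict[str, str] = {}
    decoys: Dict[str, str] = {}
    idx_counter = 90_000
    for k in picks:
        p = rsnp_sites[int(k)]
        offset = int(rng.integers(-9_000, 9_001))
        pos = max(1, p.pos + offset)
        maf = float(np.round(np.clip(
            maf_by_site[p.site_id] + rng.uniform(-0.12, 0.12), 0.02, 0.5), 4))
        trait = _MATCHING_TRAITS[int(rng.integers(0, len(_MATCHING_TRAITS)))]
        rsid = f"rs{idx_counter}"
        idx_counter += 1
        gwas_rows.append({"rsid": rsid, "chrom": p.chrom, "pos": pos,
                          "trait": trait, "maf": maf})
        true_index[rsid] = p.site_id

    n_decoys = spec.n_gwas_indexes - n_true
    violations = ["trait", "window", "maf"]
    d = 0
    guard = 0
    while d < n_decoys:
        guard += 1
        if guard > 50 * n_decoys:
            raise RuntimeError("infeasible decoy placement")
        if not planted:
            # nothing to tag: any matching-trait index is a window decoy
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            rsid = f"rs{idx_counter}"
            idx_counter += 1
            gwas_rows.append({
                "rsid": rsid, "chrom": chrom,
                "pos": int(rng.integers(1, chroms[chrom])),
                "trait": _MATCHING_TRAITS[int(rng.integers(0, len(_MATCHING_TRAITS)))],
                "maf": float(np.round(rng.uniform(0.05, 0.5), 4))})
            decoys[rsid] = "window"
            d += 1
            continue
        violation = violations[d % 3]
        p = planted[int(rng.integers(0, len(planted)))]
        anchor_maf = maf_by_site[p.site_id]
        if violation == "trait":
            pos = max(1, p.pos + int(rng.integers(-9_000, 9_001)))
            maf = float(np.round(np.clip(anchor_maf + rng.uniform(-0.12, 0.12),
                                         0.02, 0.5), 4))
            trait = _DECOY_TRAITS[int(rng.integers(0, len(_DECOY_TRAITS)))]
        elif violation == "window":
            sign = 1 if rng.random() < 0.5 else -1
            pos = p.pos + sign * int(rng.integers(12_000, 40_000))
            if not 1 <= pos <= chroms.get(p.chrom, 0):
                continue
            if _near_planted(p.chrom, pos):
                continue
            maf = float(np.round(np.clip(anchor_maf + rng.uniform(-0.12, 0.12),
                                         0.02, 0.5), 4))
            trait = _MATCHING_TRAITS[int(rng.integers(0, len(_MATCHING_TRAITS)))]
        else:
            pos = max(1, p.pos + int(rng.integers(-9_000, 9_001)))
            maf = anchor_maf + 0.2 if anchor_maf + 0.2 <= 0.5 else anchor_maf - 0.2
            maf = float(np.round(maf, 4))
            # every planted site in the window must miss the MAF criterion
            near = _near_planted(p.chrom, pos)
            if any(abs(maf_by_site[planted[i].site_id] - maf) <= 0.15
                   for i in near):
                continue
            trait = _MATCHING_TRAITS[int(rng.integers(0, len(_MATCHING_TRAITS)))]
        if violation != "window":
            # single-violation design: all other criteria must be satisfiable
            near = _near_planted(p.chrom, pos)
            if not near:
                continue
        rsid = f"rs{idx_counter}"
        idx_counter += 1
        gwas_rows.append({"rsid": rsid, "chrom": p.chrom, "pos": pos,
                          "trait": trait, "maf": maf})
        decoys[rsid] = violation
        d += 1
    gwas_df = pd.DataFrame(gwas_rows).sort_values(["chrom", "pos", "rsid"])
    write_gwas_catalog(out / "gwas_catalog.tsv", gwas_df)

    write_fasta(out / "genome.fa", sequences)

    manifest = TruthManifest(
        planted_asymmetric=planted,
        planted_rsnp_ids=planted_rsnp_ids,
        regulated_genes=regulated_genes,
        null_site_ids=[f"{c}:{p}" for c, p in null_sites],
        qc_exercise={k: [f"{c}:{p}" for c, p in v]
                     for k, v in sorted(qc_sites.items())},
        true_index_rsids=true_index,
        decoy_indexes=decoys,
        site_coverage=cov_by_site,
        rna_marker_coverage=marker_cov,
    )
    manifest.to_json(out / "truth_manifest.json")
    return manifest


BUNDLE_FILES = ["genome.fa", "genes.gtf", "otfrs.bed", "repeats.bed",
                "variants.vcf", "chip_allele_counts.tsv", "polii_peaks.bed",
                "chiapet_contacts.bedpe", "rna_allele_counts.tsv",
                "gwas_catalog.tsv", "snp_mafs.tsv", "truth_manifest.json"]
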