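"""End-to-end orchestration: het QC -> ASB -> targets -> ASE -> GWAS linkage.

Each stage reads plain TSV/BED/VCF inputs and writes a plain TSV output
under the run directory, so any stage is independently replayable; the
funnel log records (n_in, n_out, removal reasons) per stage and the
summary JSON carries the headline counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import io_formats as io
from .ase_confirmation import ase_test, promote_to_rsnp, select_markers
from .asb_detection import asymmetric_sites, detect_asb
from .config import RunConfig
from .gwas_linkage import build_report, filter_traits
from .het_qc import assemble_sites, call_het_snps, het_snps_to_frame
from .reference_model import read_gene_models
from .target_assignment import assign_targets, effective_genome_size

log = logging.getLogger("regsnp_scout")


@dataclass
class InputPaths:
    """Locations of every pipeline input."""
    variants_vcf: str
    chip_counts_tsv: str
    otfrs_bed: str
    genes_gtf: str
    rna_counts_tsv: str
    gwas_catalog_tsv: str
    maf_table_tsv: str
    chiapet_bedpe: Optional[str] = None
    polii_peaks_bed: Optional[str] = None
    repeats_bed: Optional[str] = None

    @classmethod
    def from_bundle(cls, bundle_dir) -> "InputPaths":
        """Paths for a directory written by :func:`synthetic_data.simulate`."""
        d = Path(bundle_dir)
        return cls(variants_vcf=str(d / "variants.vcf"),
                   chip_counts_tsv=str(d / "chip_allele_counts.tsv"),
                   otfrs_bed=str(d / "otfrs.bed"),
                   genes_gtf=str(d / "genes.gtf"),
                   rna_counts_tsv=str(d / "rna_allele_counts.tsv"),
                   gwas_catalog_tsv=str(d / "gwas_catalog.tsv"),
                   maf_table_tsv=str(d / "snp_mafs.tsv"),
                   chiapet_bedpe=str(d / "chiapet_contacts.bedpe"),
                   polii_peaks_bed=str(d / "polii_peaks.bed"),
                   repeats_bed=str(d / "repeats.bed"))

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"missing input file for {name}: {value}")


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    removal_reasons: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"{self.stage}: n_out {self.n_out} > n_in {self.n_in}")


@dataclass
class FunnelLog:
    stages: List[StageRecord] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int,
            reasons: Optional[Dict[str, int]] = None) -> None:
        self.stages.append(StageRecord(stage, n_in, n_out, dict(reasons or {})))
        log.info("funnel %s: %d -> %d %s", stage, n_in, n_out, reasons or {})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self.stages], fh, indent=1)


@dataclass
class PipelineResult:
    het_snps: pd.DataFrame
    asb_tests: pd.DataFrame
    asymmetric: pd.DataFrame
    targets: pd.DataFrame
    ase_results: pd.DataFrame
    rsnps: pd.DataFrame
    report: pd.DataFrame
    summary: Dict[str, int]
    funnel: FunnelLog


def run_pipeline(config: RunConfig, paths: InputPaths,
                 out_dir=None) -> PipelineResult:
    """Run all stages in fixed order; optionally write per-stage TSVs."""
    paths.validate()
    funnel = FunnelLog()

    # stage 1-3: variant intake and het QC
    variants, indel_regions = io.read_variants(paths.variants_vcf)
    counts = io.read_allele_counts(paths.chip_counts_tsv)
    sites = assemble_sites(variants, counts)
    repeats = (io.read_intervals(paths.repeats_bed)
               if paths.repeats_bed else [])
    het_snps, removed = call_het_snps(sites, config,
                                      repeat_intervals=repeats,
                                      indel_regions=indel_regions)
    funnel.add("het_qc", len(sites), len(het_snps), removed)
    het_frame = het_snps_to_frame(het_snps)

    # stage 4: allele-specific binding inside OTFRs
    otfrs = io.read_intervals(paths.otfrs_bed)
    asb_tests = detect_asb(het_snps, otfrs, config)
    asymmetric = asymmetric_sites(asb_tests)
    funnel.add("asb_detection", len(het_snps), len(asymmetric),
               {"not_in_otfr_or_not_significant":
                len(het_snps) - len(asymmetric)})

    # stage 5: target genes (proximal + ChIA-PET distal)
    genes = read_gene_models(paths.genes_gtf)
    contacts = (io.read_contacts(paths.chiapet_bedpe)
                if paths.chiapet_bedpe else [])
    g_eff = None
    if paths.polii_peaks_bed:
        g_eff = effective_genome_size([io.read_intervals(paths.polii_peaks_bed)])
    targets = assign_targets(asymmetric, genes, contacts, config, g_eff)
    n_targeted_snps = (targets[["chrom", "pos"]].drop_duplicates().shape[0]
                       if not targets.empty else 0)
    funnel.add("target_assignment", len(asymmetric), n_targeted_snps)

    # stage 6: allele-specific expression -> rSNPs
    rna_counts = io.read_rna_counts(paths.rna_counts_tsv)
    markers = select_markers(targets, genes, rna_counts, config)
    dna_counts = {(h.site.chrom, h.site.pos):
                  (h.site.pooled_ref_count, h.site.pooled_alt_count)
                  for h in het_snps}
    ase_results = ase_test(markers, config, dna_counts=dna_counts)
    rsnps = promote_to_rsnp(asymmetric, targets, ase_results)
    n_rsnp_sites = (rsnps[["chrom", "pos"]].drop_duplicates().shape[0]
                    if not rsnps.empty else 0)
    funnel.add("ase_confirmation", n_targeted_snps, n_rsnp_sites)

    # stage 7: GWAS linkage
    catalog = io.read_gwas_catalog(paths.gwas_catalog_tsv)
    indexes = filter_traits(catalog, config.trait_signatures)
    maf_df = io.read_maf_table(paths.maf_table_tsv)
    mafs = {f"{r.chrom}:{r.pos}": float(r.maf)
            for r in maf_df.itertuples(index=False)}
    report, report_summary = build_report(rsnps, indexes, mafs, config)
    funnel.add("gwas_linkage", n_rsnp_sites, report_summary["n_unique_rsnps"])

    summary = {
        "n_het": len(het_snps),
        "n_asymmetric": len(asymmetric),
        "n_targeted_snps": n_targeted_snps,
        "n_target_genes": (targets["gene_id"].nunique()
                           if not targets.empty else 0),
        "n_rsnps": n_rsnp_sites,
        "n_linked_rsnps_unique": report_summary["n_unique_rsnps"],
        "n_linked_genes_unique": report_summary["n_unique_genes"],
    }

    result = PipelineResult(het_frame, asb_tests, asymmetric, targets,
                            ase_results, rsnps, report, summary, funnel)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.het_snps.to_csv(out / "het_snps.tsv", sep="\t", index=False)
    result.asb_tests.to_csv(out / "asb_tests.tsv", sep="\t", index=False)
    result.asymmetric.to_csv(out / "asymmetric_snps.tsv", sep="\t", index=False)
    result.targets.to_csv(out / "target_assignments.tsv", sep="\t", index=False)
    result.ase_results.to_csv(out / "ase_results.tsv", sep="\t", index=False)
    result.rsnps.to_csv(out / "rsnps.tsv", sep="\t", index=False)
    result.report.to_csv(out / "linked_rsnps.tsv", sep="\t", index=False)
    result.funnel.to_json(out / "funnel.json")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
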