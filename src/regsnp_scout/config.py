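"""Validated run configuration for the rSNP discovery pipeline.

Every numeric threshold the pipeline applies lives here, so a run is fully
described by one :class:`RunConfig`.  Defaults are the published thresholds
of the procedure: 10-read site coverage, Phred 20 base quality, MAPQ 25,
5 bp indel exclusion, 10 bp SNP-cluster window, binomial heterozygosity
balance at 0.05, allele-specific binding at 0.01, +/-1.8 kb promoters,
+/-1 kb ChIA-PET SNP windows with >=20 total / >=10 per-direction pairs and
contact significance 0.001, >=10 RNA reads with a 1.5-fold allelic-ratio
gate at 0.05 for expression, and a +/-10 kb GWAS window with <=0.15 MAF
difference for locus linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import List

import yaml

#: Free-text trait signatures used to query a GWAS-catalog extract for
#: cognition-related associations (case-insensitive substring match).
DEFAULT_TRAIT_SIGNATURES: List[str] = [
    "Alzheimer's disease",
    "autism",
    "autism spectrum disorder",
    "antipsychotic",
    "anxiety",
    "bipolar disorder",
    "cognitive",
    "depression",
    "depressive disorder",
    "Parkinson's disease",
    "posttraumatic",
    "schizophrenia",
]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with published defaults."""

    # --- het-SNP QC ---
    min_site_coverage: int = 10          # pooled high-quality reads per site
    min_base_quality: int = 20           # Phred; applied upstream of count extraction
    min_mapping_quality: int = 25        # MAPQ; applied upstream of count extraction
    indel_exclusion_bp: int = 5          # distance to indel regions
    cluster_window_bp: int = 10          # clustered-SNP window
    het_balance_alpha: float = 0.05      # binomial balance filter (QC)
    het_balance_use_adjusted: bool = False   # BH-adjust the balance p first
    min_reads_per_allele: int = 3
    min_supporting_samples: int = 2
    # --- allele-specific binding ---
    asb_alpha: float = 0.01
    asb_use_adjusted_p: bool = True      # threshold BH-adjusted p (flag: raw)
    asb_count_combine: str = "mean"      # mean | min | sum over the two alignments
    # --- target assignment ---
    promoter_flank_bp: int = 1800
    snp_window_bp: int = 1000
    chiapet_min_pairs: int = 20
    chiapet_min_per_direction: int = 10
    contact_alpha: float = 0.001
    contact_use_adjusted_p: bool = False
    # --- allele-specific expression ---
    min_rna_reads: int = 10
    ase_ratio_threshold: float = 1.5
    ase_alpha: float = 0.05
    ase_test: str = "binomial"           # binomial | fisher
    ase_use_adjusted_p: bool = False
    # --- GWAS linkage ---
    gwas_window_bp: int = 10000
    maf_max_diff: float = 0.15
    trait_signatures: List[str] = field(
        default_factory=lambda: list(DEFAULT_TRAIT_SIGNATURES)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "min_site_coverage", "min_base_quality", "min_mapping_quality",
            "cluster_window_bp", "min_reads_per_allele",
            "min_supporting_samples", "promoter_flank_bp", "snp_window_bp",
            "chiapet_min_pairs", "chiapet_min_per_direction", "min_rna_reads",
            "gwas_window_bp",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.indel_exclusion_bp < 0:
            raise ValueError("indel_exclusion_bp must be >= 0")
        for name in ("het_balance_alpha", "asb_alpha", "contact_alpha", "ase_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.ase_ratio_threshold <= 1.0:
            raise ValueError("ase_ratio_threshold must be > 1")
        if not 0.0 < self.maf_max_diff < 0.5:
            raise ValueError("maf_max_diff must lie in (0, 0.5)")
        if self.ase_test not in ("binomial", "fisher"):
            raise ValueError("ase_test must be 'binomial' or 'fisher'")
        if self.asb_count_combine not in ("mean", "min", "sum"):
            raise ValueError("asb_count_combine must be mean|min|sum")
        if not self.trait_signatures:
            raise ValueError("trait_signatures must be non-empty")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic input bundle.

    Defaults describe a small diploid toy genome with a 5% planted rate of
    allele-specific binding at allele fraction 0.7, overdispersed ~80x
    ChIP coverage with a 6% reference mapping bias of opposite sign under
    the two alignment references, 80% of regulated targets showing
    allele-specific expression at fraction 0.7, 40 planted chromatin loops
    over random-ligation noise, and a GWAS extract in which 30% of indexes
    tag planted rSNPs while every decoy violates exactly one linkage
    criterion.

    Allele-specific binding is experiment-specific, as it is for real
    transcription-factor ChIP compendia: the shifted allele fraction
    applies in exactly one of the ``n_samples`` ChIP experiments (the one
    whose factor's binding the variant perturbs), with peak-enrichment
    coverage there; every other experiment samples the site at 0.5.  The
    pooled evidence therefore still looks heterozygous, which is what
    lets true ASB sites survive the pooled heterozygosity balance filter.
    A few homozygote-like artifact sites (allele fraction
    ``artifact_fraction`` everywhere) give that filter genuine signal.
    """

    rng_seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 60
    n_otfrs: int = 300
    n_het_sites: int = 2000
    frac_asymmetric: float = 0.05
    asb_allele_fraction: float = 0.7
    coverage_mean: float = 80.0
    coverage_dispersion: float = 0.2     # negative-binomial overdispersion
    n_samples: int = 96                  # ChIP experiments covering each site
    effect_coverage_enrichment: float = 3.0  # peak enrichment in the effect ChIP
    n_balance_artifacts: int = 5         # homozygote-like QC artifact sites
    artifact_fraction: float = 0.98
    reference_bias: float = 0.06
    frac_targets_with_ase: float = 0.8
    ase_allele_fraction: float = 0.7
    rna_coverage_mean: float = 100.0
    markers_per_gene: int = 2
    n_chiapet_loops: int = 40
    chiapet_noise_pairs: int = 500
    n_gwas_indexes: int = 50
    frac_indexes_near_rsnps: float = 0.3
    maf_low: float = 0.05
    maf_high: float = 0.5
    frac_annotated: float = 0.6          # het SNPs carrying an rsID

    def __post_init__(self) -> None:
        for name in ("frac_asymmetric", "frac_targets_with_ase",
                     "frac_indexes_near_rsnps", "frac_annotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length_bp", "n_genes", "n_otfrs",
                     "n_het_sites", "n_chiapet_loops", "n_gwas_indexes",
                     "n_samples", "markers_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("asb_allele_fraction", "ase_allele_fraction"):
            v = getattr(self, name)
            if not 0.5 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0.5, 1)")
        if self.effect_coverage_enrichment < 1.0:
            raise ValueError("effect_coverage_enrichment must be >= 1")
        if self.n_balance_artifacts < 0:
            raise ValueError("n_balance_artifacts must be >= 0")
        if not 0.5 < self.artifact_fraction < 1.0:
            raise ValueError("artifact_fraction must lie in (0.5, 1)")
        if not 0.0 < self.maf_low < self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low < maf_high <= 0.5")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**data)
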