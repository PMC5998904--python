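"""Allele-specific binding: asymmetric-SNP detection inside OTFRs.

For each QC-passed heterozygous SNP lying in an OTFR and each ChIP
experiment covering it, the per-allele read counts obtained under the two
alignment references (standard and alternate genome) are combined --
arithmetic mean by default, which cancels an additive reference mapping
bias of opposite sign -- and tested against a 1:1 allelic ratio with the
exact two-sided binomial test.  P-values are Benjamini-Hochberg adjusted
across every (SNP, experiment) test of the run; a SNP significant in at
least one experiment is called asymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .het_qc import HetSNP, Observation
from .io_formats import Interval
from .reference_model import OtfrIndex


def benjamini_hochberg(pvals: Sequence[float]) -> List[float]:
    """Step-up FDR adjustment; input order preserved, values capped at 1."""
    if len(pvals) == 0:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bias_corrected_counts(observations: Sequence[Observation],
                          combine: str = "mean") -> Tuple[int, int]:
    """Combine one experiment's counts from the two alignment references.

    ``observations`` must hold exactly one record per alignment reference
    ('ref' and 'alt') for a single sample/experiment.  ``combine`` picks
    the symmetric combination: per-allele arithmetic mean rounded half-up
    (default), minimum, or sum.
    """
    by_aln = {o.alignment_ref: o for o in observations}
    if set(by_aln) != {"ref", "alt"}:
        raise ValueError(
            "bias correction needs counts under both alignment references; "
            f"got {sorted(by_aln)}")
    r1, a1 = by_aln["ref"].ref_count, by_aln["ref"].alt_count
    r2, a2 = by_aln["alt"].ref_count, by_aln["alt"].alt_count
    if combine == "mean":
        return _round_half_up((r1 + r2) / 2), _round_half_up((a1 + a2) / 2)
    if combine == "min":
        return min(r1, r2), min(a1, a2)
    if combine == "sum":
        return r1 + r2, a1 + a2
    raise ValueError(f"unknown combine mode {combine!r}")


@dataclass
class AsymmetricSNP:
    het_snp: HetSNP
    experiment_id: str
    ref_count: int
    alt_count: int
    raw_p: float
    adjusted_p: float

    @property
    def allele_ratio(self) -> float:
        return self.ref_count / self.alt_count if self.alt_count else float("inf")

    @property
    def site_id(self) -> str:
        return self.het_snp.site_id


def detect_asb(het_snps: Sequence[HetSNP], otfrs: Sequence[Interval],
               config: RunConfig) -> pd.DataFrame:
    """Per-(SNP, experiment) ASB tests for het SNPs inside OTFRs.

    Returns a frame with one row per test: chrom, pos, ref, alt, rsid,
    experiment, bias-corrected ref_count/alt_count, raw_p, adjusted_p and
    the ``asymmetric`` call (adjusted p below ``asb_alpha`` by default,
    raw p when ``asb_use_adjusted_p`` is off).  Sites outside every OTFR
    are excluded before testing.
    """
    index = OtfrIndex(otfrs)
    rows: List[dict] = []
    for h in het_snps:
        if not index.contains(h.site.chrom, h.site.pos):
            continue
        by_exp: Dict[str, List[Observation]] = {}
        for o in h.site.observations:
            by_exp.setdefault(o.sample_id, []).append(o)
        for exp_id in sorted(by_exp):
            obs = by_exp[exp_id]
            if {o.alignment_ref for o in obs} != {"ref", "alt"}:
                continue                       # experiment lacks dual alignment
            ref_c, alt_c = bias_corrected_counts(obs, config.asb_count_combine)
            n = ref_c + alt_c
            if n == 0:
                continue
            rows.append({
                "chrom": h.site.chrom, "pos": h.site.pos,
                "ref": h.site.ref_allele, "alt": h.site.alt_allele,
                "rsid": h.site.rsid or ".",
                "experiment": exp_id,
                "ref_count": ref_c, "alt_count": alt_c,
            })
    columns = ["chrom", "pos", "ref", "alt", "rsid", "experiment",
               "ref_count", "alt_count", "raw_p", "adjusted_p", "asymmetric"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    from .het_qc import binomial_two_sided_balanced
    df["raw_p"] = binomial_two_sided_balanced(
        df["ref_count"].to_numpy(),
        (df["ref_count"] + df["alt_count"]).to_numpy())
    df["adjusted_p"] = benjamini_hochberg(df["raw_p"].tolist())
    which = df["adjusted_p"] if config.asb_use_adjusted_p else df["raw_p"]
    df["asymmetric"] = which < config.asb_alpha
    return df[columns]


def asymmetric_sites(asb_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-experiment tests to SNP level: any significant experiment.

    Keeps, per asymmetric SNP, the counts of its most significant
    experiment (smallest raw p).
    """
    sig = asb_table[asb_table["asymmetric"]]
    if sig.empty:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "rsid",
                                     "best_experiment", "ref_count",
                                     "alt_count", "raw_p", "adjusted_p"])
    best = (sig.sort_values(["raw_p", "experiment"])
               .groupby(["chrom", "pos"], as_index=False, sort=False)
               .first()
               .rename(columns={"experiment": "best_experiment"}))
    best = best.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return best[["chrom", "pos", "ref", "alt", "rsid", "best_experiment",
                 "ref_count", "alt_count", "raw_p", "adjusted_p"]]
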