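"""Exact recovery-power computation for planted regulatory effects.

Computes, per planted site, the probability that the pipeline's fixed
raw-p thresholds detect it, from binomial probability mass alone (no
simulation, no pipeline code):

* ASB: the dual-alignment combined count is a deterministic function of
  the sum s of the two alignment-reference draws (rounded half-up mean:
  combined ref = ceil(s/2), combined total = n for even s and n+1 for
  odd s, when both draws share coverage n), so the per-experiment
  detection probability is an exact sum over the convolution of
  Binomial(n, f + b) and Binomial(n, f - b).  A site is detected when at
  least one experiment is significant; balanced experiments contribute
  their attained false-positive level.
* ASE: a gene is confirmed when at least one RNA marker passes both the
  fold-ratio gate and the exact binomial p gate; per-marker probability
  is an exact binomial tail sum at the planted expression fraction.

These probabilities are the independent yardstick for end-to-end
parameter-recovery checks: recovery of a planted rSNP requires its ASB
detection and its target gene's ASE confirmation, which use disjoint
data and multiply.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .config import RunConfig
from .synthetic_data import TruthManifest


def _two_sided_p_balanced(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    lo = np.minimum(k, n - k)
    hi = np.maximum(k, n - k)
    return np.minimum(binom.cdf(lo, n, 0.5) + binom.sf(hi - 1, n, 0.5), 1.0)


@lru_cache(maxsize=100_000)
def asb_detection_power(n: int, f: float, bias: float, alpha: float) -> float:
    """P(combined-count exact test rejects at raw ``alpha``) for one experiment.

    ``n`` is the experiment's coverage (shared by the two alignments),
    ``f`` the true ref-allele fraction, ``bias`` the additive mapping-bias
    shift (+ under the reference alignment, - under the alternate).
    With f = 0.5 this is the attained size of the test at ``alpha``.
    """
    if n < 1:
        return 0.0
    p1 = min(1.0, max(0.0, f + bias))
    p2 = min(1.0, max(0.0, f - bias))
    pmf_s = np.convolve(binom.pmf(np.arange(n + 1), n, p1),
                        binom.pmf(np.arange(n + 1), n, p2))
    s = np.arange(2 * n + 1)
    k_comb = (s + 1) // 2                       # round-half-up mean of s/2
    m = np.where(s % 2 == 0, n, n + 1)          # combined total
    pvals = _two_sided_p_balanced(k_comb, m)
    return float(pmf_s[pvals < alpha].sum())


def asb_site_power(coverages: Sequence[int], effect_index: int, f: float,
                   bias: float, alpha: float) -> float:
    """P(ASB significant in >= 1 experiment) for one site.

    ``coverages`` are the realized per-experiment coverages; the
    experiment at ``effect_index`` carries fraction ``f``, the others 0.5.
    """
    miss = 1.0
    for i, n in enumerate(coverages):
        fi = f if i == effect_index else 0.5
        miss *= 1.0 - asb_detection_power(int(n), float(fi), bias, alpha)
    return 1.0 - miss


@lru_cache(maxsize=10_000)
def ase_marker_power(n: int, f: float, ratio_threshold: float,
                     alpha: float) -> float:
    """P(marker flagged): fold-ratio gate AND exact binomial p <= alpha."""
    if n < 1:
        return 0.0
    k = np.arange(n + 1)
    ratio = np.where(k < n, k / np.maximum(n - k, 1), np.inf)
    gate = (ratio > ratio_threshold) | (ratio < 1.0 / ratio_threshold)
    pvals = _two_sided_p_balanced(k, np.full_like(k, n))
    ok = gate & (pvals <= alpha)
    return float(binom.pmf(k, n, f)[ok].sum())


def gene_ase_power(marker_totals: Sequence[int], f: float,
                   ratio_threshold: float, alpha: float) -> float:
    miss = 1.0
    for n in marker_totals:
        miss *= 1.0 - ase_marker_power(int(n), float(f), ratio_threshold, alpha)
    return 1.0 - miss


def _balance_rejection_bounds(n_total: int, cutoff: float) -> Tuple[int, int]:
    """Largest acceptance interval [lo, hi] of pooled ref counts.

    The pooled balance test rejects when the exact two-sided p against
    Bin(n_total, 0.5) falls below ``cutoff``; by symmetry the acceptance
    region is an interval around n_total/2 whose edges are found from the
    binomial quantile and refined exactly.
    """
    guess = int(binom.isf(min(0.5, cutoff / 2), n_total, 0.5))
    hi = guess + 4
    while hi > n_total // 2:
        p = _two_sided_p_balanced(np.array([hi]), np.array([n_total]))[0]
        if p < cutoff:
            hi -= 1
        else:
            break
    return n_total - hi, hi


def qc_balance_survival_given_effect(coverages: Sequence[int],
                                     effect_index: int, f: float,
                                     bias: float, cutoff: float,
                                     s_grid: np.ndarray) -> np.ndarray:
    """P(pooled balance test accepts | effect-experiment ref sum = s).

    The pooled ref count is s plus the rest of the pool; the rest sums
    ~2(S-1) large binomials and is treated as normal with its exact mean
    and variance (the pool holds thousands of reads, so the approximation
    error is negligible next to the per-site Bernoulli noise).
    """
    n_total = int(2 * np.sum(coverages))
    mu_rest, var_rest = 0.0, 0.0
    for i, n in enumerate(coverages):
        if i == effect_index:
            continue
        for p in (0.5 + bias, 0.5 - bias):
            mu_rest += n * p
            var_rest += n * p * (1 - p)
    lo, hi = _balance_rejection_bounds(n_total, cutoff)
    sd = np.sqrt(max(var_rest, 1e-9))
    from scipy.stats import norm
    upper = norm.cdf((hi + 0.5 - s_grid - mu_rest) / sd)
    lower = norm.cdf((lo - 0.5 - s_grid - mu_rest) / sd)
    return np.clip(upper - lower, 0.0, 1.0)


def site_recovery_power(coverages: Sequence[int], effect_index: int,
                        f: float, bias: float, asb_alpha: float,
                        balance_cutoff: Optional[float]) -> float:
    """P(site passes the pooled balance filter AND shows ASB somewhere).

    Joint over the effect experiment's dual-alignment ref sum s: the ASB
    indicator is a deterministic function of s, and the balance test
    couples to it through the pooled count.  Balanced experiments add
    their attained false-positive level independently.
    """
    n_eff = int(coverages[effect_index])
    p1 = min(1.0, max(0.0, f + bias))
    p2 = min(1.0, max(0.0, f - bias))
    pmf_s = np.convolve(binom.pmf(np.arange(n_eff + 1), n_eff, p1),
                        binom.pmf(np.arange(n_eff + 1), n_eff, p2))
    s = np.arange(2 * n_eff + 1)
    k_comb = (s + 1) // 2
    m = np.where(s % 2 == 0, n_eff, n_eff + 1)
    asb_eff = _two_sided_p_balanced(k_comb, m) < asb_alpha

    miss_null = 1.0
    for i, n in enumerate(coverages):
        if i != effect_index:
            miss_null *= 1.0 - asb_detection_power(int(n), 0.5, bias, asb_alpha)
    asb_prob = np.where(asb_eff, 1.0, 1.0 - miss_null)

    if balance_cutoff is None:
        qc = np.ones_like(s, dtype=float)
    else:
        qc = qc_balance_survival_given_effect(coverages, effect_index, f,
                                              bias, balance_cutoff, s)
    return float(np.sum(pmf_s * qc * asb_prob))


def site_balance_rejection(coverages: Sequence[int], effect_index: int,
                           f: float, bias: float, cutoff: float) -> float:
    """Marginal P(pooled balance p below cutoff) for a planted site."""
    n_eff = int(coverages[effect_index])
    p1 = min(1.0, max(0.0, f + bias))
    p2 = min(1.0, max(0.0, f - bias))
    pmf_s = np.convolve(binom.pmf(np.arange(n_eff + 1), n_eff, p1),
                        binom.pmf(np.arange(n_eff + 1), n_eff, p2))
    s = np.arange(2 * n_eff + 1)
    qc = qc_balance_survival_given_effect(coverages, effect_index, f, bias,
                                          cutoff, s)
    return float(np.sum(pmf_s * (1.0 - qc)))


def estimate_bh_balance_cutoff(planted_sites, coverages_by_site,
                               bias: float, alpha: float, n_family: int,
                               n_certain_rejections: int,
                               iterations: int = 4) -> float:
    """Self-consistent raw-p cutoff of the BH-adjusted balance filter.

    The step-up rule rejects down to p <= alpha*k/m where k is the
    rejection count; artifacts (near-homozygous sites) are certain
    rejections, planted sites contribute their marginal rejection
    probabilities, and balanced nulls contribute essentially nothing at
    these cutoffs.  A few fixed-point iterations converge.
    """
    k = float(n_certain_rejections)
    cutoff = alpha * max(k, 1.0) / n_family
    for _ in range(iterations):
        k_planted = 0.0
        for site in planted_sites:
            covs = coverages_by_site[site.site_id]
            idx = int(site.effect_sample.lstrip("S")) - 1
            fmag = max(site.true_fraction, 1 - site.true_fraction)
            k_planted += site_balance_rejection(covs, idx, fmag, bias, cutoff)
        cutoff = alpha * max(n_certain_rejections + k_planted, 1.0) / n_family
    return cutoff


def coverages_from_counts(counts) -> Dict[str, List[int]]:
    """Realized per-experiment coverage per site, from the allele-count table.

    The two alignment references recount the same reads, so the
    reference-alignment total is the experiment's coverage.  Experiments
    are ordered by sample id, matching the manifest's sample naming.
    """
    ref_rows = counts[counts["alignment_ref"] == "ref"]
    out: Dict[str, List[int]] = {}
    grouped = ref_rows.sort_values("sample_id").groupby(["chrom", "pos"],
                                                        sort=True)
    for (chrom, pos), g in grouped:
        out[f"{chrom}:{pos}"] = list((g["ref_count"] + g["alt_count"])
                                     .to_numpy(dtype=int))
    return out


def planted_recovery_power(manifest: TruthManifest,
                           coverages_by_site: Dict[str, List[int]],
                           config: RunConfig,
                           reference_bias: float,
                           ase_fraction: float) -> Dict[str, float]:
    """Exact per-site recovery probability for every planted rSNP.

    ``coverages_by_site`` maps site id to realized per-experiment
    coverages ordered like the manifest's sample naming; the effect
    experiment is taken from the manifest.  The fold direction of a
    planted fraction is irrelevant by the symmetry of the tests, so
    powers are evaluated at max(f, 1-f).

    Recovery requires surviving the pooled heterozygosity balance filter,
    detecting ASB in at least one experiment, and confirming the target
    gene's ASE; the first two are computed jointly over the effect
    experiment's counts (they share data), the third multiplies in
    independently.  The balance filter's effective raw-p cutoff is the
    configured alpha when thresholding raw p-values, or the
    self-consistent step-up cutoff when BH adjustment is enabled.
    """
    planted = [p for p in manifest.planted_asymmetric]
    n_artifacts = len(manifest.qc_exercise.get("balance_artifact", []))
    n_family = len(coverages_by_site)
    if config.het_balance_use_adjusted:
        cutoff = estimate_bh_balance_cutoff(planted, coverages_by_site,
                                            reference_bias,
                                            config.het_balance_alpha,
                                            n_family, n_artifacts)
    else:
        cutoff = config.het_balance_alpha

    out: Dict[str, float] = {}
    gene_power: Dict[str, float] = {}
    for gene in manifest.regulated_genes:
        totals = manifest.rna_marker_coverage.get(gene, [])
        gene_power[gene] = gene_ase_power(totals, max(ase_fraction,
                                                      1 - ase_fraction),
                                          config.ase_ratio_threshold,
                                          config.ase_alpha)
    for site in planted:
        if not site.regulated:
            continue
        covs = coverages_by_site[site.site_id]
        sample_index = int(site.effect_sample.lstrip("S")) - 1
        f = max(site.true_fraction, 1 - site.true_fraction)
        p_asb = site_recovery_power(covs, sample_index, f, reference_bias,
                                    config.asb_alpha, cutoff)
        out[site.site_id] = p_asb * gene_power[site.target_gene]
    return out
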