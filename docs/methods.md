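# Methods

## The procedure

`regsnp-scout` implements a discovery funnel for regulatory SNPs (rSNPs)
from allele-specific signals in functional-genomics read data:

1. **Heterozygous-SNP calling and QC.** Candidate biallelic SNVs with
   per-sample, per-alignment-reference allele counts are filtered:
   sites on sex chromosomes, mitochondrial DNA or repeats; sites within
   5 bp of insertion/deletion footprints; clustered sites (≥ 2 other
   sites within 10 bp, evaluated on the pre-filter set and removed
   simultaneously); sites with pooled depth < 10, < 3 reads per allele,
   or support from < 2 samples or only one alignment reference; and
   sites whose pooled ref:alt counts are incompatible with
   heterozygosity (exact two-sided binomial test against 0.5 at
   α = 0.05). Each removal is logged under its first failing filter.
2. **Allele-specific binding (ASB).** For every retained het SNP inside
   an OTFR (a region bound by two or more transcription factors) and
   every ChIP experiment covering it, the per-allele counts obtained
   under the standard and the alternate reference genome are combined —
   arithmetic mean, rounded half-up — and tested against a 1:1 ratio
   with the exact two-sided binomial test. P-values are
   Benjamini–Hochberg adjusted across all (SNP, experiment) tests; a
   SNP significant in at least one experiment (default: adjusted
   p < 0.01) is an *asymmetric SNP*.
3. **Target genes.** Proximal targets: genes whose promoter (±1.8 kb of
   the TSS, strand-invariant, inclusive), intron or UTR contains the
   SNP; CDS-exonic positions receive no proximal target. Distal
   targets: a contact matrix over ±1 kb SNP windows × gene promoters is
   filled from ChIA-PET contacts retained at ≥ 20 total pairs, ≥ 10
   pairs per read orientation, intrachromosomal, disjoint anchors. The
   random-ligation expectation for a cell is
   `E_ij = T · (len_i/G_eff) · (len_j/G_eff) · 2`, with `T` the total
   retained pair count and `G_eff` the effective genome size — the mean
   merged RNA Pol II peak area over datasets. A cell is a reliable
   contact when the 1-df Pearson goodness-of-fit p is below 0.001 with
   enrichment (O > E); cells whose window intersects the promoter are
   excluded. Proximal and distal assignments are united, deduplicated
   per (SNP, gene) with proximal evidence preferred.
4. **Allele-specific expression (ASE).** Each targeted gene is measured
   at exonic heterozygous markers in its CDS with ≥ 10 RNA reads
   (asymmetric SNPs sitting in promoters/UTRs serve as their own
   markers). A marker shows ASE when the allelic ratio is strictly
   above 1.5 (or below 1/1.5) *and* the exact binomial p against 0.5 is
   ≤ 0.05 (Fisher's exact test of RNA vs pooled DNA counts is the
   configurable alternative). BH-adjusted values are always reported.
   An asymmetric SNP with ≥ 1 confirmed target is an rSNP; variants
   without an rsID are displayed as `chrN:pos`.
5. **GWAS linkage.** A catalog extract is filtered by twelve
   case-insensitive trait signatures covering cognition-related
   disorders; an rSNP is linked to an index SNP within ±10 kb on the
   same chromosome when their minor allele frequencies differ by at
   most 0.15 (absolute frequency units, inclusive). The report has one
   row per (rSNP, targeted gene, index, trait); the summary counts
   unique rSNPs and unique targeted genes.

## Statistical notes

**Exact two-sided binomial test.** The minimum-likelihood convention is
used (sum of probabilities of outcomes no more likely than the observed
one); at p₀ = 0.5 this equals `2·min(P(X≤k), P(X≥k))` capped at 1. The
test is conservative by discreteness: its attained size at nominal 0.01
varies between ~0.005 and ~0.0099 with coverage, so empirical
false-positive rates on null data sit *below* 0.01 — the calibration
tests compare against the exactly computed attained level, not the
nominal one.

**Dual-alignment averaging.** Averaging the counts obtained under the
two alignment references cancels an additive reference-mapping bias of
opposite sign exactly in expectation. It also halves the sampling
variance of the combined count relative to a single binomial draw of
the same depth, which makes the nominal binomial test conservative on
combined counts and correspondingly *raises* its power at a fixed
cutoff for true effects. The closed-form power computations in
`regsnp_scout.power` model the combined count exactly via the
convolution of the two binomial draws (the rounded-mean combination is
a deterministic function of their sum).

**QC balance vs ASB.** The heterozygosity balance filter and the ASB
test both ask whether ref:alt counts deviate from 1:1, at α = 0.05 and
0.01 respectively. They are only jointly meaningful because they
operate at different granularity: the balance filter pools evidence
over *all* experiments, where a genuine binding effect — present only
in the ChIP of the factor whose site the variant perturbs — is diluted
toward 0.5, while the ASB test works per experiment, where the effect
is undiluted. A site imbalanced in the pooled evidence looks
homozygous or copy-number-distorted and is discarded. Because the
pooled test still removes ~5% of perfect nulls (and a data-dependent
share of diluted true signals) at a raw 0.05 cutoff, the filter can
optionally be applied to BH-adjusted p-values
(`het_balance_use_adjusted`), confining removal to gross artefacts;
the recovery analyses in `analysis/` use this option, together with
raw-p ASB thresholding (`asb_use_adjusted_p=False`), so that observed
recovery is comparable to the exact fixed-cutoff power.

**Multiple testing.** BH adjustment is applied within three separate
families — the pooled balance tests (optional), the (SNP, experiment)
ASB tests, and the ASE markers. Contact-matrix cells are not adjusted
by default (configurable), as the chi-squared cutoff of 0.001 with an
enrichment requirement is already stringent under the random-ligation
null.

## Tunable parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `min_site_coverage` | 10 | pooled reads per site |
| `min_base_quality`, `min_mapping_quality` | 20, 25 | Phred / MAPQ, applied upstream of count extraction |
| `indel_exclusion_bp` | 5 | bp to nearest indel footprint |
| `cluster_window_bp` | 10 | bp window for the clustered-SNP rule |
| `het_balance_alpha` | 0.05 | pooled heterozygosity balance test |
| `min_reads_per_allele`, `min_supporting_samples` | 3, 2 | allele/sample support |
| `asb_alpha` | 0.01 | ASB significance (BH-adjusted by default) |
| `promoter_flank_bp` | 1800 | promoter half-width around the TSS |
| `snp_window_bp` | 1000 | ChIA-PET SNP-window half-width |
| `chiapet_min_pairs`, `chiapet_min_per_direction` | 20, 10 | contact filters |
| `contact_alpha` | 0.001 | contact reliability |
| `min_rna_reads` | 10 | RNA depth per marker |
| `ase_ratio_threshold`, `ase_alpha` | 1.5, 0.05 | ASE gates (ratio strict, p inclusive) |
| `gwas_window_bp`, `maf_max_diff` | 10000, 0.15 | linkage window and MAF tolerance (inclusive) |

## The synthetic study

The generator (`regsnp_scout.synthetic_data.simulate`) emits every
input the pipeline consumes, with planted truth recorded in a manifest.
Default conditions: two 1-Mb chromosomes (plus a small chrX to exercise
the blacklist), 60 non-overlapping genes with four exons and terminal
UTRs, 300 OTFRs, 2,000 heterozygous sites of which 5% carry a true
allele fraction of 0.7 (random direction), negative-binomial coverage
(mean 80, dispersion 0.2) over 96 ChIP experiments, and a ±0.06
reference-mapping bias under the two alignments.

Design choices worth stating:

* **Experiment-specific binding effects.** Each planted site's shifted
  fraction applies in exactly one experiment — the ChIP of the factor
  whose binding it perturbs — with 3× peak-enrichment coverage there;
  all other experiments sample it at 0.5. This mirrors how a variant
  disrupting one factor's motif behaves in a heterogeneous ChIP
  compendium and is what lets true ASB sites pass the pooled balance
  filter (pooled imbalance z ≈ 5.06·E/√(S−1+E) ≈ 1.5 at E = 3,
  S = 96). Five homozygote-like artifact sites (fraction 0.98
  everywhere) give the balance filter genuine signal.
* **Targets and expression.** 60 planted sites are placed in
  promoters/introns/UTRs of distinct genes; 40 are deep intergenic and
  joined to a promoter > 10 kb away by a ChIA-PET loop (≥ 24 pairs,
  balanced orientations) over ~500 random-ligation noise contacts. 80%
  of planted sites have a *regulated* target: its two CDS markers
  (~100× RNA depth) are drawn at fraction 0.7; all other genes' markers
  are balanced. Planted sites with a regulated target are the planted
  rSNPs.
* **GWAS extract.** 30% of 50 indexes tag planted rSNPs (within ±10 kb,
  MAF within 0.12, cognition-related trait); every decoy violates
  exactly one linkage criterion (wrong trait, outside the window with
  respect to *all* planted sites, or MAF off by 0.2), so each criterion
  is individually exercised.
* A handful of extra sites exercise each QC filter (sex chromosome,
  repeat, clustered triplet, indel-proximal, sub-threshold depth).

What the generator does **not** emulate: read-level data (counts are
drawn directly), sequence-dependent mapping artefacts, linkage
disequilibrium and haplotype structure, phasing between regulatory and
marker alleles, allele-count overdispersion beyond binomial sampling
(no beta-binomial), isoform structure, or population variation across
individuals. Passing end-to-end tests therefore demonstrates the
correctness and calibration of the statistical machinery under its own
model, not robustness to these real-data complications.

## Numerical choices

* Intervals are 0-based half-open; point positions 1-based; membership
  converts `pos → pos−1`. Promoter windows are inclusive at both ends
  in 1-based space and clamped at chromosome bounds.
* Combined dual-alignment counts round half-up per allele; allelic
  ratios with a zero denominator are +∞ (flag-eligible).
* The clustered filter is inclusive (≤ 10 bp), symmetric, and applied
  simultaneously against the pre-filter set; iterative removal would be
  order-dependent.
* Filter order is fixed (blacklist → clustered → indel → support →
  balance) so funnel logs are reproducible; ties in canonical-transcript
  selection break lexicographically.
* Per-site recovery power is computed exactly (binomial pmfs and one
  convolution per experiment). Survival of the pooled balance filter is
  modeled jointly with ASB detection over the effect experiment's
  counts; the rest of the pool (thousands of reads) enters through a
  normal approximation with exact mean and variance, and the step-up
  filter's effective cutoff is obtained by a short fixed-point
  iteration over the expected rejection count. The only stochastic
  residual is per-site Bernoulli noise (~2–3 percentage points on the
  mean over ~90 planted sites).
* Problem sizes in the shipped analyses: 2,000 sites × 96 experiments
  for the end-to-end study, 20,000 draws for null calibration, ≥ 100
  random instances per brute-force oracle comparison.

## Open design points resolved here

* The ASE test defaults to the binomial test against 0.5, with
  Fisher's test vs pooled DNA counts as the alternative; the
  significance gate defaults to raw p ≤ 0.05 (adjusted values are
  computed and reported).
* Promoters use the canonical (longest) transcript's TSS.
* MAF similarity is an absolute difference ("15%" read as 0.15 in
  frequency units), and the MAF criterion applies to every reported
  row; MAFs are inputs, not live lookups.
* "Both directions" for ChIA-PET filtering is read as read
  orientation; forward + reverse counts partition the total.
* The contact-null constant 2 in `E_ij` reflects the two orientations
  in which a ligation product can span an (i, j) pair.

## Limitations

The per-experiment ASB model treats experiments as independent; shared
cell-line genotypes or copy-number changes would correlate them. The
random-ligation contact null ignores genomic-distance decay, which
real ChIA-PET backgrounds show. Window-plus-MAF linkage is a proxy for
LD, not a substitute for it. The exact binomial machinery is
deliberately simple — overdispersion-aware models (beta-binomial) are
a natural extension and are out of scope here.
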