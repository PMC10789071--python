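# Methods

## Candidate elements

ATAC peaks are ranked per ancestry by read count summed over that ancestry's
samples, the top k (default 150,000; a synthetic run keeps all) resized to
500 bp around the summit (clipped, not shifted, at contig edges), and the two
rankings interleaved evenly — AFR₁, EUR₁, AFR₂, … — so both ancestries
contribute equally regardless of depth. Overlapping intervals are merged at
each step (union); a merged element keeps the best interleaved position of
its constituents (the rule is ours; ties in ranking break by coordinate for
determinism). 500-bp TSS-centered windows are then added, merged, and
anything overlapping a blacklist interval by ≥ 1 bp removed. An element is a
*promoter* iff it overlaps a window [TSS − 500, TSS + 500] for some gene —
an interval-overlap reading of "within 500 bp of a TSS", chosen because the
TSS regions are themselves 500-bp windows; the same rule decides per pair
whether an element is a promoter *for that gene*, so a distal promoter acts
as an enhancer for other genes' pairs.

## Score decomposition

All components are quantile-normalized to the across-sample mean
distribution, separately for enhancer-class and promoter-class features
(ATAC RPM per element; HiChIP 5-kb bin totals; connecting bin-pair counts).
Ties receive the average of the tied reference values, so each sample's
marginal is exactly the common reference. A bin holding both classes counts
as promoter-class (promoter signal dominates); a bin pair is promoter-class
if either end is. Elements map to bins by midpoint (deterministic when a
500-bp element straddles two bins); self-pairs use the diagonal bin count.
RPM uses supplied library sizes when given, otherwise total counts over all
peaks (documented fallback). The four scores follow the displayed formulas
exactly; a zero denominator yields all-zero scores for that gene rather than
an error, matching the downstream filters that remove such genes; a bin with
contacts but zero total is rejected as inconsistent data. The 5-Mb window is
measured TSS-to-element-midpoint. The promoter-pair 0.1 filter applies "in
at least one sample", consistent with the 0.015 rule; the nonzero-support
filter applies to all pairs (a promoter pair passing 0.1 has support in that
sample anyway).

## Differential testing and FDR

Welch (unequal-variance) t-tests compare 8 AFR vs 6 EUR samples per pair and
score type; the Welch form is used because the gene-ranking statistic is the
Welch statistic. Degenerate pairs (both group variances zero) give t = 0,
P = 1 when means agree and the smallest positive double with a flag when
they differ; a group mean of exactly zero flags the log2FC as a signed
infinity and such pairs are excluded from fold-change summaries. The FDR at
α is (#null positives per shuffle) / (#real positives), NA when the
denominator is zero and capped at 1 for reporting. The shuffle null draws,
per pair, one AFR population whose two replicates both join the group of
eight; every other population contributes one replicate to each group,
preserving the 8-vs-6 structure. One shuffle per pair per run by default
(`n_shuffles` raises precision); all shuffles are seeded and the seed
recorded. ChIP/HiC calls sharing a 5-kb bin are collapsed to the lowest-P
representative before any CRE-level counting, since bin-resolution signal
makes them one observation.

## Enrichment framework

Every 2×2 uses one count per CRE. The DE tests take the most differential
CRE per gene (lowest P, ties to larger |log2FC|, then coordinate), collapse
to unique CREs, and cross diff status (P < 0.05 vs P ≥ 0.5; the middle
excluded) with DE-target status (≥ 1 target gene at LFSR < 0.05). The
promoter stratum restricts to promoter CREs and requires promoter-for-target;
the enhancer stratum requires promoter-for-none-of-its-DE-targets. Direction
tests use diff-CREs whose DE targets agree in sign and cross CRE direction
with DE direction, so OR > 1 means matching; the same layout serves the bQTL
direction tests (high-affinity-allele frequency AFR > EUR defines QTL
direction; CREs whose QTL disagree are excluded; the lowest-P QTL represents
a CRE; an optional F_ST floor restricts to top-quantile QTL). The reported
OR is the sample estimate ad/bc (∞ when bc = 0) with an exact one-sided 95%
lower bound from inverting Fisher's noncentral hypergeometric distribution —
stated explicitly because standard implementations differ (R's `fisher.test`
reports the conditional-MLE OR). Degenerate universes return NA results with
a warning instead of raising, so a small run can report all tests.
Significance stars follow Bonferroni-corrected thresholds 0.05 / 0.005 /
5e-4 / 5e-5.

## F_ST

Per-site Weir–Cockerham (1984) θ̂ = a/(a+b+c) over two groups: the pooled
AFR and pooled EUR samples (subpopulation tallies are summed before
estimation; the two-group pooling is our reading of the between-continent
contrast). Sites with a+b+c = 0 are undefined and dropped; negative
estimates clamp to zero, so output is in [0,1]. Observed heterozygote counts
enter c directly, which is why the generator emits genotype tallies (HWE
multinomial draws), not just frequencies. Wilcoxon comparisons are one-sided
rank-sum tests, exact when both groups are ≤ 50 and tie-free, otherwise
mid-rank normal approximation with continuity correction. Decile binning
ranks the combined diff + non-diff set by mean AFR/EUR allele frequency and
cuts ten equal-count bins (boundary ties broken by rank; a constant
frequency vector collapses to one bin); empirical quantiles use linear
interpolation. iHS-style comparisons reuse `wilcoxon_compare` on any
per-CRE score; computing iHS itself is out of scope.

## Synthetic data

The generator emulates a pooled two-ancestry LCL design: 4 AFR + 3 EUR
populations × 2 replicates, each pool treated as a single sample with count
noise (no within-pool growth variance is modelled). Defaults, and why:

- **Genome** — 6 chromosomes × 52 Mb, 2,184 genes (≥ 10 kb TSS spacing),
  7,000 peaks (one promoter peak per TSS plus uniform distal peaks). This
  shape yields ≈ 9,000 filtered pairs at ≈ 4 pairs per gene and ≈ 1.7 pairs
  per element — the pair multiplicity of genuine ABC maps — and ≈ 5,000
  distinct elements, enough quasi-independent units for the calibration
  checks below. Gene density is lower than a real genome; dense gene
  neighbourhoods (promoter competition, shared enhancers at high
  multiplicity) are under-represented.
- **ATAC counts** — negative binomial around lognormal per-peak means
  (mean 100 reads, promoters ×3), dispersion k = 40, per-sample lognormal
  depth (σ = 0.2). k = 40 reflects replicates that are re-grown libraries of
  identical cell pools, much tighter than cross-individual designs.
- **Contacts** — expected count = depth · exp(−rate·distance) · anchor
  enrichments, rate 5e-5/bp (signal dies by ~200 kb; steeper than genomic
  power-law decay but it concentrates pairs at realistic enhancer–gene
  distances), depth 20 at the diagonal, ×3 boosts at element bins and ×5 at
  TSS bins for H3K27ac, truncated at 800 kb (expected counts beyond are
  ≪ 1). Counts are gamma-Poisson: each library draws per-bin visibility
  factors (CV 0.15) multiplying both anchors — the standard overdispersion
  model for proximity-ligation counts. A side effect of the steep decay is
  that ABC mass concentrates heavily on promoter-proximal elements; real
  maps spread contact mass wider.
- **Injected effects** — a fraction (default 0.1) of distal peaks with a
  target gene within 150 kb get a channel (atac / chip / hic, round-robin)
  and an ancestry sign. atac multiplies the peak's count mean by 2^lfc in
  that ancestry; chip multiplies every contact touching the peak's bin (the
  diagonal once, so the bin marginal scales by exactly 2^lfc); hic
  multiplies the single element–promoter bin pair. Flagged pairs get an
  expected-count floor of 3 and at least one observed contact per sample so
  injected truth stays observable.
- **Variants** — Balding–Nichols: ancestral frequency ~ U(0.05, 0.95),
  per-ancestry Beta draws with F = `divergence_param` (F = 0 collapses to
  identical frequencies); 50 diploids per population, HWE genotype
  multinomials. In-element variants become bQTL (six QTL types) with
  probability 0.4; each flagged element is guaranteed one. With probability
  `coupling` a flagged element's bQTL high-affinity allele is set to the
  truth ancestry's higher-frequency allele, otherwise chosen at random — so
  coupling = 1 forces 100% direction match and coupling = 0 leaves direction
  independent of truth.
- **DE tables** — 22 cellular contexts; truth-target genes are DE
  (LFSR ~ U(0, 0.05)) with the injected sign with probability
  `de_match_prob` (default = coupling) and the opposite sign otherwise;
  all other genes draw LFSR ~ U(0.05, 1).

Same config + same seed reproduces every table byte-for-byte: each stage
derives its RNG from (seed, stage index).

## What the calibrations do and do not show

With no injected effects and no divergence, per-pair Welch P-values are
uniform and the shuffle FDR ≈ 1. Two facts shape how this is verified.
First, pairs sharing an element (or, for ChIP/HiC, a 5-kb bin) are
near-identical tests, so uniformity is assessed on de-duplicated units —
one pair per element for ABC/ATAC, one per bin for ChIP/HiC — the same
reasoning behind the bin-level dedup in the enrichment counting. Second,
the t-test itself is only calibrated at n = 8 + 6 when the per-pair sample
distribution is not strongly skewed; the default noise levels keep
sample-level score skew ≲ 0.4, which the pooled-replicate design supports.
Noisier designs (cross-individual samples, shallow libraries) would need
the permutation FDR rather than nominal P-values — which is exactly the
role the shuffle FDR plays. The exact one-sided Fisher tests are
conservative on small discrete tables, so their null rejection rate sits at
or below the nominal 5%. Passing these checks shows the machinery is
correct and calibrated under the stated generative model; it does not show
that real LCL data satisfy that model.

## Numerical notes

Quantile normalization with many zeros maps zeros to zero as long as the
zero-fraction is balanced across samples (the reference order statistics at
those ranks are zero). The ChIP×HiC decomposition identity holds to
floating-point rounding (≤ 1 ulp, asserted at 1e-12). Fixed-difference F_ST
is exactly 1.0 for equal group sizes; unequal sizes can leave one part in
1e-16 of cancellation error. The CI lower bound solves
P_ψ(X ≥ a) = 0.05 by bisection in log ψ over ψ ∈ [e⁻⁵⁰, e⁵⁰]; a at the
bottom of its support returns 0, and a table whose tail cannot reach 0.05
returns ∞.
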