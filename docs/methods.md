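# Methods

This note records the models, conventions, parameter choices and known
limitations behind `medipgmr`. Coordinates are 0-based half-open
internally; report tables print 1-based inclusive positions.

## The GMR statistic

At one nucleotide, with per-animal read counts NRᵢ (i = 1..n),

    GMR = exp( meanᵢ ln(NRᵢ + 1) − ln 2 / n ),    GMR := 0 if all NRᵢ = 0.

The correction −ln 2⁄n generalizes the six-cow form ln 2⁄6 so the anchor
property (one read in one animal ⇒ GMR = 1) holds for any cohort size.
GMR is permutation-invariant in animal order, non-decreasing in every
count, and equals (x+1)·2^(−1/n) when all n animals have x reads.

## Gene-body profile

Standardized lengths default to the medians of the supplied gene set
(recomputed per run; the reference bovine medians 159/128/503 bp for
first/middle/last exons and 2616/1343 bp for first/last introns can be
passed as overrides). The position map for an element of length k onto
standardized length L:

* k = L — identity;
* k > L — positions 1..⌊L/2⌋ and the last ⌊L/2⌋ map base-for-base onto the
  flanks; the interior collapses onto slot ⌊L/2⌋+1;
* k < L — the first ⌈k/2⌉ positions map to 1..⌈k/2⌉, the rest to
  L−(k−i). Interior slots stay empty for that gene rather than being
  interpolated; the profile averages each slot over the genes that
  populate it.

All middle exons of a gene are standardized to the middle-exon length and
averaged within the gene before the gene contributes once. Middle introns
are not profiled (only first and last introns are part of the profile).
Genes with two exons contribute first and last exon, and their single
intron counts as both the first and the last intron — it is both, by
position; single-exon genes contribute the first exon and flanks only.
Flanks (default 1 kb) use genomic GMR with no masking of neighbouring
genes. Upstream positions run 5′→3′ so position `flank` abuts the TSS; the
nadir is reported as the offset (bp upstream) of the minimum, ties broken
toward the TSS.

## Regions and the permutation DMR test

Region construction marks nucleotides where any cow has ≥ 1 read, takes
maximal runs, merges runs whose gap is < 200 bp, drops merged runs
< 200 bp, and splits runs > 4000 bp into 4-kb pieces, folding a final
remainder < 200 bp into the preceding piece — so lengths lie in
[200, 4199] bp.

Per-cow region totals are transformed as log₂(reads + 1) — the offset
makes zero-read regions well defined (configurable) — and standardized
within cow to mean 100, SD 5, using the sample SD (n−1). The case-control
statistic of a region is the mean over the two case-control environments
of the (standardized case)/(standardized control) ratio; the environmental
statistic of an environment slot is the mean of its two cows over the mean
of the remaining four.

The null is estimated by Monte Carlo: each draw picks a region uniformly
with replacement and one of the 48 scenarios uniformly, so per-region draw
counts vary by chance (at 48 draws per region, roughly 20–90). Sampling
scenarios uniformly is equivalent to the sequential random assignment of
pairs to environments followed by random case designation, which induces
the same uniform distribution over the 48. P-values use the normal
approximation with the empirical null mean and SD, doubled for the
two-tailed test and clipped to [0, 1]; an empirical-quantile alternative
(`empirical_pvalues`) is provided for sensitivity analysis.
Benjamini–Hochberg step-up controls the genome-wide FDR. Environmental
P-values from all three environment slots enter one pooled FDR data set
(3 × n_regions values); calls are reported only for environments backed by
a true herd pair — the intermediate slot's two cows are not herd-mates, so
its calls are computed, adjusted, and flagged non-reportable.

## PMD detection

Windows are non-overlapping 10-kb bins; terminal partial windows are
dropped from both the moving average and the permutation pool to avoid
edge-fraction bias. The moving average spans 10 consecutive windows within
a chromosome. The significance threshold is the empirical α-quantile
(α = 0.01) of one million means of 10 windows drawn with replacement from
the genome-wide pool; it is used at full precision. A PMD is a maximal run
of below-threshold moving-average positions converted to the union of its
member windows (two adjacent qualifying positions yield 110 kb, not
200 kb), so every call is ≥ 100 kb and a multiple of 10 kb. Note the union
conversion widens each call by up to span−1 windows beyond the underlying
low-coverage block; a planted domain must be several times the 100-kb
detection floor before truth-overlap measures like Jaccard are
informative. Genes overlap a PMD if their TSS–TTS span intersects it by
≥ 1 bp; autosomal and X fractions are reported separately.

"Methylated regions" for window coverage are the read-covered regions of
the DMR stage (their pre-split form); peak intervals from an external
peak caller can be substituted via the interval-set reader.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
not the sequencing process. Per-nucleotide depth for cow c is negative
binomial (dispersion r = 0.5, variance m + m²/r) with mean

    μ_c(x) = baseline · lib_c · bias_c(x) · enrich(x) · cpg(x) · dip(x)
             · pmd(x) · fold_c(x)

* `baseline` = 0.80 reads/nt before enrichment.
* `enrich` — log-normal enrichment shared across cows, piecewise constant
  over 1-kb blocks (ln-SD 0.9, clipped at ±2 SD). Because it is shared, it
  cancels from case/control ratios: it is what concentrates the null ratio
  near 1.
* `bias_c` — per-cow log-normal local bias over 6-kb blocks (ln-SD 0.31,
  clipped at ±3 SD), modelling animal-specific immunoprecipitation and
  library bias. It is the dominant cow-specific term and sets the null SD.
* `cpg` — exp(0.4·z) where z is the standardized CpG density of the 1-kb
  block (clipped ±3); promoters and random patches are CpG-enriched in the
  generated sequence, which links depth to CpG density and gives the
  positive gene-density correlation.
* `dip` — a Gaussian depth trough centred 95 bp upstream of each TSS
  (depth ×0.25 at the centre, SD 150 bp), reproducing the upstream
  methylation nadir.
* `pmd` — planted domains are block-thinned: 10% of their 1-kb blocks keep
  normal enrichment (the sparse methylated patches that make the domain
  "partially" methylated), the rest drop to ~nothing. Uniform depth
  scaling was rejected: it sheds 200-bp regions holding a handful of reads
  whose log₂ noise is unbounded.
* `fold_c` — planted DMRs multiply the mean by 4 for the affected cows
  (the two case cows, or both cows of one farm for environmental DMRs).
  Each planted DMR is flanked by 300-bp unmappable margins so that it
  forms exactly one read-covered region; without the margins the fold is
  diluted across arbitrary 4-kb chunk boundaries and the truth intervals
  do not correspond to the units the caller tests.
* 15% of the genome (outside genes and planted DMRs) is "unmappable" —
  exactly zero depth, in 3-kb blocks kept ≥ 5 kb apart — giving the
  zero-coverage gaps of real uniquely-mapped data without creating sliver
  regions.

Defaults: 3 chromosomes × 6 Mb, 150 genes (3–8 exons, log-normal length
spread, both strands, spread uniformly along each chromosome), 8
case-control DMRs (fold 4, 2 kb), 4 farm-specific DMRs, 2 PMDs of 400 kb,
per-cow library scales uniform on [0.7, 1.3]. A fixed seed reproduces
every output byte-for-byte.

Calibration. The bias SD was chosen so the case-control null SD lands
near the ~0.02 level reported for real MeDIP cohorts of this design
(measured 0.017–0.019 at the default scale), and the genome size so the
permutation-null draw distribution is smooth enough for its z-scores to be
indistinguishable from standard normal at the resolution of a KS test on
10⁴ draws: the draw population is a mixture over regions that share
block-level bias values, and its CDF converges to the normal like one over
the square root of the number of independent bias realizations (~15,000 at
the default scale). The statistic itself is only asymptotically normal — a
mean of ratios has slight positive skew (~0.05) — so extremely large draw
counts would eventually expose the approximation; the same caveat applies
to the normal-approximation P-values on real data.

What passing tests do and do not show. The generator's null is built to be
exchangeable across relabellings, so null calibration here demonstrates
internal consistency of the permutation machinery, not robustness to real
confounding (batch effects aligned with farms, GC-amplification
differences between libraries, copy-number variation). Planted effects are
clean multiplicative folds on well-covered regions; real differential
methylation is smaller, patchier, and confounded with CpG density.
Read-level artefacts (fragment-length structure, mapping ambiguity,
strand bias) are not modelled — depth is drawn per nucleotide, so
"coverage" here is smoother at the sub-100-bp scale than aligned-read
pileups.

## Scales used by the test suite

Problem sizes were picked so the full suite runs in a couple of minutes on
one CPU: the 10-seed DMR-recovery experiment uses 2 × 1 Mb chromosomes
with 50 genes and no planted PMDs (PMD recovery has its own default-scale
check; at 1-Mb scale two 400-kb domains would occupy 40% of the genome and
distort the within-cow standardization), null calibration uses the default
scale with ~2 × 10⁵ draws, and the oracle comparisons use 50 random 100-kb
tracks. Measured at those scales: planted-DMR sensitivity 0.89 with
empirical FDR 0.066 (bounds 0.75 / 0.10), planted-PMD Jaccard 0.74
(bound 0.7), null mean 1.000 ± 0.0005.

## Numerical conventions and degenerate inputs

Sample SD (n−1) everywhere a SD standardizes data; folded-F variance tests
and Welch location tests for the chromosome-segment comparison (the
variance results justify the unequal-variance form); Spearman correlation
flags all-tied input as undefined (NaN with a warning) rather than
guessing; a cow whose region totals are constant cannot be standardized
and is a named error; a permutation null with zero spread (all rows equal)
is flagged degenerate; CpG obs/exp with no C or no G in the window is 0;
the CpG-island scan slides a 200-bp window by 1 bp and merges overlapping
qualifying windows, the classical criteria-scan reading of the ≥200 bp /
GC ≥ 50% / obs/exp > 0.6 rule. CpG sites are counted once per dinucleotide
on a forward-strand scan; site depth is taken at the cytosine, pooled
across cows by default (per-cow averaging is an option, since a cohort
fraction could be defined either way).

## Known limitations

* The region/scenario machinery assumes the paired-plus-intermediates
  design (2 case-control farms + 2 intermediates); other designs fail fast
  at scenario enumeration rather than silently generalizing.
* Normal-approximation P-values understate the tails for regions with very
  few reads; the empirical-quantile option exists but inherits the
  resolution limit of the draw count.
* No liftover/assembly handling: all inputs must share one coordinate
  system.
* The X-chromosome PMD summary relies on chromosome naming ("X"/"chrX").
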