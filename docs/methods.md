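# Methods

## Coordinates and file formats

All intervals are 0-based half-open (BED convention). Peak files are read as
BED3/BED6/ENCODE narrowPeak; only chrom/start/end (and strand where present)
are used. Gene annotation is a TSV (`gene_id chrom start end strand`); the
TSS is derived from the strand (span start on `+`, span end − 1 on `-`).
SNP catalogs are TSVs with optional MAF; unknown MAFs are retained and
flagged rather than dropped, but are excluded by the common-variant filter
with a logged count. PWMs are TRANSFAC count blocks normalized to
frequencies at parse time; the pseudocount defaults to 0 and is configurable
because the information term f·ln(4f) must be defined as 0 at f = 0, which
makes zero-count cells legal but occasionally fragile for near-degenerate
matrices.

## Peak integration

Replicates of one experiment keep reproducible signal: every pair of
intervals sharing ≥ 1 bp contributes its intersection span (a `union` mode
retains the merged pair span instead; the source description does not
disambiguate, so both are exposed with intersection — the conservative
reading — as default). More than two replicates fold left. Independent
experiments of one factor in different cell lines are pooled, with
overlapping **and bookended** intervals merged into maximal spans: two
abutting intervals describe one contiguous bound region. FOXA1 and FOXA2
peaks are pooled the same way into a single FOXA set, reflecting their
redundant regulation in liver.

## Dual-target regions and promoters

A dual-target region is any (FOXA peak, ERα peak) pair on one chromosome
whose edge-to-edge gap is **strictly** less than 250 bp (0 when the peaks
overlap). The reported region is the merged span of the pair, giving
downstream scanning one contiguous sequence. Distances are edge-to-edge
because BED3 inputs carry no summit information; a `summit` mode uses
interval midpoints. Pairs are reported individually (the same FOXA peak near
two ERα peaks yields two regions); a `merge` option collapses overlapping
regions for users who want unique genomic footprints. Promoters are the
5,000 bp strictly upstream of each TSS, strand-aware and clipped at
position 0; a dual region is kept if it overlaps any promoter by ≥ 1 bp
(full or partial overlap), and carries all overlapping gene ids.

## PWM scanning

Scores follow the Match core/matrix-similarity scheme. Information is in
nats; any fixed log base cancels in the MSS ratio, natural log is pinned for
reproducibility. The core is the 5 consecutive positions with the largest
information sum, leftmost on ties; matrices of length ≤ 5 are their own
core. Both strands are scanned — reverse-strand windows are scored on the
reverse complement, with hit coordinates always reported on the forward
strand. Windows containing non-ACGT characters are skipped, not scored.
Degenerate matrices (Max = Min) score 0. Default cut-offs are core 0.75 /
matrix 0.85, a common Match-style operating point, overridable globally or
per run; the strict profile used for planted-recovery checks is 0.90/0.95.

## Variant prioritization

Variant-in-element containment uses the half-open element span. A variant
inside two elements yields two candidate records, preserving the element
and gene context of each; consumers deduplicate by rsid. "Common" means MAF
strictly greater than 0.05. The pipeline driver chains all stages, labels
any failure with its stage name, and is deterministic given its inputs; the
stage-count report (peaks, dual regions, promoter-proximal regions,
elements, variants, common variants) snapshots the full parameter set.

## Association statistics

Crude odds ratios use the cross-product ratio with Woolf CIs
(z = 1.96 throughout), which for a single binary predictor is identical to
the logistic-regression Wald interval — both routes are implemented and
tested for agreement to ≥ 6 decimals. Any zero cell triggers the
Haldane-Anscombe 0.5 correction and flags the result. The additive model is
a dosage (0/1/2) logistic fit; Cochran-Armitage was considered and not used
because the dosage fit reproduces the published per-allele estimate.
Adjusted ORs come from `statsmodels` Logit via IRLS with Wald CIs;
separation and non-convergence raise rather than returning unstable
estimates. The genotype model additionally reports the 3×2
genotype-distribution χ² p-value, matching the convention of placing one
overall P per model block. Covariates: age (continuous), smoking/drinking
(ever vs never, with "unknown" kept as a third indicator level by default to
preserve n, or excluded on request), and sex in the overall stratum only.
Missing genotypes are dropped listwise per analysis. The age comparison
defaults to Welch's t: from the published summary statistics Welch
reproduces the printed p = 0.149 (0.1484) while the pooled test gives
0.136, so Welch is treated as the variant actually used; the pooled option
remains available. Smoking/drinking comparisons exclude the "unknown"
category. HWE is the 1-df χ² goodness of fit with allele frequency
estimated from the counts; monomorphic input returns χ² = 0, p = 1 with a
warning. Power uses the two-sided normal-approximation Wald formula with
expected-cell-count SE; at the study's sample size (1,081/2,008), OR 1.30
and control exposure frequency 0.48 it gives 0.934, consistent with the
published 0.94 and with a Monte-Carlo estimate to within 0.01. No
multiple-testing correction is applied (single-variant design).

## Expression analysis

ΔCt averages technical replicates per sample and gene before subtraction;
rel = 2^−ΔCt exactly, so log2(rel) = −ΔCt. The duplicate QC coefficient of
variation is computed per gene on raw Ct replicates (SD/mean, sample SD);
an option computes it on linearized 2^−Ct values. Samples exceeding 5% CV
are flagged `high_cv`, mirroring a re-analysis rule, not dropped.
Mann-Whitney uses the exact null for combined n ≤ 20 without ties and the
normal approximation with tie and continuity correction otherwise;
Kruskal-Wallis is tie-corrected, and all-tied data returns p = 1 with a
warning. Groups with fewer than 2 observations are skipped with a warning.

## Synthetic data

The regulatory fixture divides a random genome into one slot per gene
(10 kb default) and plants FOXA/ERα pairs with gap < 250 bp inside selected
promoters, embedding the matrix consensus at the FOXA peak centre and SNPs
at chosen motif offsets; common planted variants draw MAF ~ U(0.10, 0.40),
rare ones U(0.001, 0.04). Replicate BED files are jittered by at most a
quarter peak length so the replicate intersection still covers the motif.
Decoy FOXA and ERα peaks are confined to alternating slot tails, > 1 kb from
any promoter and > 9 kb from each other, so they cannot form
promoter-proximal dual regions — decoy SNPs are therefore structurally
unrecoverable, making planted-recovery tests sharp. What this generator does
**not** emulate: peak-width and signal distributions of real ChIP-seq,
motif-degenerate binding sites, GC structure, linkage disequilibrium between
SNPs — so passing recovery tests demonstrates the correctness of the
integration/scanning logic, not performance on real ENCODE data, whose
stage counts depend on matrices and cut-offs outside this package's scope.

The cohort simulator draws control genotypes in HWE at the configured risk
allele frequency (default 0.48) and case genotypes with
P(g|case) ∝ P(g|control)·OR_g, which makes the planted cross-product OR
exact in expectation under case-control sampling. Stratum-specific ORs
default to a female-only effect (het 1.4, hom 2.0) so the stratified
analysis path is the primary recovery test. Covariates are drawn
independently of genotype with the study-scale imbalances (smoking 59.9% vs
48.9% ever, drinking 52.9% vs 44.7%, ~80% male, age ≈ 55 ± 11); adjusted
estimates therefore center on the crude ones by construction. The Ct
simulator uses group sizes 22/38/12, reference baseline 20 cycles,
between-sample biological SD 1.0 cycles, duplicate technical SD 0.1 cycles,
and genotype ΔCt shifts (CC 0, CG −0.75, GG −1.5); a −1 cycle shift is a
2-fold expression increase. The biological SD and shifts were chosen once as
a realistic qPCR effect large enough for the 22-vs-12 comparison to be
well-powered.

## Problem sizes used in checks

Planted-recovery fixtures use 16–20 genes with 3–5 planted sites; interval
oracles use 100×100 random peak sets against an O(n·m) scan; PWM scores are
verified by exhaustive enumeration of all 256 windows of toy 4-mers and
brute-force scans of 150–300 bp sequences. Calibration uses 10,000 null
replicates per test (genotype tables of 500+500 at allele frequency 0.3;
expression groups of 22/38/12) and parameter recovery a 20,000-subject
cohort, sizes at which Wald/χ² approximations are expected to hold and
Monte-Carlo error (≈0.002 on a 5% rate) is small relative to the ±0.01
acceptance band.

## Known limitations

No bigWig/bigBed or remote resources; no IDR or peak calling; no
higher-order or dinucleotide motif models; no LD expansion, imputation or
population-structure correction; no efficiency-corrected (Pfaffl) qPCR
quantification. Exact published stage counts and covariate-adjusted ORs are
not reproducible without the original external data and individual-level
records; correctness of those code paths is established by oracle tests and
parameter recovery on synthetic data instead.
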