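# Methods

## Signal model

A targeted panel is an ordered list of P regions grouped into genes (BED
0-based half-open coordinates; regions sorted by chromosome and start, a
gene symbol occurring in non-adjacent coordinate runs is split into blocks
`gene#1`, `gene#2`, …). For one sample, the per-region signal is the number
of distinct UMI sequences among passing reads overlapping the region, and
`U` is the number of distinct UMIs among all passing reads in the file.
Normalizing by `U` (not by the mean per-region depth — the two differ by
the constant factor P, which cancels in every log-ratio but not in absolute
deviation magnitudes) makes samples of different library size comparable.

Read filters: primary, mapped, not QC-fail, MAPQ ≥ 20 (configurable).
Duplicate-flagged reads participate in the UMI union but not in the read
count column: UMI deduplication supersedes positional duplicate marking,
which would delete legitimate distinct-UMI fragments aligned at identical
coordinates. Overlap means ≥ 1 aligned reference base (POS through CIGAR
reference span) intersects the region; strand is ignored; UMI comparison is
exact string match (no error-tolerant clustering — a deliberate non-goal).
A UMI seen on both mates or several reads of one region counts once there;
a UMI spanning two regions counts in both, which is why `U` is the
genome-wide distinct count rather than the column sum.

## Pseudo-reference

The baseline is the region-wise geometric mean of the controls' normalized
fractions. Regions with a zero count in any control are excluded as
zero-coverage rather than pseudocounted: the geometric mean is undefined at
zero, and a zero in a deep targeted control indicates assay failure, not
signal.

Outlier screening pools all (region, sample) absolute deviations
`|x − R_p|` of the control set into one distribution and sets a single
scalar fence `T = Q3 + 1.5·IQR` (linear-interpolation quartiles, the
default of mainstream numeric stacks). Samples with ≥ 20 % of regions
beyond `T` are excluded; if any sample falls, the reference is rebuilt from
the survivors and the deviations and `T` recomputed before regions beyond
`T` in ≥ 50 % of retained controls are excluded in turn. One pass for
samples, then one for regions — no fixed-point iteration. Both fractions
are configurable.

Because the deviations are *absolute*, the fence is dominated by the
high-efficiency regions' noise: corruption confined to low-efficiency
regions can sit under `T`, and corruption concentrated in the regions that
carry most of the library is partly absorbed by the total-`U`
renormalization. A corrupted control is therefore most visible when its
distortion hits mid-efficiency regions; the test fixtures exploit exactly
this.

Segmentation weights are the inverse variances of the retained controls'
fractions (sample variance, floored at 1e-12), min–max scaled to [0, 1] and
then floored at 0.01: the plain min–max scaling would assign weight exactly
0 to the noisiest retained region and silently delete its data point, so a
small floor keeps it while preserving the ordering. Equal variances
degenerate to all-ones weights.

## Log-ratios and centering

`L_p = log2(tumor fraction / R_p)` on retained regions. Tumor regions with
count 0 are kept with a half-count pseudocount `0.5/U` and flagged — a zero
at 2000× molecular depth is evidence of homozygous deletion, not missing
data. Log-ratios are invariant to the tumor's sequencing depth.

Because the tumor's own `U` renormalizes the profile, a sample with net
copy gain or loss shows a global shift. A univariate Gaussian mixture with
k = 1–3 free-variance components is fitted to the log-ratios
(scikit-learn's EM, tol 1e-8, ≤ 500 iterations, deterministic k-means++
initialization from a fixed seed, default 17), the model chosen by BIC, and
the component whose mean is closest to 0 — assumed diploid — is subtracted
(ties go to the larger mixing proportion; collapsed components have their
SD floored at 1e-6 and are flagged). Centering can be disabled, which is
recommended for panels where most targets are expected altered; the
polyploid case, where the dominant component is not diploid, is a known
limitation. On small panels the mixture may also lack the evidence to
separate a single altered gene from the diploid bulk (BIC then keeps k = 1
and the centering inherits a bias of order the altered mass times its mean
log-ratio); at the default 20 × 15 scale one amplified gene is resolved
reliably.

## Segmentation

Each gene's ordered log-ratio vector is segmented independently by a
weighted circular binary segmentation written for this package: for every
arc of the circularized sequence with both arc and complement spanning at
least `min_width` regions, a pooled-variance weighted two-sample
t-statistic compares in-arc with out-of-arc values

    t = (m_A − m_B) / sqrt(s²·(1/W_A + 1/W_B)),
    m_X = Σ w v / W_X,  W_X = Σ w,
    s² = (Σ w v² − W_A m_A² − W_B m_B²) / (n − 2),

with the residual variance floored at 1e-16 times the signal's mean square
so a perfectly separating arc scores a very large but finite statistic.
Significance of the maximal |t| is assessed by permuting the values while
the weights stay attached to their positions — the weight encodes the
position's assay variance, not the observation's — and splitting recurses
while the permutation p-value is below `alpha`. Permutations stop early
once the exceedance count guarantees p ≥ alpha. After splitting, adjacent
segments whose weighted means differ by less than `undo_sd` times the
pooled per-unit-weight residual SD are merged back, closest pair first.

Defaults: alpha 0.01, 10 000 permutations, min_width 2, undo_sd 1.0, all
exposed in the configuration. Genes with fewer than `2·min_width` retained
regions, or a constant signal, return a single segment; single-region
segments and genes with fewer than 6 regions are flagged as below the
recommended minimum for a confident state call. Permutation RNGs are seeded
per (sample, gene-block position) from the global seed, so results are
reproducible and independent of gene processing order. Breakpoints never
cross gene boundaries, and segment weighted means reconstruct the signal
exactly.

## Calling and tumor-fraction estimation

Segments with ≥ 2 members get a two-sided one-sample t-test of their
*unweighted* member values against 0 (the weights served segmentation
only); Benjamini–Hochberg adjusts across the sample's tested segments, and
a segment is a gain (loss) when q < 0.05 with positive (negative) mean.
Zero-variance segments use the convention p = 0 when the mean is nonzero,
p = 1 otherwise, and are flagged. Single-member segments are reported
untested.

Tumor fraction: the observed log-ratio of a clonal single-copy event in a
sample with tumor-cell fraction c is `L = log2(c·CN/2 + (1 − c))`.
Inverting for CN = 3 gives `c = 2(2^L − 1)` applied to the pooled member
log-ratios of all gain segments, and for CN = 1 gives `c = −2(2^L − 1)` on
the loss side; pooling member values (rather than segment means) weights
long segments proportionally to their evidence. The two estimates are
averaged; if one side has no significant segments the other stands alone,
and raw estimates outside [0, 1] are clamped and flagged rather than
rejected — amplifications beyond one extra copy legitimately push the gain
inversion past 1. Consequently the estimate is unbiased only for
single-copy events: a CN = 4 or CN = 0 event contributes roughly twice the
per-copy signal, so profiles dominated by multi-copy events overestimate c
by up to 2×. No subclone deconvolution or integer copy-number assignment is
attempted.

## Synthetic-data generator

The generator emulates the structure of a lymphoma-type amplicon panel at
desk scale: 20 genes × 15 regions (P = 300) by default — real panels of
this design run to ~70 genes and ~1500 primers — with per-region capture
efficiencies drawn log-normal (σ = 0.5, a spread typical of amplicon
panels). Library sizes vary log-normally (σ = 0.2) around a target of
`mean_depth · P` with `mean_depth` = 2000 distinct molecules per region,
matching the ≥ 500–1000× depths targeted panels are run at. Counts are
negative binomial with size 50 (variance μ + μ²/50, i.e. ~14 % extra-
Poisson CV), reflecting that UMI counts across real controls still carry
residual region-level variability; the Poisson limit is available. Tumor
samples scale each region's expected count by the copy ratio
`c·CN/2 + (1 − c)` and are renormalized to the target library size, so the
raw profile carries exactly the global shift the centering stage must
remove. Events span whole genes by default (sub-gene spans are available),
with the canonical quartet CN = 4, 3, 1, 0 on four well-separated genes.

What the generator does *not* model: GC and amplicon-length biases shared
between samples (they cancel against the pseudo-reference only partially in
real data), UMI sequencing errors and barcode collisions, fragment-length
effects, and allele-specific signal. Passing tests therefore demonstrate
the pipeline's statistical behavior under honest overdispersed counting
noise, not robustness to those artifacts.

BAM fixtures invert the counting stage: a toy reference and a sorted,
indexed BAM in which region p is covered by exactly the requested number of
globally distinct 12-mer UMIs (read-name suffixes), each UMI emitted as 1–3
reads with the extra copies duplicate-flagged, so counting must reproduce
the programmed matrix with zero tolerance.

## Sensitivity at the default noise level

With NB size 50, a per-region log-ratio has SD ≈ sqrt((1/50 + 1/2000) ·
(1 + 1/5)) / ln 2 ≈ 0.23 against a 5-control reference. A single-copy event
at tumor fraction f shifts 15 regions by |log2(1 ± f/2)| ≈ 0.07·(f/0.1), so
the one-sample t at f = 0.1 is ≈ 1.2 — far below any FDR-corrected
threshold — and single-copy events become reliably detectable only around
f ≈ 0.4–0.5. The dilution experiment shipped with the package accordingly
finds all four canonical events in ≥ 9/10 replicates from f = 0.5 upward;
at lower f only the multi-copy events (CN = 4, CN = 0), which carry twice
the per-copy signal, remain detectable. Detection down to f = 0.1 requires
per-region noise several-fold smaller (NB size ≳ 10³, approaching the
Poisson limit of deep UMI counting); the generator's default deliberately
represents a noisier assay. For the same reason the purity-recovery
correlation across a 0.5/0.3/0.2/0.1 dilution series runs ≈ 0.92–0.94
rather than higher: which events reach significance changes with f, and the
multi-copy events estimate ~2f while full detections estimate ~1.5f,
bending the programmed-vs-estimated relationship.

## Problem sizes and numerical choices

Test and acceptance simulations use the 20 × 15 default panel (property
suites use 4–8 genes × 8–10 regions), 5 controls, and 10 (sensitivity) or 5
(purity) replicates per dilution point — sizes chosen so the full
experiment reruns in about a minute. Quartiles use linear interpolation;
variance floors are 1e-12 (weights), 1e-6 (mixture SDs), 1e-16 relative
(segmentation); permutation p-values use the add-one estimator
`(1 + #exceedances)/(1 + N)`. All randomness flows from explicit seeds:
fixed seeds reproduce count matrices, segmentations and report files
byte-for-byte.
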