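# Methods

This note documents the models, conventions and design choices behind
`peakscape`, in the spirit of the methods documentation of mature
scientific packages: what each stage computes, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical
details a careful user should know.

## Coordinate model

All coordinates are BED-convention 0-based half-open `[start, end)`,
including every printed output; a single convention end to end prevents
off-by-one drift. Interval sets are always sorted by
`(chrom, start, end, name)` — names break ties so outputs are
deterministic. A peak summit is an offset from the interval start (the
narrowPeak column-10 convention); when absent it defaults to the interval
midpoint by floor division, which is what the clustering stage anchors on.
`merge` collapses overlapping *and* bookended intervals (distance 0), the
default of the standard interval-merging tools.

## Replicate consensus

A replicate-1 peak enters the consensus iff each other replicate contains
at least one peak overlapping it by at least `min_frac` (default 0.5) of
*both* peak lengths, with ≥ is used at the boundary and ≥1 shared base
required before the fraction test. Consensus coordinates are the
replicate-1 intervals: a shared-peak count needs one coordinate
convention, and the first replicate is the designated reference. Matching
is existence-based — a peak matching two partners in another replicate
counts once; no one-to-one assignment is attempted. Venn subset counts
assign every peak of every replicate a support signature (the replicates
holding a reciprocal match); each subset is counted from its lowest-index
member so a physical peak region is not double counted. With
`require_all=False` a strict majority of replicates suffices.

Replicate signal agreement is the Pearson correlation (Spearman by flag)
of mean per-base signal over genome-tiling bins (default 1 kb); a
zero-variance track is an error rather than a silent NaN.

## Chromatin-state assignment

Peaks receive the single state contributing the most overlapping bases;
ties break by palette order (the 11-state promoter → enhancer → insulator
→ transcription → repressed → heterochromatin → repetitive ordering).
Unsegmented bases compete as a pseudo-state, so a peak mostly outside the
segmentation is labeled `Unsegmented` (with a warning) while a peak mostly
inside keeps its majority state. Grouped fractions use a configurable map
defaulting to promoters = {Active, Weak, Poised Promoter}, enhancers =
{Strong, Weak/Poised Enhancer}, heterochromatin/repressed =
{Heterochrom/lo, Repressed}, everything else "other"; the membership of
the pooled repressed group is configuration, not hard-coded. Fractions are
exact; rounding (half-up, 1 decimal) happens only at report time.

## Signal matrices and clustering

Signal tracks have bedGraph semantics (piecewise constant, uncovered = 0,
negative values rejected at load). Windowed means come from an exact
prefix integral, so the conservation property holds to float precision:
the sum of `bin_mean × bin_bp` over a window equals the track integral
over that window. Windows truncated at chromosome edges are zero-padded.
For TSS anchors on the minus strand the bin order is reversed so bins run
5′→3′ along the gene; the promoter window (−5000..+500 around the TSS) is
likewise strand-aware and mirrored in half-open coordinates.

Before k-means, rows are arcsinh-transformed and each column is z-scored.
The variance stabilization keeps one bright track from dominating the
Euclidean objective; raw-space clustering is available by flag. The
reference clustering tool's internal normalization is not published, so
this transform is a documented substitute, not a reproduction. K-means
uses k-means++ initialization with an explicit seed and keeps the best of
`n_init = 10` restarts. Cluster names C1..Ck are assigned by descending
centroid mean of a designated ordering track (the promoter mark H3K4me3
when present), replacing by-inspection naming with a deterministic rule;
ties in the ordering statistic resolve by stable sort.

## Colocalization

Two merged tracks define a 2×2 base-pair table (both / query-only /
reference-only / neither). The tetrachoric correlation uses the classical
cosine approximation `r = cos(π / (1 + √(ad/bc)))` — closed-form and
testable, unlike the bivariate-normal inversion of the full estimator.
Limits: `bc = 0, ad > 0 → +1`; `ad = 0, bc > 0 → −1`; a zero row or
column is degenerate and raises. The approximation is scale-invariant and
antisymmetric under swapping `(a,d) ↔ (b,c)`.

The Monte-Carlo null rotates all query intervals of each chromosome by an
independent offset uniform on the chromosome length, with wrap-around
(an interval crossing the end splits in two). This preserves interval
lengths, per-chromosome covered bp and inter-element distances exactly
while the reference stays fixed. The empirical p-value uses the add-one
estimator, so `p ≥ 1/(n_mc+1)` and is never zero; under independence p is
uniform on its support, making the test exactly calibrated. Significance
across many pairs is handled by fixed-n Monte-Carlo plus
Benjamini–Hochberg — simpler and fully reproducible compared with
sequential sampling-depth schemes. Excluded-region masking is not
implemented.

The pairwise similarity matrix (Jaccard by default) is clustered with
complete linkage on Euclidean row distances; rows are pre-sorted by name
so equal-distance merges are deterministic, and the tree is exported as
Newick. A published length normalization of the tetrachoric coefficient
is not fully specified in the literature this follows; the raw coefficient
and the overlap bp are therefore reported separately rather than guessing
a formula.

## Motif enrichment

Scanning uses log-odds `log2((p + 0.001)/bg)` per position (uniform
background unless the PWM supplies frequencies), both strands, N-containing
windows skipped; a window is a hit at ≥ `threshold_frac` (default 0.8) of
the motif's maximum achievable score. The per-motif detection thresholds
of reference tools are not published, so the fraction is exposed and
recorded in output metadata. Counting is sequence-level (≥1 hit), matching
"% of targets" semantics; the test is a single exact one-sided
hypergeometric tail on the pooled target+background population rather
than a mixture of approximations, BH-adjusted across motifs, ties in p
broken by target percentage. Peak sequences are fixed windows (±100 bp
around the summit) by default, with full-peak extraction available.
Backgrounds are mononucleotide-shuffled copies of the targets (length and
composition preserved per sequence) or length-matched random genomic
windows rejected against the peak set.

## Target classification

A gene is responsive when its knockdown padj < α (default 0.05; the
original thresholds live with the source expression dataset, so α is
configuration). A rescue contrast counts only when significant *and*
signed opposite to the knockdown change — the sign condition prevents a
significant change in the same direction as the knockdown from counting
as rescue. Pioneer = rescued by wild type and not the mutant; non-pioneer
= rescued by both. Direction: genes down after knockdown are "activated"
by the factor. Direct = at least one regulatory element of the gene
overlaps a peak by ≥1 bp; element-wise overlap reports
(total/overlapped/percent, half-up integer rounding) follow the same ≥1 bp
rule.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every stage at these default study
conditions: 2 chromosomes × 1 Mb; 500 true peaks of 200–600 bp placed one
per slot (disjoint, ≥200 bp apart); three replicates with endpoints
jittered by rounded N(0, 20 bp), 5% independent dropout and 25 uniform
noise peaks each; five balanced peak archetypes driving six signal tracks
(promoter-like: narrow H3K4me3+ATAC; enhancer-like: narrow
H3K4me1+H3K27ac; intragenic: broad H3K36me3; repressed: broad H3K27me3;
unmarked: background only) as Gaussian bumps (amplitude ≈ 8 narrow / 5
broad, sd 150/800 bp) over gamma background noise at 25 bp resolution; an
11-state segmentation that partitions each chromosome exactly, with
peak-covering blocks matching each archetype and quiet-skewed background
blocks elsewhere; i.i.d. sequence at GC 0.41 with an 8-bp consensus motif
embedded near 60% of summits on a random strand (exact consensus by
default, PWM-sampled by flag, so scan-stage ground truth is unambiguous);
300 genes of which 30 pioneer and 60 non-pioneer, with |log2FC| ~ U(1,3)
at padj 10⁻⁶ for planted effects and N(0, 0.1) at padj 0.9 otherwise
(noisier variants by flag); partner tracks overlapping true peaks with
probability 0.5; super-enhancer and footprint sets anchored on a subset of
peaks plus peak-free decoys. Every artifact draws from its own stream
seeded `seed + fixed offset`, so adding an artifact never perturbs the
others, and a fixed seed reproduces the bundle byte-identically on disk.

All pioneer genes are linked to a distinct true peak through an
overlapping regulatory element; half the non-pioneer genes are
deliberately left unlinked (their elements are rejected against a padded
union of the true peaks) to provide indirect targets.

Deliberately not modeled: read-level noise (no FASTQ, fragment-size or
sonication effects), mappability and blacklist structure, copy-number and
GC bias in signal, overlapping/nested true peaks, realistic gene density
and correlated gene placement, and linkage between expression noise and
chromatin state. Passing tests on this generator therefore demonstrates
the correctness of the arithmetic, the calibration of the null and the
recoverability of cleanly planted structure — not performance on the
confounds of real sequencing data.

## Problem sizes and numerical details

The test suite and the acceptance script run everything at desk scale:
the default 2 Mb bundle for recovery checks, 100 randomized genomes of
5–50 kb for per-base oracle equivalence, 500 trials at `n_mc = 99` for
null calibration (the exact binomial 95% acceptance band around α = 0.05),
and 10 k-means seeds for the clustering check (adjusted Rand index ≥ 0.9
against the planted archetypes; observed ≈ 0.93, with the residual
confusion almost entirely unmarked-background peaks drifting into
broad-mark clusters). Empirical p-values are never 0 or >1 by
construction; percentage reports round half-up; fractions are computed
exactly and rounded only when printed. Columns with zero variance are
left centred at 0 by the z-score step rather than dividing by zero.
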