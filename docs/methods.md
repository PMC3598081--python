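# Methods

## Study design emulated by the synthetic cohorts

The package targets two-stage ("funnel") methylation studies: a small
genome-wide screening cohort followed by targeted replication of the top
candidates in a larger independent cohort. The synthetic defaults encode
that design: 9 cases vs 8 controls screened over 2000 genes (1–3 probes per
gene) with 90 truly differential genes, one third hypermethylated and two
thirds hypomethylated in cases at |Δβ| = 0.2; and 30 cases vs 28 controls
fine-mapped on 20 candidates with 5 CpG units each, of which 12 carry a true
replication effect (|Δβ| = 0.1) in the screening direction and 8 carry none.
Sample sheets include sex (cases skew male), age and LVEF (cases < 45 %),
so sex-matched re-analysis is exercisable.

## Noise model

Methylation fractions are drawn from beta distributions parameterized by
mean m and precision φ (shape parameters mφ and (1−m)φ; default φ = 50 for
the array stage, 60 for amplicons). The bounded support matches methylation
fractions, so no value is ever clipped; validity is enforced at the
parameter level instead — a design whose planted means would leave (0, 1)
is rejected outright. Probe-level heterogeneity is a Gaussian perturbation
of the gene mean (SD 0.02), clamped to (0.005, 0.995) so the beta parameters
stay defined; per-CpG heterogeneity in the amplicon panel works the same
way. Setting the amplicon precision to `None` disables sampling entirely,
which gives the noise-free panels used for exact round-trip checks. Bead
channels are intensity·β and intensity·(1−β) plus half-normal noise, so
intensities stay nonnegative. What the generators deliberately do **not**
model: dye/channel bias, batch effects, probe cross-hybridization, detection
failures, cell-type composition. Passing tests therefore demonstrate the
statistics and plumbing are correct, not that the pipeline is robust to
those real-data artifacts.

## Preprocessing

β = M/(M + U + α) with α = 100 intensity units by default (a conventional
stabilizer for low-intensity probes; configurable). Quantile normalization
maps each sample onto the per-rank mean of the column-sorted values; tied
values receive the mean of the reference values over their rank span, which
makes the operation order-independent and idempotent. The two channels are
normalized separately by default; a joint mode (one shared reference for
both channels) is available. Sample QC flags arrays whose mean total
intensity deviates from the cross-sample median by more than 3 robust
z-units (median/MAD, normal-consistent scaling); with zero MAD any deviation
fails. The threshold is configurable and recorded in the report.

## Gene screen

The per-gene test uses probe-mean betas (one value per sample per gene)
rather than pooled probes, so every gene contributes a single significance
value. Exactness policy for the two-tailed rank-sum p:

* no ties and combined n ≤ 25 — exact, from the subset-sum DP null
  distribution of the rank sum (two-sided p = 2·min(lower, upper tail),
  capped at 1);
* ties and combined n ≤ 12 — exact, enumerating all C(n, n₁) assignments of
  the observed average ranks;
* otherwise — normal approximation with the standard tie correction and no
  continuity correction.

Both default cohorts (17 and 58 samples) are thus exact and approximate
respectively, and the discrete null at 9 vs 8 attains P(p < 0.05) ≈ 0.046,
inside the calibration band checked by the tests. Constant genes report
p = 1 and a degenerate flag. Direction uses a dead-band ε (default 0: any
nonzero median difference classifies). Candidate selection is the union of
the top-n-by-p and top-n-per-direction-by-|Δβ| sets after optional
p/effect/CGI/heart-expression filters, ordered by (p, gene id) — gene-id
tie-breaks keep the list reproducible.

## Clustering

Samples are ranked per gene (1 = lowest methylation; average ranks for
ties, with a documented "competition" mode that breaks ties by column order
for strict-integer emulation), distances are Euclidean in rank space, and
the agglomeration is a direct O(n³) implementation with smallest-(i, j)
tie-breaking — chosen over a library call because the merge order is part of
the contract and cohorts are tens of samples. Complete linkage is the
default (single/average available). Output is a merge list, flat cuts and
Newick; no plotting.

## Enrichment

The sorted list is built from probe-level |median case − control|
differences; a gene with several probes sits at the median of its probe
positions (half-integer medians sort before the next integer; remaining
ties by gene id). The unweighted running sum gains (n−k) at hits and loses
k at misses; since the prefix sum after i positions with h hits is
h·n − i·k, the exact null tail P(RS_max ≥ s) reduces to counting lattice
paths staying strictly below s, a constrained Pascal recurrence over
(position, hits). Counting uses Python's arbitrary-precision integers
throughout, so the DP is exact at any list size and needs no log-space
fallback; the cost is O(n·k) big-int additions. The statistic is one-sided
(enrichment toward the top) because sorting is by absolute difference; a
max-|prefix| two-sided mode was considered and left out of the default
path. Benjamini–Hochberg adjustment is delegated to statsmodels.

## Replication statistics

Group comparisons use pooled-variance Student's t (paired t on differences
for pre/post-transplantation designs); zero-variance inputs are flagged
degenerate rather than erroring. Dunnett's many-to-one adjustment is
computed by seeded Monte-Carlo on the equicorrelated multivariate-t maximum
(T_j = (√λ_j Z₀ + √(1−λ_j) Z_j)/W, λ_j = n_j/(n_j+n₀), W² ~ χ²_df/df;
default 100 000 draws, MC standard error ≲ 0.002), cross-checked in tests
against an independent implementation. Calibration fits measured on nominal
standards (0–100 %) by least squares and declares amplification unbiased
for slope in [0.9, 1.1] and |intercept| ≤ 5 points. Direction consistency
requires both stage effects nonzero (beyond a 1e−12 dust tolerance — a
noise-free null candidate must not count as replicating) with equal sign;
"significant" additionally requires replication p < 0.05. Sex matching
keeps, per group, the largest subset achieving the target female fraction
(both sexes must stay represented for a fractional target) or min(F, M)
in 1:1 mode, with seeded within-sex draws.

## Sequence utilities

CpG islands: sliding 200 bp windows (step 1) pass when GC ≥ 0.5 and/or
observed/expected CpG ≥ 0.6 with length ≥ 200; the AND mode is the
canonical conjunction, the OR mode admits loosely defined islands that meet
a single criterion — both exist because the two criteria are also useful
separately. Overlapping qualifying windows merge; a merged interval that no
longer satisfies the criteria is trimmed one base at a time, alternating 3′
then 5′, until it does or it drops below the minimum length. O/E uses a
left-to-right non-overlapping CpG count; N bases are excluded from the GC
denominator. Bisulfite simulation converts every cytosine outside a
methylated CpG to thymine with the given conversion rate (no sequencing
error; an injection hook is deliberately absent from the default path), and
clone calling reads C as methylated and T as unmethylated at reference
CpGs, reporting conversion efficiency from non-CpG cytosines so failed
conversion is distinguishable from full methylation.

## Expression

ΔCT = CT_target − arithmetic mean of the housekeeper CTs (GAPDH, RPL13,
β-actin by default; the arithmetic mean of cycles matches the usual
multi-reference delta-CT practice), fold = 2^−ΔΔCT on group means with a
pooled t-test on ΔCT values, and a strict RIN > 6 sample filter (a sample at
exactly 6 is excluded).

## Determinism and numerical choices

Every stochastic operation takes an explicit seed; the pipeline derives
per-operation seeds from the run seed by fixed offsets. Artifact headers
carry the config hash and seed but no timestamps, so identical (config,
seed) runs are byte-identical — verified file-by-file in the tests. Floats
are written with %.10g. Linkage tie-breaks, gene-id tie-breaks and sorted
category iteration remove all order dependence.

## Problem sizes used in the checks

The test suite and acceptance script run the full default screening design
(2000 genes, 9 vs 8) and replication design (20 candidates, 30 vs 28);
null calibration pools 5–10 independent 2000-gene screens; enumeration
oracles cover combined cohorts ≤ 8 (rank-sum) and lists ≤ 10 (enrichment
DP grid); CGI detection is checked against the all-windows oracle on ~2 kb
sequences. These sizes were chosen so each guarantee is checked at full
fidelity while the whole suite stays fast.

## Known limitations

No IDAT parsing (signals enter as TSV), no detection p-values or background
correction, no batch correction, no weighted GSEA, no clone-to-reference
alignment (clones must be pre-aligned), no primer-efficiency correction.
The QC filter models only global intensity outliers; real array failures
are more varied.
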