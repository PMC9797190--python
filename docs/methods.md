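# Methods

This note documents the models and procedures chipdyn implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Coordinate and track model

All coordinates are 0-based, half-open; BED files keep their native
convention on I/O. Signal lives on a fixed-width bin grid (default 25 bp)
per chromosome. Interval statistics are overlap-weighted: a window's score
is the bp-weighted mean of the bins it covers. Two edge conventions exist
and are used deliberately:

* **clip** — normalize by the in-chromosome covered width (promoter scores,
  origin EdU scores);
* **w0** — out-of-range bp contribute zero with full weight (metagene
  matrices), so edge anchors are not inflated.

bedGraph input is resampled onto the grid by coverage-weighted mean with
absent regions counted as 0; bin-aligned data round-trips exactly.

## Normalization

Simple normalization is the log2 ratio of IP to input per bin with each side
reciprocally scaled by the other sample's total, written on the
mean-coverage-normalized scale:

    value_i = log2( (ip_i·B/T_ip + c) / (in_i·B/T_in + c) )

with B the number of genome bins, T the sample totals and pseudocount
c = 1 by default. Placing the pseudocount on the normalized scale (the usual
convention when ratioing 1×-normalized coverage tracks) rather than on raw
counts keeps log ratios bounded at empty bins **and** makes the output
exactly invariant to rescaling either library — a property the test suite
asserts at 1e-12; with c = 0 the bare reciprocal-total formula is recovered.
The cost is shrinkage of extreme ratios by roughly one coverage unit per
side, identical across samples and therefore harmless to the residual
analysis, which compares genes within a fitted trend.

Origin-aware normalization partitions bins into origin-proximal (any bin
intersecting the closed ±5-kb interval around an origin center; radius 0
still marks the center bin) and the complement, and applies the same formula
independently per partition with partition-restricted totals and bin counts.
This absorbs the elevated replication background near fired origins; the
price, documented here because it surprises, is that absolute levels are not
comparable across the partition boundary. Replicates are each normalized
against their own input, then averaged bin-wise.

A partition (or a whole sample) with zero total counts in either track is a
hard error naming the partition: there is no defensible imputation.

## Promoter scoring and significance

The scoring promoter is the 500-bp window upstream of the TSS (strand-aware;
clipped windows use the covered width and are flagged). For peak annotation
the promoter is −500/+50 around the TSS, and category precedence is
promoter > gene body > other when a peak spans several features; the gene
body requires a gene-extent column, which the gene table carries for that
reason.

Empirical promoter significance uses a null of n (default 10 000) 500-bp
windows placed uniformly over the genome (in-bounds, chromosome chosen
proportional to usable length), scored identically, with the one-sided
add-one p-value p = (1 + #{null ≥ obs}) / (1 + n). The null construction and
α = 0.05 are this package's choices — the simplest defensible null over the
same signal distribution; on signal-free tracks the p-values are uniform
(asserted by a KS test at α = 0.01 over 500 genes).

Binding specificity is summarized by the Gini index from the Lorenz curve of
nonnegative per-gene signal: ascending cumulative shares, trapezoidal area,
gini = 1 − 2·area. This equals half the relative mean absolute difference,
which the tests use as an independent oracle (agreement < 1e-12); gini is
scale-invariant and bounded by (n−1)/n. All-zero input is an error.

## Differential binding (residual analysis)

OLS of HU scores on G1 scores over all shared genes; residual r = y − ŷ.
The direction of regression matters (residuals differ under reversal) and is
fixed as stressed-on-reference, with G1 as predictor. Genes are filtered
when their unit-max-scaled score is below −0.075 in **either** compared
sample — the conservative reading, excluding promoters that are low in
either stage; scaling is per sample. Ranking is by |r| descending with
lexicographic gene-id tie-break for full determinism; top-K (default 1000)
is the call, and two experiments are combined by set intersection ordered by
the worse rank. The group test z-scores residuals over all genes (sd with
ddof = 1) and compares a gene group to the rest by two-sided Wilcoxon
rank-sum, exact for combined n ≤ 30, continuity-corrected normal
approximation otherwise.

## Origin typing

The per-origin statistic is the mean EdU track value over ±2.5 kb of the
center — a window chosen well inside the ~10-kb fork extent so the plateau
dominates, wide enough to average bin noise; it is configurable. Rules, with
threshold 2.0 on the normalized EdU scale: early ⇔ wild-type signal at the
first HU timepoint exceeds the threshold; otherwise late ⇔ the mean across
checkpoint-deficient genotypes at the later timepoint exceeds it; otherwise
inactive. "First" and "later" are HU45 and HU90. Aggregating mutants by mean
is the default; requiring every mutant separately is available as
`late_rule="all"`. The three classes always partition the origin set, and
raising the threshold can only move origins toward inactive.

Replication timing is assigned from profiled windows by nearest window
center within 5 kb (ties to the lower coordinate; otherwise missing).
Blacklist filtering treats an origin as the point [center, center+1), so a
center touching an interval end is retained (half-open semantics).

## Gene–origin conflicts

Distance is TSS-to-center on the same chromosome, nearest origin with ties
to the lower coordinate; categories <1 kb, 1–2 kb, 2–5 kb, none (≥5 kb or no
origin on the chromosome) partition the genes. Orientation follows the fork
that reaches the gene: it travels away from the origin center, so
transcription pointing toward the center is head-on (HO), away is
co-directional (CD); distance 0 is NA. Both labels are invariant under
mirroring the genome and flipping strands (property-tested). The
default nearest-origin universe is all origins with the class recorded;
`active_only=True` restricts to early/late, since the right universe is a
judgment call.

Down/up-regulated gene counts are stacked by distance category, origin class
and orientation (the latter two among genes within 5 kb), and the
late-vs-early and HO-vs-CD contrasts are two-sided Fisher exact tests on the
2×2 down/up tables. Empty strata skip the contrast with a warning rather
than erroring a whole report.

## Integration statistics

Fisher tests use the classical two-sided convention (sum of conditional
table probabilities ≤ the observed table's) and report the sample odds ratio
ad/bc (∞ allowed); degenerate margins are errors. TF-target enrichment takes
the gene universe as an explicit parameter — never inferred from the inputs —
and reports overlap frequencies as percentages with a one-sided (greater)
test. The DB–expression association is a two-sided Fisher test of direction
concordance; the DB–expression correlation is Spearman's rank correlation
with average ranks for ties, exact permutation p for n ≤ 10 tie-free,
t-approximation otherwise.

The DE surrogate is intentionally naive and labelled as such in its output:
median-of-ratios size factors (geometric-mean reference over genes positive
in all samples), log2FC = log2((mean_b + 1)/(mean_a + 1)) on normalized
counts, significance by |log2FC| ≥ 1. It is a placeholder with honest
semantics — externally computed DE tables (e.g. from an NB-GLM engine) are
accepted as first-class input wherever a DE result is consumed, because that
engine is an off-the-shelf dependency, not something worth reimplementing.
Raw p-values are reported throughout (no multiplicity correction by
default), matching how the surrounding analyses consume them.

## Metagene profiles

Anchor × flank-bin matrices (TSS flank 1 kb, origin flank 15 kb by default)
with w0 averaging; rows of minus-strand genes are reversed when strand-aware
so upstream is always left; origin matrices are never strand-aware. Row
ordering is a stable sort by a per-anchor key (missing keys last), optionally
within contiguous cluster blocks with descending key — the layout used for
expression-ordered heatmaps per coexpression cluster.

## Synthetic data

The generator emulates the study design: genotypes WT and two
checkpoint-deficient mutants; timepoints G1, HU45, HU90; assays IP, input,
EdU, RNA; negative-binomial counts throughout (var = μ + αμ², α = 0.05
default, Poisson at α = 0). Default conditions: 4 chromosomes × 750 kb,
2000 genes, 120 origins split 0.31/0.32/0.37 early/late/inactive (the mix in
curated origin databases), background depth 50 reads/bin, fork extent 10 kb
(half at HU45), EdU plateau 4 on background 0.2, 150 planted binding shifts
of |Δlog2| = 1 (70% up), 200 planted expression changes of |log2FC| = 2, and
conflict-suppression probabilities 0.8 (HO) vs 0.4 (CD) for genes within
5 kb of late origins in checkpoint-deficient genotypes.

Construction details that matter:

* Genes sit on a jittered grid with promoter windows guaranteed disjoint
  (divergent pairs need a 1-kb TSS gap), so every planted effect is
  attributable to exactly one gene; infeasible densities raise a placement
  error rather than silently overlapping.
* Each gene has a fixed baseline promoter enrichment drawn once
  (N(2.0, 0.5) in log2), shared across samples and experiments — without
  between-gene spread the G1→HU regression would be degenerate (slope ≈ 0)
  and unrepresentative of real promoter landscapes.
* Promoter components are rectangular over the 500-bp scoring window and
  realise a target log2 enrichment exactly, so planted shifts are
  interpretable on the score scale; fork components are flat plateaus over
  the fork extent of fired origins (G1: none; WT: early; mutants:
  early + late; inactive never).
* One integer seed drives a single root SeedSequence with per-sample spawned
  child streams, so outputs are byte-identical across runs and independent
  of generation order.

What it does **not** emulate: read-level artefacts (mappability, GC,
fragment-length effects), chromatin structure, correlated biological
replicate variation, gradients of origin firing efficiency, or realistic
promoter architecture beyond the rectangular window. Passing recovery
benchmarks therefore demonstrates correctness of the estimators under the
declared noise model, not performance on real libraries.

## Benchmark problem sizes

The packaged benchmarks (also run by `scripts/acceptance.py`) use: planted
differential-binding recovery on 2000 genes / 150 planted / two experiments /
top-300 + intersection, medians over 10 seeds; origin typing over 120 origins,
10 seeds; orientation-bias power over 100 simulations of 60 near-origin genes;
promoter-p uniformity over 500 genes with 10 000 null windows; group-test
calibration over 1000 random groups; and normalization invariants over 100
random track pairs. The differential-binding benchmark switches the fork
component off (`fork_amplitude=0`): fork signal raises HU promoter scores of
origin-proximal genes identically in both experiments, which is true biology
but makes "false member" ill-defined for a benchmark of the promoter
procedure; fork signal is exercised by the origin-typing benchmark instead.

A structural note on the intersection benchmark: with K = 300 and 150
planted among 2000 genes, each experiment's selection necessarily carries
~150 noise picks, and two independent experiments share ≈ 1850·(150/1850)²
≈ 12 of them by chance alone, so even a perfect caller's intersection is
≈ 7% non-planted in expectation. The benchmark reports this fraction
honestly rather than tuning conditions to hide it.

## Known limitations

* The naive DE surrogate has no dispersion model and no p-values; treat its
  significance flags as fold-change thresholds only.
* Empirical promoter p-values share one null across genes; clipped promoter
  windows near chromosome ends are scored on their covered width, which the
  null windows (always full-width) do not mimic — negligible for interior
  genes, conservative at edges.
* Origin-aware normalization makes levels incomparable across the partition
  boundary; use the simple mode when absolute genome-wide comparability
  matters.
* The exact Spearman permutation p enumerates n! permutations and is
  restricted to n ≤ 10.
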