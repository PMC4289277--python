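# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `cnevolve`. Everything quantitative stated here is
computed by the test suite (`tests/`) or by `scripts/acceptance.py`.

## Genome model and coordinates

A genome is an ordered set of chromosome arms tiled by fixed-size
windows (default 1 kb), 0-based half-open everywhere (BED convention;
GFF3's 1-based closed coordinates are converted at the I/O boundary).
The last window of an arm may be short; terminal windows under half the
window size are flagged and excluded from statistics to keep edge
artifacts out of density histograms. Windows with mappability strictly
below 0.9, or GC fraction outside the inclusive range [0.30, 0.45], are
masked: their values are retained but they enter no statistic, break
segments (no bridging of copy states across unmappable gaps), and bridge
significant regions without contributing length.

## Normalization and peak clustering

Count tracks are rescaled so the *modal density peak* — not the global
mean — sits at 1.0. The global mean drifts with a line's copy-number
burden; the dominant peak is the baseline state by construction.

Peaks are found by weighted agglomerative average-linkage clustering in
one dimension. For disjoint clusters of sorted scalar values, the
average pairwise dissimilarity between two adjacent clusters equals the
difference of their means (every cross-pair difference decomposes as
(x − mean_right) + (mean_right − mean_left) + (mean_left − y), and the
first and last terms average to zero), and the closest pair under this
linkage is always adjacent in sorted order. The full agglomeration is
therefore computed exactly as an adjacent-merge over value bins
(bin resolution: 1/50 of the merge threshold, far below any distance
that matters), merging the closest adjacent pair until no two adjacent
centers are closer than the minimum peak separation, 0.167 density-ratio
units — the spacing expected from hexaploidy, which bounds the
resolvable ploidy at 8. Clusters supported by fewer than 500 windows are
dropped; that count matches a full ~1.2e5-window 1 kb genome (~0.4%),
so the pipeline scales it for smaller genomes as 0.5% of unmasked
windows, floored at 50 and capped at 500.

The per-line calling chain (`cnevolve.pipeline.analyze_line`) clusters
*segment-median* values rather than raw window ratios: each window
carries the median of its provisional segment, which collapses every
copy state into a peak whose width is the standard error of a median
over tens of windows rather than the raw counting noise. Clustering raw
ratios at realistic noise (ratio cv ≈ 0.08) carves a single broad state
into several spurious ≥ 0.167-spaced clusters; clustering segment
medians does not. Peak centers are then refined to the median of member
values from *long* (≥ 8-window) segments only, because short segments'
medians scatter between states and bias cluster means. Anchoring and
ploidy peaks use autosomal windows only: a male line's halved X would
otherwise inject a peak at 0.5 that corrupts the spacing estimate.

## Minimal ploidy

Density ratios of copy states are fractions over a common denominator;
the smallest denominator is the minimal ploidy. The unit spacing is
estimated as the *median of adjacent-peak differences* — deliberately
not exact rational fitting, which is brittle against the few-percent
peak-center wobble real histograms show (plausible tolerances let a
wrong denominator fit a slightly wobbled quarter-step ladder). Minimal
ploidy is the modal (baseline) peak expressed in spacing units, rounded
half away from zero, capped at 8. A single peak is indeterminate
(minimal ploidy 1); a ladder in which any peak deviates from its nearest
integer multiple of the unit by more than a quarter unit is flagged
ambiguous, and the CLI then requires an explicit `--assume-ploidy`
override rather than guessing.

## Sex calling

DNA sex: X:A > 0.75 female, < 0.75 male, exactly 0.75 ambiguous, with
X:A the ratio of mean per-window coverage (Y:A can be restricted to a
trusted repeat-free interval of the Y scaffold). Marker sex, when a
marker table is supplied, is a majority vote of male-biased FPKM markers
(roX1/roX2/msl-2-like), female-biased ones (tra-like), and PSI markers
(male-like at PSI ≥ 0.5). The published marker calibration rests on a
sexed whole-animal RNA-Seq reference panel that is not shipped; the
fixed FPKM thresholds here (8.0 male-biased, 3.0 female-biased) are a
configurable stand-in. The final call is the DNA call unless markers
contradict it, in which case the line is reported ambiguous.

## Segmentation and copy states

The segmenter is a deliberately simple, deterministic greedy pass — the
scientific content of this pipeline lies downstream of segmentation, so
a transparent stand-in is preferred over a penalized-regression
segmentation. Within each unmasked run: a window extends the current
segment while it stays within half a copy unit (0.5/N in ratio units) of
the running median; segments shorter than `min_segment_windows`
(default 3) are absorbed into the neighbour with the closer median;
adjacent segments whose medians differ by less than the threshold are
merged. Re-segmenting a segmented track reproduces the same boundaries.
States are `round(median × N / baseline_peak)` with half-copy ties
rounded away from zero; class is high/normal/low against the ploidy
baseline; masked windows are undetermined. Genes take the state of the
window containing their TSS and are undetermined if any window
overlapping the gene body is.

The 3-window minimum bounds call resolution: events shorter than 3
windows, or short events fragmented by an interior masked window, are
absorbed and cannot be called. This is configurable but is the default
trade-off against noise-driven fragmentation.

## Recurrence statistics

Gains and losses are tested separately, one-sided. The null relocates
every line's changed windows uniformly over that line's determined
windows (class counts preserved). Two equivalent computations are
provided: Monte-Carlo label shuffling with the +1 pseudocount estimator
`p = (1 + #{K_perm ≥ K_obs}) / (1 + n_perm)` (never 0, never above 1),
and the closed form — under per-window exchangeability the count of
changed lines at a window is a sum of independent Bernoulli draws with
each line's genome-wide change frequency, a Poisson-binomial tail
evaluated exactly by convolution, grouped over windows sharing a
determined-line pattern. The pipeline uses the exact path; the
Monte-Carlo path is kept for verification against enumeration oracles.

Both paths assume per-window label exchangeability, which breaks spatial
autocorrelation: with real segment lengths the per-window tests are
anti-conservative, and BH rank-boosting across the correlated windows of
one long segment can manufacture significance. A segment-preserving
sensitivity mode (`method="rotate"`: each line's label vector circularly
shifted within each arm) is provided and restores calibration on
segmented null data; the exchangeable-null calibration tests therefore
use single-window changes, where the assumption holds. Cross-line
recurrence excludes the X: a male line's halved X is sex, not acquired
copy change, and would otherwise appear as a genome-scale recurrent
loss.

Per-window p-values are BH-adjusted (statsmodels); maximal runs of
windows with q below α (masked windows bridging without contributing)
become regions, annotated with whether they reach 5 kb; each region's
member p-values are combined with Stouffer's method (unit weights,
`Z = Σz_i/√n`); regional 2×2 enrichment uses the two-sided Fisher exact
test.

Power note: recurrence detection depends directly on panel size. A
driver carried by ~70% of 8 lines is statistically indistinguishable
from a ~20%-per-line changed-window background; the recurrence studies
therefore use a 19-line panel, at which penetrance-0.7 drivers are
recovered reliably.

## Breakpoints and hotspots

A breakpoint is a transition between consecutive determined windows on
one arm with different states, assigned to the left window (fixed
convention for cross-line matching); a transition across a masked run is
recorded once at the last determined window before it. A hotspot is a
window where at least `min_lines` lines break — default 5, the only
sharing threshold the source analyses state (used there for motif
work), flagged to users as an inference. The global hotspot count is
tested by relocating each line's breakpoints uniformly (without
replacement within a line) over unmasked windows. Annotation overlap
(repeat classes etc.) is strand-agnostic within ±1 window.

## Dosage response

All dosage arithmetic is in log2 space, where the dose offsets are
symmetric. Expressed genes (FPKM > 1) are centered on the expressed
normal-class median (0 by construction). For each non-normal state c
with at least 20 expressed genes, the expectation under one-to-one dose
response is log2(c/N) — including odd states on even ploidy — and a
two-sided Mann-Whitney U compares the state's centered values against
the *expectation-shifted* normal-class values: the question is departure
from proportionality, not difference from normal genes. The genome-wide
slope of log2 FPKM on log2(c/N) (with Spearman correlation alongside)
estimates the response exponent β: 1 proportional, < 1 buffered, 0
fully compensated.

## ChIP correlation

Signal tracks are step functions parsed from fixed/variable-step wiggle
or bedGraph. The mean signal over a region is area under the step
function divided by region length; positions a track does not cover
contribute zero area but full length (area-under-histogram semantics,
not missing data). Promoters are the 1 kb upstream of the TSS,
strand-aware ([TSS−1000, TSS) on +, (TSS, TSS+1000] on −); bodies are
the annotated gene interval. Pearson r between integer copy state (not
class rank) and signal is computed per region type; a correlation passes
at |r| > 0.1 and p < 0.001, tightened to 0.2 when the tested subset is
exclusively X-linked. Zero-variance input yields an explicit
no-correlation result. The expressed-only variant is a flag, defaulting
to all genes.

## Complex coherence

Per complex: ternary class composition over determined members
(undetermined members excluded from the denominator); one-sided
hypergeometric tails for high and for low over-representation against
the determined gene universe; the coherence flag — at least 2 changed
members and strictly more than 90% of them in one direction. The
catalog-level test reassigns the genome-wide class multiset to genes
without replacement (every permutation preserves the class counts
exactly) and recounts coherent complexes, `p = (1 + #{≥ obs})/(1 + n)`,
default 1000 permutations. The proximity filter excludes complexes with
any member pair within 500 kb (inclusive) on one arm — linked passengers
mimic coherence; exclusion depends only on coordinates, so it applies
identically to observed and permuted counts and can only reduce the
observed count. On the synthetic genome the filter distance is scaled to
10 kb, preserving the published rule's proportion (~2% of an arm).

## The synthetic generator

The generator defines the study conditions; defaults were chosen once to
emulate the statistical structure of a real cell-line panel and are not
tuned per analysis:

- **Genome**: 5 arms × 400 × 1 kb windows (2 Mb), X last. Small enough
  for seconds-scale replicated studies, large enough for ≥ 50-window
  density peaks.
- **Lines**: 8 (recurrence studies: 19), ploidies alternating 2/4, sex
  random; male lines have X-window states halved (integer floor).
- **Copy structure**: baseline state = ploidy; 6 shared driver regions
  (penetrance 0.7, redrawn until ≥ 2 carriers so recurrence is defined)
  plus Poisson(6) private segments per line; geometric segment lengths,
  mean 40 windows; gains:losses 0.8:0.2 (the observed genome-wide
  gain:loss block ratio in such panels is ≈ 4:1); gains add one copy,
  losses remove one, floored at 0. Together ≈ 20% of the genome altered
  per line, matching the reported scale. Drivers are planted at ≥ 8
  windows: the caller's 3-window minimum plus a possible interior masked
  window bound the size below which a planted driver would be
  unrecoverable by construction, and recurrent regions of interest in
  such data are themselves tens of kb. Driver coordinates are shared
  exactly by default; the optional per-carrier endpoint jitter
  (`driver_edge_jitter`, in windows) models independently arising
  rearrangements with nearby but non-identical breaks — the regime in
  which breakpoints are regionally, not precisely, shared — and is used
  by the regional-enrichment analyses.
- **Counts**: negative binomial with mean
  `depth × (state/ploidy) × gc_bias × mappability`, `var = μ + 0.002 μ²`,
  depth 200 reads/window — ratio cv ≈ 0.08, the sharp-peak regime
  windowed read densities show in practice; dispersion 0 is the
  deterministic limit. GC bias is a unimodal Gaussian curve (optimum
  0.375, width 0.15), 1.0 at the optimum; default GC profiles are tight
  around the optimum with ~2% out-of-range outliers, mappability is 1.0
  with ~2% low windows, so the masking rules are exercised.
- **Expression**: `log2 FPKM = baseline_g + β log2(state/ploidy) +
  N(0, 0.5)`, baselines N(5, 1) log2 units, 1500 genes of 1–5 kb placed
  uniformly. β defaults to 0.7 (the sublinear, buffered regime such
  panels show). The baseline level keeps the FPKM > 1 expression cutoff
  ≈ 4 sd below the loss-state mean — with a lower baseline the cutoff
  truncates loss-gene distributions and attenuates every slope estimate,
  an effect no sample size removes. Zero-copy genes are silent. No
  MSL-style compensation is modeled on the male X: the dose response
  applies to the halved X like any other region, so X-vs-autosome
  expression balance holds only under β = 0 (the compensated scenario
  used for that test).
- **Complexes**: 120 clusters, sizes 3 + Poisson(3); a planted-coherent
  complex draws ≥ 2 changed members from one direction's gene pool and
  pads with normal genes; the rest draw uniformly, hence background
  composition. Default coherent fraction 0.3.
- **Junctions**: Poisson inclusion/exclusion counts, 50:2 in the
  sex-concordant orientation; exclusion depth 0 gives the noiseless
  PSI ∈ {0, 1} limit.
- **Seeding**: one global seed; every stage (and every line within a
  stage) draws from its own `SeedSequence([seed, stage, index])` stream,
  so outputs are bit-identical across runs and adding draws to one stage
  never shifts another.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: read-level artifacts (duplicates,
mapping bias beyond a scalar mappability), empirical depth/dispersion
profiles of real libraries, subclonal or allele-specific copy number,
karyotype heterogeneity between cells, gene-specific (feedback) dosage
compensation, real protein-complex topology, and real repeat-driven
breakpoint hotspots (planted hotspots arise only from shared driver
edges).

## Numerical choices and degenerate inputs

Half-copy state ties round away from zero. PSI with both coverages zero
is a missing value, not 0. Stouffer inputs at exactly 0 or 1 are clamped
into the open interval with a warning. Permutation p-values use the +1
pseudocount. Fisher/hypergeometric tests reject empty or inconsistent
tables. Zero-variance correlation inputs return an explicit
no-correlation result. BH rejects p outside (0, 1]. The coverage-ratio
denominator must be positive; the numerator may be empty (ratio 0).
Peak-center refinement that collapses two peaks merges them
(count-weighted).

## Problem sizes used in checks

Replicated studies run at the default 2 Mb genome: 20 panels for
ploidy/sex recovery and slope recovery (4 exponents × 20), 10–20 panels
for calibration checks, 5–10 19-line panels for driver recovery,
10⁵ permutations for the Monte-Carlo-vs-enumeration comparisons (tiny
genomes, ≤ 4 lines × ≤ 12 windows), 2 × 10⁴ for the hotspot study, and
10³ for complex coherence — the same permutation depth the source
protocol prescribes for that test.
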