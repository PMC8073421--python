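# Methods

This note documents the models, conventions, defaults and known limitations
of `grtime`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Coordinates and formats

All genomic coordinates are 0-based half-open (BED convention).  Annotation
sources with 1-based inclusive starts are converted on read
(`read_annotation(one_based=True)`).  The TSS is strand-aware by default
(gene start for `+`, gene end for `-`); `tss_mode="naive-start"` reproduces
a literal "gene start = lower coordinate" reading.

Peak amplitude is the narrowPeak signalValue (column 7) when present, else
the BED score.  The BED score is capped at 1000 by the format; signalValue
is the actual measurement, so it is preferred.

Coverage is modeled as a piecewise-constant non-negative signal.  bedGraph
is the canonical text representation so the entire test suite runs without
binary formats; bigWig input is supported behind the same interface via
pyBigWig.  Bases covered by no record have value 0: they enter means and
never raise; querying an absent chromosome returns 0 with a logged warning.
Interval queries (max, length-weighted mean, bucketed means, leftmost
argmax) run on sorted segment arrays with binary search and a precomputed
cumulative integral, and are property-tested against per-base scans.

## Expression stage

**Quantile normalization.** The reference distribution is the across-sample
mean of sorted columns.  Ties within a column receive the mean of the
reference values at the tied ranks, which makes the map well defined and
idempotent.  A single sample passes through with a warning.

**Differential expression.** Per gene, one-way ANOVA with time point as the
grouping factor (≥ 2 replicates per time point required), followed by
Benjamini–Hochberg FDR across genes.  BH is used because it is the field
default where only "FDR correction" is specified.  Genes with zero variance
across all samples are assigned F = 0, p = 1 and flagged.

**Scaling and classification.** The replicate-averaged profile is z-scored
across time points (sample standard deviation, ddof = 1) and leveled to 0 at
the baseline time point.  A gene enters the up/down clusters only when its
FDR is below the main threshold (default 1e-7; a secondary 0.1 threshold is
used for the EP300 top-K overlap).  The call is the sign of the summed
leveled profile over t > 0 — more robust to single-time noise than the sign
of any one time point.  Zero-variance profiles have no z-score and are
excluded with a log entry.

**Random control genes.** Controls are drawn from non-regulated genes,
stratified jointly on deciles of mean normalized expression and deciles of
transcript length, matching the regulated set's stratum proportions
(largest-remainder apportionment).  Strata short of candidates are topped up
from the nearest stratum, with expression-level closeness outranking
transcript-length closeness, since expression matching is the primary
purpose of the control set.  The draw is deterministic given the seed.  The
control set size defaults to the number of regulated genes and is
configurable, since a fixed external size would be arbitrary.

**Outlier removal.** Before computing expression MWT, per-time-point
replicate values outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are
dropped.  Quartiles use the linear-interpolation convention (type 7, the
numpy/R default); with fewer than 3 values the data pass through.

**Expression MWT.** Forward differences of the cleaned, replicate-averaged
profile are attributed to the later time point.  Weights are clamped to the
cluster's direction by default (`max(d, 0)` for up): "time of maximum
expression change" for an upregulated gene means its upward dynamics, and
absolute weights would let post-peak decay drag the statistic late.
`weights="absolute"` exposes the alternative.  All-zero weights leave the
gene excluded with a log entry.

## Peak-to-gene mapping

Replicate peak sets are intersected base-wise (regions present in every
replicate; amplitude = mean of contributing replicate amplitudes); the
operation is commutative and associative over replicate order.

Window membership uses the **peak midpoint**: a peak belongs to a gene when
its midpoint lies within ±100 kb of the TSS, promoter iff |distance| ≤ 2 kb.
Midpoint membership makes the promoter/enhancer split a true partition — no
peak is counted as both.  Distances are signed along the gene (negative =
upstream on the gene's strand).  One peak may be assigned to several genes;
uniqueness is enforced only in the EP300 top-K path, where the convention
is one peak per gene keeping the higher NR3C1 amplitude.

The strongest-enhancer-peak selection runs at the 1 h reference time, the
time of highest overall GR binding; ties break toward smaller |distance to
TSS|, then smaller start, so the result is deterministic.  Nearest-gene
assignment minimizes |peak midpoint − TSS| with lexicographic gene-id
tie-break.

## Signal kinetics

Per-peak amplitude series use **maximum** coverage within the peak
coordinates (default) for the kinetic time courses, and **mean** coverage
for the EP300 dynamic-range scan — the latter mirrors an
average-over-region extraction, and the two summaries are exposed via
`mode`.

**Chip MWT** includes t = 0 in the weights and applies no baseline
subtraction; the statistic is the plain amplitude-weighted mean of time.  A
non-zero baseline biases MWT toward mid-course, which is why the synthetic
background is kept far below pulse height (see below); the alternative of
subtracting the baseline is left to the caller since it changes the
statistic's meaning.

**EP300 dynamic range** is max − min over times ≥ 0.5 h — the largest
absolute pairwise difference, direction-free.  Ranking ties break toward
larger NR3C1 peak amplitude, then smaller start.

**Centered average profiles** center each peak on the leftmost position of
maximal NR3C1 coverage at the reference time (summit-like), then average
10-bp-bucketed coverage over ±2 kb per factor × time × cluster.  Windows
running past a chromosome edge are zero-padded and logged.

## Group statistics

The time × cluster interaction ANOVA uses type-II sums of squares
(statsmodels OLS), which tolerate the unbalanced gene counts across
clusters; for balanced layouts this equals the classical cell-mean
computation, which the tests use as an independent oracle.  An all-constant
layout gets F = 0, p = 1 by convention.  Post hoc ratio tests and MWT
pairwise tests are Welch (unequal-variance) by default because cluster
variances differ; pooled-variance mode is available.  The MWT pairwise
family is expression-vs-each and NR3C1-vs-each (the shared pair counted
once, 7 tests for 5 groups), Bonferroni-multiplied by the number of tests
performed.  Cubic trend fits return ascending coefficients from a
least-squares Vandermonde solve; the expression-dynamics variant fits the
forward differences scaled ×100 for co-plotting.

## Synthetic data generator

The generator emulates the analyzed study's shape: a 0–12 h dexamethasone
grid (0, 0.5, 1, 2, …, 12 h), 200 up / 200 down / 2,000 null genes, 4
replicates.

*Expression.* Up genes follow μ(t) = b·(1 + A·logistic((t − t50)/s)) with
A = 4 (5-fold plateau), t50 = 4.8 h, s = 1.2 h; down genes divide the
baseline by the same factor; null genes are flat.  Counts are Gamma–Poisson
(negative binomial) with dispersion 0.01, typical of cell-line RNA-seq for
well-expressed genes and consistent with a study where hundreds of genes
clear an FDR 1e-7 threshold.  Regulated baselines are log-uniform on
50–500; null baselines span a wider 5–5,000 so the regulated genes sit in
the interior of the expression distribution, as their matched-control design
implies.  The noiseless-mean expression MWT (clamped weights, per-direction)
is recorded per gene as ground truth; with these defaults the up-gene
ground-truth median is ≈ 5.43 h.

*ChIP.* Each up gene gets one enhancer locus at a random offset in
±(2 kb, 100 kb] from its TSS (25% also get a promoter locus within ±2 kb);
24% of null genes get a static low-amplitude locus, so a flat "random"
background cluster exists; down genes get none.  Spatial profile is Gaussian
(σ = 150 bp) sampled at 10-bp bin midpoints with the locus center aligned to
a bin midpoint, so the track maximum equals the pulse amplitude exactly.
The temporal pulse is a(t) = H·(t/τ)^κ·e^{κ(1−t/τ)} with κ = 2 and H = 50
over a Poisson(0.25)-per-bin background (~50:1 peak-to-background, as for
strong GR peaks), rising from 0 at t = 0 and peaking at τ.  The default
pulse timescales τ = 3.52, 3.74, 3.98, 4.75 h for NR3C1, H3K4me1, H3K27ac,
EP300 place the discrete amplitude-weighted centroids on the default grid at
≈ 4.60, 4.80, 5.00, 5.55 h — chosen to emulate the kinetic ordering and
magnitudes reported for these factors after dexamethasone (GR earliest,
EP300 latest); this is a fixture choice, not a claim of mechanism.  Each
locus's exact discrete centroid per factor is stored as ground truth.
Overlapping locus windows sum their coverage contributions; locus centers
are re-drawn on collision (closer than twice the called peak half-width,
300 bp).  Peak calls are emitted wherever the pulse amplitude is positive,
with signalValue equal to the pulse amplitude.  A `noiseless` switch
removes background and count noise for exact-oracle tests.

*What the generator does not emulate:* read-level sampling, fragment-length
and GC bias, mappability gaps, replicate-specific peak calls (peaks are
emitted replicate-merged; the replicate-intersection operation is tested on
constructed inputs), inter-gene expression correlation, and genes regulated
with heterogeneous kinetics.  Passing tests therefore demonstrate that the
pipeline's machinery recovers known kinetics from data of the right shape
and noise family — not that any biological conclusion transfers to a new
dataset.

## Problem sizes and numerical choices

The default synthetic study (2,400 genes, ~730 ChIP loci × 4 factors × 12
time points) simulates and analyzes in well under a minute on one core;
the acceptance script adds a 50-replicate global-null Monte-Carlo (500
genes each) and a 500-replicate interaction-calibration Monte-Carlo.  These
sizes give Monte-Carlo error comfortably below the tolerances tested while
keeping the whole run interactive.

Tie-breaks are deterministic everywhere (documented per operation above);
all randomness flows through explicit integer seeds via
`numpy.random.default_rng`; output tables are written with fixed column
order and row sort, so a fixed config reproduces byte-identical outputs.

## Known limitations

- Quantile normalization under strong global regulation slightly distorts
  genes at the extreme ranks; in the default simulation this produces ~1% of
  null genes spuriously clustered even at FDR 1e-7.  This is a property of
  the normalization itself (the regulated tail reshapes the reference
  distribution), not of the testing stage — the global-null calibration is
  clean.
- The expression MWT attributes forward differences to the later time
  point; on a coarse grid this shifts the statistic late by up to half a
  grid step relative to the continuous-time centroid of the derivative.
- Type-II interaction tests and Welch post hocs are choices, not the only
  defensible ones; pooled-variance and alternative-weight variants are
  exposed as flags.
- The EP300 dynamic-range score ignores within-series ordering (range only),
  so monotone drift and a single transient excursion can score identically.
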