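# Methods

## Model and assumptions

The central assumption is dose doubling: in an S-phase cell a genomic
region that has replicated is present at twice its G1/G2 copy number,
so binned read depth carries the replication state. The pipeline
therefore reduces single-cell replication-timing (scRT) inference to a
chain of copy-number problems:

* read counts per fixed bin, corrected for mappability and GC bias,
  are piecewise-constant in the copy number (CN) up to Poisson noise;
* an S-phase cell's profile is a mosaic of the base CN and its double;
* normalising against the G1/G2 median profile turns that mosaic into
  a near-binary log2 signal (0 = unreplicated, 1 = replicated), which
  is thresholded per cell;
* averaging binary profiles across cells ordered by their replication
  percentage reconstructs the population RT track (1 = early).

Working at 20-kb count bins and 200-kb RT bins assumes replication
domains are not much smaller than a few hundred kb, which holds for
mammalian genomes.

## Copy-number calling

Counts on usable bins are divided by bin mappability and rescaled by
GC class (GC rounded to 0.01; classes under 20 bins merged with their
nearest neighbour; short terminal bins are corrected but excluded from
the median pools). Corrections preserve zeros and are equivariant
under global scaling of a cell's counts.

**Segmentation.** The default change-point detector evaluates the
circular (arc vs complement) mean-shift statistic
`|mean(arc) − mean(rest)| · sqrt(m(n−m)/n)` on a stride-5 grid with
exact local refinement, splits when the statistic exceeds
`sigma · (sqrt(2 log n) + 2)` (`sigma` a robust successive-difference
scale per segment), and recurses. The arc form matters: an S-phase
cell is an alternating mosaic whose best *single* split is
uninformative, so greedy binary segmentation stalls; arcs detect a
short doubled domain inside a flat background directly. A greedy
least-squares binary segmentation with a likelihood-ratio penalty is
available as `method="bic"`. On noiseless piecewise-constant input the
recovered breakpoints are exact; with noise at 5% of a step the
breakpoint is recovered within ±2 bins in ≥95% of replicates.

**Ploidy solving.** With segment mean counts `R_n` and sizes `S_n`,
`chi(X) = sqrt(Σ S_n sin²(π R_n/X))` is evaluated on a 2000-point grid
over the inclusive [5th, 95th] percentile window of segment counts
(order statistics, so small segment sets keep their extreme
candidates), local minima are refined by bounded scalar minimisation,
and `CN_n = round(R_n/X)` (half away from zero). Minima whose implied
mean ploidy falls outside the configured limits are discarded. When
the globally best minimum is infeasible, the octaves `X/2` and `2X` of
the detected minima are also evaluated: `chi` is near-periodic in the
unit, and a cell deep in S phase can have its true reads-per-copy
value just outside the count window. The ploidy confidence is the
`chi` gap between the best and runner-up feasible minima; gaps under 2
are flagged unreliable, and the solver defaults to limits (1, 8) while
the pipeline ships a dataset configuration of (1.5, 8) that rejects
the degenerate half-unit solution for near-diploid profiles (the
analogue of choosing per-dataset ploidy limits).

## DIMAPD and cell-cycle staging

Raw counts are aggregated to 500-kb bins; the vector of neighbouring
differences scaled by the cell mean gives MAPD, which multiplied by
the root coverage (`sqrt(total reads / genome Mb)`) is MAPDC. The
linear trend of MAPDC in the centred root coverage is estimated across
cells by Theil–Sen and removed, centring the statistic at 1
(`DIMAPD = 1 + MAPDC − a·(C−median C) − b`). A robust fit is essential
here: the replicating cells the statistic is meant to expose are
exactly the outliers that tilt an ordinary least-squares line.

Automatic staging fits the bulk of the DIMAPD distribution robustly
(median, 1.4826·MAD) and labels cells above the one-sided
`1 − alpha` quantile (default `alpha` = 0.01) as S phase; metadata and
manual thresholds (with an optional "unknown" gate) are alternatives.
Near-complete S cells are structurally indistinguishable from G1/G2
and are the known blind spot of any dose-based classifier.

**Two-branch correction.** The integer solver locks cells late in
S phase onto the doubled reads-per-copy unit, so their called ploidy
approaches the G1/G2 value from below. Cells below the G1/G2 median
ploidy form the second branch; a multiplicative shift is searched on a
grid and scored by preferring a monomodal corrected ploidy
distribution with maximal spread, falling back to a bimodal one with
minimal spread (spread = interquartile range, modes counted on a
Scott-rule KDE requiring a 25% valley between peaks). Because the artefact is a
unit error by an integer harmonic, segment CNs are re-derived at
`x_min / round(shift)` — the solver's own fitted unit then
self-calibrates the correction and insulates the copy numbers from
small errors in the fitted shift. The per-cell replication fraction is
`(P_corrected − P_G1G2)/P_G1G2` clipped to [0, 1].

The ploidy-median branch rule has a blind spot: a nearly dose-complete
S cell solved at the doubled unit can land marginally *above* the
G1/G2 median and stay uncorrected, collapsing its binary profile to
zero. Such cells are unambiguous at the profile level — a genuinely
early cell deviates from the G1/G2 reference upward (replicated bins
near +1) while a mis-unit cell deviates downward (unreplicated bins
near −1) — so after normalisation, cells whose nCN mass below −0.5
dominates the mass above +0.5 have their unit doubled and are rebuilt
(`flag_mis_unit_cells`, one refinement pass).

**Coverage threshold.** Reads are subsampled without replacement
(multivariate hypergeometric across bins) to target coverages; the
threshold is the smallest coverage at which ≥75% of cells re-estimate
ploidy within 5% of their full-coverage value, reported per haploid
genome; without a down-sampling run the default is 160 reads/Mb per
haploid genome.

## scRT extraction

Per 200-kb RT bin the overlap-weighted median of segment CNs is taken
(even splits resolve to the mean of the straddling values). The G1/G2
reference is the per-bin median across G1/G2 cells (zero or undefined
bins masked); with sub-population labels each S cell is normalised
against its own group's reference, which keeps sub-clonal CNV out of
the replication signal. Binarization minimises
`Σ (nCN − 1{nCN ≥ th})²` exactly: the loss changes by `2v − 1` as the
threshold passes a value `v`, so it is unimodal with its minimum
attained on the plateau around 0.5 and the exact optimum is found by
evaluating the data values as candidate thresholds (a 10⁻³ grid search
lands on the same plateau). Bins missing in ≥25% of cells are masked
matrix-wide.

The simple-matching-coefficient filter drops a cell whose binary
profile differs by ≥25% from ≥60% of its comparison set. In the
pipeline the comparison set is restricted to cells within ±0.1 of the
cell's replication percentage: across a whole asynchronous S phase,
early and late cells legitimately disagree on most bins, and an
aberrant cell is one that diverges from its own stage.

Pseudo-bulk RT averages profiles within 2.5%-wide replication-
percentage intervals, drops extreme intervals on the heavier tail
until the mean retained percentage is within 0.05 of one half, and
takes the unweighted mean of interval means, so uneven sampling of
S-phase progression does not bias the track.

## T_width and the bootstrap

Cells are placed at pseudo-time `replication percentage × 10 h`. For a
bin subset, per-cell replicated fractions are averaged within 0.25-h
windows, constrained to be non-decreasing by pool-adjacent-violators,
and `T_width` is the linear-interpolation spread between the 25% and
75% crossings. This estimator is exact on both reference shapes — a
linear ramp gives 5 h and a logistic front of scale `s` gives
`2·s·ln 3` — whereas a least-squares logistic fit is biased by >10% on
the linear ramp and was therefore not used. Known limitation: the
0.25-h windowing inflates very sharp fronts (`T_width` ≲ 1.5 h) by
about +2%.

The group comparison permutes bin labels between the two groups
(sizes preserved), recomputes both `T_width`s with the same estimator
and reports `p` as the plain fraction of permutations reaching the
observed absolute difference (no +1 smoothing; resolution 1/N,
N = 10⁴ by default).

## Heterogeneity and stochasticity

Embeddings take CNV matrices directly or scRT matrices through
pairwise simple-matching distances; t-SNE uses perplexity
`max(n/50, 10)`, theta 0.25 and 5000 iterations, and every embedding
requires an explicit seed. Gates are user-supplied rectangles or
polygons with closed boundaries; automatic clustering is out of scope.

Stage gates are ≤30% (early), 40–60% (mid) and ≥70% (late) of
replicated genome; per-bin replication probabilities are means over
the gated cells, and the early-stage probability doubles as the
initiation landscape handed to downstream replication simulators.
Out-of-schedule events are late bins (pseudo-bulk RT < 0.5) replicated
in early-stage cells and early bins (RT > 0.5) unreplicated in
late-stage cells. The headline per-stage event rate is the median of
per-cell rates: cells that completed replication but were solved at
the G1/G2 dose produce empty binary profiles, fall into the early gate
with a rate of exactly zero, and would bias a pooled estimate
downward. G1/G2 cells pushed through the same binarization provide the
technical noise floor.

## The simulator and what passing tests mean

`scrt.synth` generates the statistical structure the pipeline
consumes, with the following default study conditions:

* genome: three 100-Mb chromosomes (the 500-kb DIMAPD aggregation
  needs a few hundred bins for a stable median; ~600 bins gives a
  G1/G2 spread comparable to genome-scale data);
* RT landscape: a rank-uniform smoothed Gaussian field with 0.6-Mb
  correlation length, matching typical constant-timing-region sizes;
* temporal jitter: sd 0.12 of S-phase duration per cell and bin —
  chosen so the implied `T_width` (~2·1.2 h·ln 3 ≈ 2.6 h) matches the
  cell-to-cell variability observed in mammalian cells;
* out-of-schedule events: with probability `ectopic_rate` per cell and
  bin, a late bin fires at S entry or an early bin not at all (the
  fully-displaced form is what makes the injected rate recoverable as
  an early/late-stage event rate);
* clones: an aneuploid profile spanning CN 1–4 (the spread anchors the
  reads-per-copy unit, as real aneuploid genomes do), optionally with
  whole-chromosome gains distinguishing sub-clones;
* coverage: uniform 250–450 reads/Mb per haploid genome; counts are
  Poisson around dose × GC bias × mappability, with an optional
  over-dispersion knob; 20% of cells are in S phase, uniformly spread
  over 5–95% completion.

The generator works at the count level: amplification chemistry,
read-level artefacts, mappability structure of real genomes and
chromosome-scale karyotype complexity are not emulated, so passing
tests demonstrate correctness of the inference chain under its own
model assumptions, not performance on any particular platform's data.
Recovery on real data depends additionally on library quality and is
bounded by the known blind spots above (earliest/latest S cells).

Benchmarks in `scrt.evaluation` scale the problem to one CPU: 300-cell
populations for end-to-end recovery, 10⁴-cell draws for closed forms,
10⁴ bootstrap iterations for power. The recovery harness runs the
asynchronous workflow end to end: the automatic classifier stages the
cells (and is scored against truth), and the scRT chain runs on the
cells it calls — which also keeps dose-complete S cells, correctly
left in the G1/G2 pool, out of the early stage gate. Clone labels come
from the simulator, standing in for manual embedding gates. Four-group
separation in the CNV embedding is summarised by the mean silhouette
of the true (phase × clone) labels; S-phase cells form elongated
trajectories rather than compact clusters, so values above ~0.15
already indicate clean visual separation, and the G1/G2-only clone
silhouette is reported alongside (>0.5 for a whole-chromosome gain).

## Numerical choices and degenerate inputs

* Rounding is half-away-from-zero everywhere CNs are assigned.
* Weighted-median ties resolve to the mean of the straddling values.
* `chi` grids use 2000 points plus bounded refinement; ties between
  equal-`chi` minima resolve to the smaller X.
* Zero-variance DIMAPD distributions stage everything as G1/G2 with a
  warning; all-zero cells, empty stages, all-missing binarization rows
  and empty bin subsets raise.
* Embedding of identical cells returns seeded micro-jitter rather than
  feeding a zero-variance matrix to the optimisers.
* All randomness flows through explicit seeds; simulations are
  bit-reproducible given (model, seed).
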