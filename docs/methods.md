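# Methods

## Setting and model

The package evaluates copy-number aberration (CNA) detection from shallow
whole-genome sequencing (average depth below 1×) of DNA amplified from a
few cells.  At this depth individual positions are covered at most once on
average, so copy number is estimated at the level of fixed, non-overlapping
windows (1 Mb by default) tiling a genome model given as an ordered list of
named chromosome lengths.  All coordinates are 0-based half-open; BED is
the native interval dialect and chromosome names match as exact text.

The count model is Poisson: with mean depth `d`, read length `L`, window
width `w_i` and local copy number `CN_i`, the expected window count is

    lambda_i = (d * w_i / L) * (CN_i / 2) * b_i * g(gc_i)

where `b_i` is a multiplicative amplification-bias factor and `g` an
optional mean-one quadratic GC response.  At the default study conditions
(d = 0.8, L = 75 bp, w = 1 Mb) this is ~10,667 reads per window, so the
Poisson coefficient of variation per window is about 1%, far below the 50%
count shift of a single-copy change — which is why a clean 3 Mb event is
trivially detectable while a heavily biased profile is not.

## Synthetic data

The generator emulates the evaluation conditions of a few-cell WGA
sequencing experiment:

- **Truth karyotype.**  Default is a diploid female baseline (chrX at CN 2,
  chrY excluded).  The packaged reference karyotype is the six-event CNA
  set of the LOUCY leukemia cell line: loss of the whole X chromosome,
  distal ~72 Mb (5q) and ~45 Mb (6q) deletions, a ~3 Mb 13q duplication,
  and 13 Mb (16p) plus ~3.4 Mb (distal 16q) deletions.  The published
  characterization anchors these events to cytobands only, so the package
  fixes exact coordinates as constants, placing interior boundaries on
  1 Mb multiples; distal events run to the chromosome end.  Losses map to
  CN 1 and gains to CN 3 unless an explicit copy number is given; windows
  partially covered by an event take the length-weighted mean CN.
- **Bias regimes.**  `none` gives `b_i = 1`.  `lognormal` draws mean-one
  factors `exp(sigma*Z - sigma^2/2)`, keeping depth and bias orthogonal so
  median normalization is unaffected in expectation.  `hotspot` adds
  regional structure: region seeds arrive by a Poisson process
  (`hotspot_rate` per Gb), each spanning a geometric number of consecutive
  windows (mean `span_windows`, default 3) and multiplying them by
  `1 + 10*Pareto(hotspot_gain)`; dropout regions chosen the same way
  multiply by `dropout_factor` (default 0.05) and cover `dropout_prob` of
  windows in expectation.  Regional (multi-window) extent is deliberate:
  over- and under-represented stretches in heavily biased amplifications
  span many windows, and only spatially structured bias produces the
  false segmental calls that make such data uninterpretable.  Strictly
  window-independent bias would be invisible to a permutation-calibrated
  segmenter.
- **Read starts.**  Uniform sampling over the 2 × genome-length
  (position, strand) sites; a hotspot variant concentrates a configurable
  fraction of reads into ~48 kb pileup regions, the length scale of the
  read buildups seen in heavily biased libraries.
- **Determinism.**  Every generator consumes a single integer seed through
  `numpy.random.default_rng`; identical configurations give byte-identical
  outputs.

What the simulator does *not* model: base-level sequences and quality,
mappability structure of a real reference (annotations are drawn from
tight bells around GC 0.41 and mappability 0.95), real blacklist geography,
inter-sample correlation of bias, and amplification chemistry.  Passing
tests therefore demonstrate correctness of the machinery and its behavior
under controlled bias, not performance on any particular real library.

## Normalization

Counts are first rescaled by `window_size / width` so short terminal
windows do not masquerade as deletions.  Blacklisted windows (overlap
fraction with blacklist intervals >= 0.5 by default, or mappability < 0.2)
are excluded from every downstream statistic.  The GC/mappability
correction fits a quadratic least-squares surface in (gc, mappability) to
usable counts after trimming the extreme 1% tails, divides by the fitted
relative response (mean factor rescaled to 1), and degrades gracefully to
the identity when annotations are absent, constant, or the fit turns
non-positive.  A quadratic surface was chosen over local regression because
it needs little support, is exactly reproducible, and removes the simulated
quadratic GC signal to below |r| = 0.1; it cannot capture non-quadratic
response shapes.  Copy number is then `cn_i = 2 * corrected_i / median`,
the median taken over all usable windows genome-wide — valid exactly when
aberrations are rare enough that the median window is diploid.

## Segmentation and calling

CBS treats each chromosome's usable-window CN vector as a circle.  A split
is an unordered pair of cut points; each is enumerated once as an arc
(i, j] with both the arc and its complement at least `min_width = 2`
windows.  The two-sample t-statistic (pooled variance) between inside- and
outside-arc values is computed on `log2(cn + eps)` with
`eps = 1/median count`, which stabilizes zero-count windows; segment means
are computed and thresholded on the CN scale (mean of member windows, not
mean of logs).  The best arc is accepted when its permutation p-value is
below `alpha = 0.01` (10,000 permutations nominally, with two-sided early
stopping: reject as soon as the exceedance count's lower confidence bound
clears alpha, accept when `(e+4)/done < alpha` after at least 500
permutations; a zero-within-variance step is accepted outright).  Accepted
cut points partition the vector and the procedure recurses on each piece.
Ties in the arc scan resolve to the lexicographically first (i, j), and an
exhaustive-search oracle fixes the same convention.

Calls use strict inequalities on `log2(mean_cn / 2)` against ±0.35
(CN > 2.55 gain, CN < 1.57 loss, boundaries neutral); adjacent same-call
segments merge into one interval and neutral segments break adjacency.

## Dereplication and the bias statistic

Dereplication groups reads by (chromosome, position, strand) and keeps the
first occurrence, making it deterministic and idempotent.  Strand-aware
grouping (site count 2 × genome length) is the convention under which the
closed-form collision expectation `1 − (1 − 1/s)^(n−1)` reproduces the
sub-1% duplicate fractions expected at the study's read counts; the
strand-blind alternative would double the expectation.

The variance statistic `V = [1/(2(N−1))] Σ ((x_i − x_{i+1})/a)² − 1/a` is
assembled from adjacent usable window pairs, excluding pairs that span a
chromosome boundary or a masked window; `a` is the mean usable count and
the divisor counts pairs actually used.  This layout is the unique
adjacent-difference form for which the correction exactly cancels the
Poisson expectation (`E[((x_i − x_{i+1})/a)²] = 2/a`), so `V` is centered
at zero for bias-free data of any depth and equals exactly `−1/c` for
constant counts `c`.  It is computed on raw counts by default (a flag
switches to corrected counts).  Group comparisons use Welch's t-test with
Satterthwaite degrees of freedom; the degenerate all-constant case returns
p = 1 (equal means) or 0 (distinct means) by convention.

## Evaluation

A call is a true positive if and only if an unmatched truth event exists on
the same chromosome with the same direction, positive overlap, and
`|size_call − size_truth| / size_truth <= 0.10`.  Assignment is greedy by
descending overlap and one-to-one, so a truth event fragmented into several
size-matching calls yields exactly one TP and the remainder FP — the
conservative reading of a rule whose published statement covers only the
size criterion and the whole-chromosome false-positive example.  A call of
the correct size but with no overlap is FP.  PPV is undefined (NaN) when
there are no calls; replicate summaries exclude and count such replicates.

## Problem sizes and defaults

Simulation-backed checks use a 3,053-window hg19-like female genome or a
200-window single chromosome, 20 replicates for detection-rate claims,
12-vs-12 samples for the group comparison, and 1e6-read collision
simulations at the study's read/site ratio; these sizes put every
Monte-Carlo check at least three standard errors from its decision
boundary.  Key defaults: window 1 Mb; depth 0.8×; read length 75 bp;
CBS alpha 0.01, min_width 2; call threshold 0.35; blacklist overlap 0.5;
size tolerance 0.10.

## Known limitations

Segmentation is O(n²) per permutation in windows per chromosome and is not
optimized beyond vectorization; no outlier smoothing or undo-splits pruning
is applied, so isolated single-window spikes are (correctly, under
exchangeability) never split out but can drag segment means.  The GC
surface is quadratic only.  The evaluation counts events, not breakpoint
accuracy.  Real-data ingestion is limited to read-start tables plus an
optional BAM adapter.
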