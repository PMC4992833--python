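# shallowcna

Copy-number aberration (CNA) detection from shallow (< 1×) whole-genome
sequencing of whole-genome-amplified DNA — and a benchmark for how badly
amplification representation bias breaks it.

When only a handful of cells are available (pre-implantation diagnosis,
cell-based liquid biopsy), the DNA must be amplified before sequencing.
Amplification is never perfectly uniform: some regions are over-represented,
others drop out.  At shallow depth, CNAs are inferred from read counts in
fixed 1 Mb windows, so representation bias is read directly as spurious
copy-number signal.  This package implements the complete evaluation
machinery for that setting:

- **Binning and normalization** — read starts counted in non-overlapping 1 Mb
  windows, blacklist masking, GC/mappability correction, then median
  normalization: `CN = 2 · (window count / median window count)`.
- **Circular binary segmentation (CBS)** — each chromosome's window vector is
  treated as a circle; the arc maximizing the two-sample *t*-statistic is a
  candidate change-point pair, accepted by permutation test and recursed.
- **Threshold calling** — a segment is a gain when `log2(CN/2) > 0.35`
  (CN > 2.55) and a loss when `log2(CN/2) < −0.35` (CN < 1.57).
- **Dereplication** — reads sharing a (chromosome, position, strand) start are
  collapsed to one.  Under uniform placement of *n* reads over *s* stranded
  sites, the expected duplicate-start fraction is
  `1 − (1 − 1/s)^(n−1)` — under 1% for tens of millions of reads on a 3.1 Gb
  genome, so any large observed fraction indicts the amplification.
- **Representation-bias statistic** — the Poisson-corrected scaled
  adjacent-window variance

  ```
  V = 1/(2(N−1)) · Σ_i ((x_i − x_{i+1}) / a)²  −  1/a
  ```

  with window counts `x_i`, mean count `a`, and `N−1` genomically adjacent
  pairs.  For i.i.d. Poisson counts `E[V] = 0`: the `1/a` term exactly
  removes the variance due to random read generation, leaving only what
  sample processing (the amplification) added.  Groups of samples are
  compared with Welch's unequal-variance *t*-test.
- **Benchmark scoring** — calls match truth events only at the same direction,
  with overlap, and within 10% of the truth size; a whole-chromosome call
  over an arm-level event is a false positive.  Sensitivity = TP/|truth|,
  PPV = TP/(TP+FP).
- **Synthetic data** — per-window Poisson counts and read-start records at
  configurable depth, with a known truth karyotype (including the six-event
  LOUCY leukemia cell-line reference: five deletions and one ~3 Mb
  duplication) and a tunable amplification-bias model from none, through
  mean-one lognormal scatter, to Pareto-tailed regional hotspots and dropout.

## Worked example

```python
import shallowcna as sc

genome = sc.hg19_genome(include_chrY=False)          # female genome frame
truth = sc.loucy_truth_set(genome)                   # 6 reference CNAs
cfg = sc.SimulationConfig(genome=genome, truth=tuple(truth), seed=30000)
prof = sc.normalize_profile(sc.simulate_window_counts(cfg))
segs = sc.call_segments(sc.segment_profile(prof, sc.SegmentationParams(seed=0)))
calls = sc.segments_to_calls(segs)
res = sc.match_calls(calls, truth)
print(len(calls), res.tp, res.fp, res.fn)
```

prints `6 6 0 0`: at depth 0.8× with no amplification bias, all six LOUCY
events — including the whole-X loss and the 3 Mb 13q duplication — are
recovered exactly, with no false calls.  Running the same chain under the
heavy hotspot/dropout bias regime (`analysis/05_evaluate_regimes.py`) gives

```
none   summary: sensitivity 1.00 +/- 0.00, PPV 1.00 +/- 0.00
heavy  summary: sensitivity 0.00 +/- 0.00, PPV 0.00 +/- 0.00
```

the false-positive-dominated profile characteristic of strongly biased
whole-genome amplification.  The numbered drivers under `analysis/` walk the
full study: `01_simulate_cohort.py` (12 mild + 12 heavy samples),
`02_call_cnas.py` (calling + line profiles), `03_dereplication.py`
(duplicate-start expectations: 0.35–0.88% for 2.2–5.5 × 10⁷ reads),
`04_bias_variance.py` (variance statistic, Welch *p* = 0.019 heavy vs mild),
`05_evaluate_regimes.py` (sensitivity/PPV per regime).  Tables land in
`results/`, figures in `scratch/figures/`.

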