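# Methods

## Coordinate model

All intervals are 0-based, half-open (BED convention).  Two intervals
overlap when they share at least one base; intervals that meet only at
a boundary coordinate do **not** overlap, but they do merge in
`merge_regions` (the usual convention for adjacent half-open
intervals).  Strand is ignored everywhere: the statistics are
strand-blind.  Chromosome order is the order of the chrom.sizes file,
never lexicographic, so outputs are locale-independent.

Region sets are record collections, not merged territories: a
duplicated interval counts twice, and query sets are never merged
before counting.  This keeps reported counts equal to the record counts
of the input peak files.  Overlap counting defaults to *count-once*
semantics — each query region contributes at most 1 however many
reference regions it touches — which is the statistic a single
observed-overlaps bar summarizes; total-pairwise counting is available
via `count_mode="pairwise"` but is not the default.  `min_overlap_bp`
(default 1) requires the threshold to be met within a *single*
reference interval, not against the merged union, so two abutting
reference peaks cannot jointly satisfy it.

## Randomization model

A permutation draw re-places every query region uniformly at random,
preserving the region count and the exact multiset of lengths.

- **Strategy.**  `per_chromosome` (default) keeps each region on its
  own chromosome with a uniform start over the placeable span
  `[0, L − ℓ]`; it preserves the chromosome composition of the peak
  set.  `genome_wide` picks the chromosome with probability
  proportional to the placeable span for that region's length, then a
  uniform start.  The strategy used is echoed in every result so runs
  are self-describing.
- **Mask.**  Excluded intervals (e.g. assembly gaps) are avoided by
  rejection sampling, which is exactly uniform over the feasible
  placements.  Each region is retried up to `max_retries` (default
  1,000) before a hard error naming the offending region; a pathological
  mask (acceptance probability near zero) therefore fails loudly rather
  than biasing the null.
- **Self-overlap.**  Randomized regions may overlap one another
  (independent placement), matching the independence assumption of the
  null and avoiding an intractable packing problem for dense sets.
  `allow_self_overlap=False` switches to a sequential per-region
  rejection algorithm; it consumes the random stream in a different
  pattern than the vectorized default, so reproducibility is defined
  per policy, not across policies.
- **Reproducibility.**  Draw *i* of stream *s* uses
  `np.random.default_rng([seed, s, i])`.  Draws are therefore
  order-independent and parallelizable: evaluating permutations in any
  order, or splitting them across workers, reproduces the identical
  null.  The fast kernel used by `null_distribution` consumes exactly
  the same stream as the public `randomize_regions` path and is tested
  to agree draw-for-draw with it.

## Test definitions

With null counts `null_1..null_N` and observed count `obs`:

- empirical p (greater) = `(1 + #{null_i ≥ obs}) / (N + 1)` — the
  add-one estimator, never zero, bounded below by `1/(N+1)`; `less`
  mirrors it and `two_sided` is `2·min(one-sided)` capped at 1;
- `z = (obs − mean(null)) / sd(null)` with the sample standard
  deviation (denominator N − 1); when `sd = 0` the z-score is reported
  as an explicit undefined marker (`None` / `NA`) while the empirical p
  remains valid — a degenerate null is a reportable state, not a crash;
- `threshold_count_at_p05` is the smallest integer count whose
  upper-tail empirical p is ≤ 0.05, i.e. (k+1)-th largest null value
  plus one where `k = ⌊0.05·(N+1) − 1⌋`.

The differential test statistic is `obs₁ − obs₂` against one common
reference.  Its null randomizes **both** query sets independently per
permutation (streams 1 and 2) and takes the difference of their null
counts — the symmetric choice when the null hypothesis is that *both*
sets relate to the reference only through their sizes and lengths.  A
`first_only` variant (second count held fixed) is available and
labelled in the output.  `n_perm` below 20 is an error and below 100 a
warning; defaults are 500 for the single-set test and 1,000 for the
differential test, giving p-resolutions of ~0.002 and ~0.001.

The colocalization table counts regions of each set overlapping any
(default) or all of the companion sets; `mode="any"` is equivalent to
testing against the companions' union.  The Yates-corrected χ² uses
the closed form with the continuity term clamped at zero and errors on
any zero margin.  No multiple-testing correction is applied inside the
tests; the pipeline can append Benjamini–Hochberg adjusted values as an
extra column (off by default, raw p never overwritten).

## Synthetic generator

The generator emulates peak-scale interval data: a small genome
(default 2 chromosomes, 10 Mb + 5 Mb), a reference set (default 500
regions) and query sets (default 300 regions) with lengths uniform in
200–600 bp — the scale of typical ATAC/ChIP peak sets, shrunk to a
genome on which a full permutation test runs in tens of milliseconds.
At these densities a background query region hits the reference ~2–3%
of the time, so null overlap counts average ~8: non-degenerate, but
far from saturation.

Each query region is planted with probability *f* (anchored to a
uniformly chosen reference region, start jittered by up to ±`jitter`
bp, default 100, then clipped so ≥ 1 bp of anchor overlap survives) and
otherwise placed as background.  The clipping makes *f* an exact lower
bound on the overlap fraction, and the hidden truth vector supports
power accounting.  Scenarios: `null` (two background queries),
`enriched` (one planted query), `differential` (planted vs background,
equal sizes).  Bundles are pure functions of the config seed.

What the generator does **not** emulate: GC or accessibility-matched
backgrounds, peak-width/signal correlation, clustering of peaks along
the chromosome, and chromosome-count realism.  Passing calibration here
shows the machinery is correct under its own assumptions — uniform
placeability — not that uniform randomization is an adequate null for
any particular real genome; for real data a mask (and, where
appropriate, the per-chromosome strategy) is the main lever for making
the null biologically honest.

## Calibration behaviour and known limitations

Because overlap counts are small integers, the permutation null is
discrete and the add-one p-value is *super-uniform*: under the default
desk-scale conditions (null mean ~8 counts, N = 200 permutations) the
true rejection rate at α = 0.05 is ≈ 0.036–0.04 rather than the
nominal 10/201 ≈ 0.0498, i.e. the test is mildly conservative, never
anti-conservative.  The conservatism shrinks as the null mean grows or
N increases.  The differential null — a difference of two counts —
takes more distinct values and sits closer to nominal (≈ 0.045
measured).

Validation experiments use 200–1,000 replicates at N = 200
permutations, sizes chosen so the full battery runs in about a minute
on one core while leaving binomial noise well inside the decision
bands.  Other known limitations: rejection sampling can be slow (not
wrong) for masks covering most of a chromosome; the
`allow_self_overlap=False` path is quadratic in set size; and no
GC-matched or block-bootstrap nulls are provided.
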