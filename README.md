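# regiondiff

Permutation enrichment statistics for genomic region sets.

`regiondiff` answers a question that comes up constantly in regulatory
genomics: *do two sets of genomic intervals — say, ATAC-seq peaks that
lose accessibility in a disease condition and the ChIP-seq peaks of a
transcription factor — overlap more than chance would allow?*  It is
aimed at epigenomics analysts working with BED-format peak sets who
need calibrated enrichment statistics, a differential version of the
test for comparing two peak sets against a common reference, and a
synthetic data generator to validate the whole machinery without any
external download.

## The statistics

**Permutation enrichment test.**  For a query set *Q* of *n* regions
and a reference set *R*, the observed statistic is the count-once
overlap

&nbsp;&nbsp;&nbsp;&nbsp;obs = #{ q ∈ Q : q shares ≥ 1 bp with some r ∈ R }

under 0-based half-open (BED) coordinates.  The null is built by
re-placing *Q* uniformly at random over the genome *N* times (region
count and length multiset preserved; per-chromosome by default; masked
bases avoided by rejection sampling) and recomputing the count.  The
test reports

- z = (obs − mean(null)) / sd(null),
- the add-one empirical p-value p = (1 + #{null_i ≥ obs}) / (N + 1),
- the smallest count that would reach p = 0.05 (the significance bar
  of the classic permutation plot).

**Differential permutation test.**  For two query sets Q₁, Q₂ and one
reference R, the statistic is the difference of overlap counts
d = obs₁ − obs₂.  Each permutation independently randomizes *both*
query sets and records the difference of their null counts, giving a
null distribution of differences; z and the empirical p are computed
against it exactly as above.  This asks whether Q₁ intersects R more
often than Q₂ *to a degree beyond what their sizes and region counts
explain*.

**Colocalization χ².**  Given two region sets and companion set(s),
`colocalization_table` builds the 2×2 table (colocalized / not, per
set) and `yates_chi2` applies the continuity-corrected chi-square
statistic N·(|ad − bc| − N/2)²₊ / ((a+b)(c+d)(a+c)(b+d)) with 1 df.

**Synthetic generator.**  `make_scenario` produces genomes and region
sets with a *planted fraction f* of query regions guaranteed (by
clipped jitter around a reference anchor) to overlap the reference —
a known ground-truth effect size for calibration and power studies.

## Worked example

Simulate a differential scenario — 500 reference peaks, two query sets
of 300 peaks each on a 15 Mb two-chromosome genome, `query_1` with 90%
of regions planted onto the reference, `query_2` pure background:

```bash
$ cat cfg.yaml
planted_fraction: 0.9
seed: 5
$ regiondiff simulate --scenario differential --config cfg.yaml --out demo
differential bundle written to demo

$ regiondiff permtest demo/query_1.bed demo/reference.bed \
    --genome demo/genome.chrom.sizes --n-perm 500 --seed 7
observed=272	null_mean=7.954	null_sd=2.672	z=98.8017	p_empirical=0.00199601	threshold_p05=13
```

272 of the 300 query regions overlap a reference peak, while random
placement yields ~8 ± 2.7 — a z-score of 98.8 and the smallest
empirical p attainable with 500 permutations, 1/501 ≈ 0.002.  Any
observed count ≥ 13 would have cleared p = 0.05.

```bash
$ regiondiff diffperm demo/query_1.bed demo/query_2.bed demo/reference.bed \
    --genome demo/genome.chrom.sizes --n-perm 1000 --seed 7
observed_1=272	observed_2=8	observed_diff=264	null_mean=0.148	null_sd=3.896	z=67.7273	p_empirical=0.000999001

$ regiondiff coloc demo/query_1.bed demo/query_2.bed \
    --genome demo/genome.chrom.sizes --companions demo/reference.bed --mode any
a=272	b=28	c=8	d=292	chi2_yates=463.185	p=9.74377e-103	df=1
```

The differential test finds the 264-count gap between the two query
sets far outside its null of differences (z = 67.7, p = 1/1001), and
the colocalization table confirms the two sets differ sharply in their
companion overlap (Yates χ² = 463.2, p < 0.0001).

The same analyses run declaratively from a YAML manifest
(`regiondiff run --manifest m.yaml --out dir/`), producing
`enrichment.tsv`, `differential.tsv`, `colocalization.tsv`,
`filters.tsv`, `run.json` and `run.log`, reproducible bit-for-bit from
the manifest seed.

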