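# Methods

## Problem and model

The package characterizes one *reference* sample against two
*comparison* samples using 1–3 pre-normalized omics matrices (features:
e.g. expression, copy number, methylation, variant allele frequency),
merged by inner join on the gene identifiers in the first column.  The
user states a profile — a direction of change, "up" or "down", per
feature — and the method ranks genes by their joint support for that
profile and cuts the ranking into gene sets.  The analysis makes no
distributional assumption about the input values beyond finiteness; all
cross-feature comparability comes from rank standardization.  Inputs are
assumed pre-processed and normalized within samples; the package does no
normalization of its own.

## Profile statistic

Per gene and feature, the raw directional support is the mean
reference-minus-comparison difference, negated for "down" profiles, so
larger is always better.  Raw differences are standardized to rank
proportions rank(d)/G with average ties, giving per-feature scores in
(0, 1]; the profile statistic is their sum across features.  This
statistic is a deliberate canonicalization, chosen because it is
(a) ascending-sortable for change-point segmentation, (b) strictly
positive, so per-feature percent contributions are well defined, and
(c) invariant to positive rescaling of any feature, so matrices from
different platforms can be combined.  It is not a reproduction of any
particular published scoring formula.  Final ordering ties are broken by
lexicographic row ID, making results tables bit-reproducible.

Consequence worth knowing: because ranks are uniform by construction,
the ascending statistic series is always a near-linear ramp over (0, F)
with structure only in its ties and extremes; signal appears as a
compact, elevated cluster at the top of the series.

## Change-point segmentation

Detection runs on the ascending-sorted statistic series.  Segment costs
are Gaussian:

- `mean` — residual sum of squares about the segment mean
  (minimum segment length 1);
- `variance` — m·log σ̂² with the mean fixed at the *global* series mean
  and σ̂² the segment's mean squared deviation from it (minimum length 2);
- `both` — m·(log 2π + log σ̂² + 1) with the segment's own MLE mean and
  variance (minimum length 2).

Variance estimates are floored at 1e-12 so costs stay finite on constant
segments.  A segmentation is scored as Σ segment costs + penalty per
change point; the default penalty is MBIC-like, k·log n with k = 3 for
mean/variance and k = 4 for the joint cost, and is user-overridable.
Four searches are provided: AMOC (single best split), binary
segmentation (greedy, bounded by `max_cpts`), PELT and segment
neighborhood (both exact for the penalized objective; segment
neighborhood subject to its `max_cpts` bound).  "SeqNeigh" is accepted
as a spelling variant.  All searches are deterministic; equal-cost
splits resolve to the smaller index, equal-cost segment counts to the
smaller count.

One numerical subtlety: PELT's candidate pruning with constant K = 0 is
provably safe only for the `mean` cost, where every position may end a
segment.  With the 2-point minimum segment length of the variance-based
costs, a pruned candidate can become optimal again (the soundness
argument extends the dominating candidate by one point, which the length
constraint forbids), and exhaustive enumeration on short series exhibits
real violations.  The implementation therefore prunes only for `mean`
and otherwise runs the unpruned optimal-partitioning recursion — the
exact optimum is the contract, pruning only a speed-up.

Group numbering counts from the top of the sorted series: the segment
with the largest statistics is group 1.  A change-point index is the
last position of its segment, so the boundary gene belongs to the lower
group.  With zero change points every gene is group 1.

### Default settings

The package defaults are `change_type="both"`, `method="BinSeg"`.  On a
ramp-shaped ranked series the pure mean cost places its few affordable
change points mid-series and never isolates a small top set, while the
full-likelihood cost rewards the low internal variance of a compact top
cluster.  Among the searches, the greedy binary segmentation stops
splitting earlier than the exact optima, which (because short
low-variance segments have strongly negative likelihood cost) tend to
subdivide the top cluster into several adjacent groups.  These defaults
were selected with the package's own planted-signal benchmark as the
configuration that best isolates a planted top set; users segmenting
series with different structure should revisit them.  When the top set
does get split across adjacent groups, the `--up-to` display cutoff is
the intended remedy.

## Diagnostics

The slope of a gene in one feature is the mean comparison-minus-
reference difference divided by the feature's global value range
(max − min over the whole matrix): a ratio of differences that is
comparable across features and is negative for genes matching an "up"
profile (lower-left corner of the slope plot) and positive for "down"
(upper-right).  This is a canonicalization of the loosely specified
"ratio of differences" diagnostic; per-group values are arithmetic means
over member genes.  Distribution summaries are five-number summaries
(min, Q1, median, Q3, max) of the raw input values per feature and
sample role over genes in the displayed groups; quartiles use the
linear-interpolation convention.

## Percent decompositions

Between-sample: within one feature, each sample's percentage of the
three-sample sum, after shifting all three values by −min(0, min) so
contributions are nonnegative (negative inputs such as log-ratios
otherwise break the notion of "percent of total"); a zero shifted sum is
reported as undefined rather than an error.  Between-feature: each
feature's rank-proportion score as a percentage of the gene's profile
statistic (always defined, since scores are ≥ 1/G).  Every emitted
percentage vector sums to 100 within 1e-9.

## Synthetic data generator

`SyntheticSpec` plants `n_planted` of `n_genes` genes whose reference
value is shifted by `effect_size`·`noise_sd` in the profile direction of
every feature simultaneously, over i.i.d. Normal(0, `noise_sd`)
backgrounds with three samples and independent features.  Defaults —
200 genes, 10 planted, 2 features up/up, effect size 6, unit noise —
describe a strong, clearly separable signal: the benchmark regime the
test suite uses for recovery checks.  The generator emulates merged,
already-normalized matrices only; it does not model dropout, platform
bias, feature correlation, heavy tails or batch effects, so passing
recovery tests demonstrate correctness of the pipeline's mechanics, not
performance on real assay noise.  Everything is deterministic given the
seed, and fixtures round-trip through the package's own file format.

At these defaults the pipeline virtually always places the change point
separating planted from background genes correctly (the top-cluster
boundary), but the exact searches may add further change points inside
the planted cluster, so group 1 alone can be a strict subset of the
planted set — see "Default settings" above.

## Problem sizes in the test suite

Unit and property tests run on 4–200-gene matrices.  Exactness of
PELT/segment neighborhood is checked against exhaustive enumeration of
all segmentations on 100 seeded series of length ≤ 12 per cost type, and
the two exact searches are cross-checked on 100 seeded series of length
500.  Recovery and null-calibration checks use 20 seeds of the default
generator; conservation checks use 1000 random genes.

## Known limitations

- Exactly three sample roles; additional columns are carried but ignored
  by the scoring.
- Missing values are rejected rather than imputed.
- Rank standardization discards effect magnitudes: a gene barely above
  the comparisons and one far above can receive similar scores when the
  ranking is unchanged, and the ranked series' ramp shape limits what
  mean-type change-point detection can find (see above).
- The between-sample decomposition operates on raw (min-shifted) input
  values; transformed inputs (e.g. log scale) decompose on that scale.
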