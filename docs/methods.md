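# Methods

This note documents the statistical and algorithmic choices behind
`annotlink`: what each operation computes, the conventions adopted where
more than one was defensible, what the synthetic generators emulate, and
what the test suite does and does not establish about real data.

## Data model

A cell table is a rectangle of annotations — one row per cell, each column
tagged *categorical* (string values) or *numeric* (finite reals) — with a
unique, non-empty string `cell_id` per row. Missing values are first-class
in both kinds and are excluded from all counts unless an operation says
otherwise.

**Kind inference.** A column read from text is numeric iff every
non-missing entry parses as a finite real; anything else (including `inf`)
makes it categorical. Integer-coded cluster labels therefore come back
numeric from csv unless forced categorical through a per-column override
(TOML config, `[kinds]` table). Typed formats (feather, h5ad `obs`) take
kinds from the stored dtype, so a string-typed "1"/"2" column keeps its
categorical tag across feather round trips.

**Missing-value dialect.** On csv read, the empty string and the literal
`NA` are missing; on write, missing becomes the empty string. The dialect
is fixed rather than configurable-by-default so that write→load round
trips are stable (the config can widen the read-side token list). Floats
are written with shortest-repr formatting and parsed back through Python's
float conversion, which is round-trip exact; pandas' faster C parser is
not, and is deliberately avoided on the numeric path.

**h5ad.** Only the per-cell metadata (`obs`) and its index are read. The
package is annotation-centric: no operation touches an expression matrix,
so loading one would only cost memory.

## Filtering

Filters compose conjunctively, at most one per column. Categorical filters
keep rows whose value is in the included set, XOR an invert flag; numeric
ranges are inclusive on both ends (slider semantics). A row missing a
filtered value fails that filter *in both invert states*: an include-set
membership test cannot be asserted either way for a missing value, and
making the convention explicit keeps retained counts reproducible. The
consequence, checked by property tests, is that kept + inverted = total
only over rows non-missing in the filtered column.

## Correspondence statistics

All pairwise statistics use **pairwise-complete** records: a cell missing
either of the two columns under comparison is dropped from that statistic
only. In river models over three or more columns this means each
adjacent-column link set uses its own complete pairs, and count
conservation (link totals = node counts) holds per adjacent pair restricted
to those pairs — not listwise across all columns. Pairwise completion
maximizes usable data when studies annotate different subsets of cells.

- **Counts**: n_ij, summing to the number of complete pairs.
- **Row/column fractions**: n_ij divided by its axis total; empty axes stay
  all-zero rather than NaN.
- **Jaccard**: J_ij = n_ij / (n_i· + n_·j − n_ij). The denominator is the
  union of the two record sets; it is zero only when both sets are empty
  after filtering, and J is then defined as 0 ("no relationship").

**Label ordering.** If an annotation-info table covers a column, its row
order dictates display order. Values it does not list (and columns with no
info at all) fall back to descending record count with lexicographic
tie-break, which puts the dominant categories first in plots.

**Direction tallies.** The direction vocabulary is fixed to
{up, down, unchanged, unknown}; any other string in an info file maps to
unknown with a warning. A value breakdown tags each matched value with its
direction, and the concordance tally reports per compared column the
direction counts and the argmax ("dominant") direction, with ties —
including the empty tally — reported as unknown. `by_value` weighting
counts each distinct matched value once; `by_cell` weights by record count,
which favors the direction of the bulk of cells rather than of the most
labels.

## Probabilistic harmonization

Given shared cells carrying both a reference label s and a study label c,
the proportion table is the maximum-likelihood conditional
p(c | s) = n_sc / n_s over cells complete in both columns. Reference labels
present in the column but never co-observed with a study label receive the
reserved distribution {`noMappedCells`: 1}; the same reserved label is
assigned (with a warning, not an error) to reference labels that appear at
assignment time but were absent from the proportion table — taxonomy
mismatch is an expected condition, not a bug. `noMappedCells` passes
through broad-label inference verbatim, and input tables using it as a
genuine category draw a validation warning.

**Randomness.** Assignment consumes exactly one uniform variate per table
row, in row order, from a generator seeded per call (`numpy` PCG64). Rows
with a missing reference label still consume their variate (they receive
missing); this keeps the draw stream aligned with row positions, so the
assignment for row i depends only on (table, proportions, seed, i) and runs
are bit-reproducible regardless of how rows are grouped internally.

**Resolution levels.** Broad labels are inferred from fine ones through an
explicit total mapping; coarsening the proportion table first and assigning
at broad resolution agrees in distribution with assigning fine labels and
coarsening after, which the suite checks empirically at a battery of fixed
seeds.

Whether to subsample reference cells before or after assignment is left to
the pipeline; the CLI's `harmonize --subsample-cap` subsamples first, which
keeps the assignment draw count (and hence the draw stream) tied to the
subsampled table.

## Even-by-cluster subsampling

"Even" is implemented as iterative waterfilling: the even share is the
remaining cap divided (integer division) by the number of unsettled
clusters; clusters at or below the share are kept whole and removed from
the pool; the share is then recomputed. The loop terminates with every
remaining (large) cluster at a common share. Properties: no nonempty
cluster is emptied; the retained total never exceeds the cap and falls
short of it by at most one record per cluster (integer division); per-
cluster retained counts depend only on the size profile and cap, not the
seed — the seed only selects which rows survive, uniformly within each
cluster. Missing cluster values form the pseudo-cluster `(missing)` so
unlabeled cells are subsampled like any others instead of silently dropped.
The default cap is 500,000 records.

## Synthetic generators

The generators are first-class, tested code and define the conditions the
suite runs under:

- `make_toy_neurons` — 9 records. Sizes are fixed constants chosen so the
  two-group split (threshold 15) and the three-group split (thresholds
  13, 19) nest consistently; the ninth neuron's first-pass label is missing
  because it did not exist at first classification, so the 8-cell overlap
  emerges from the data model rather than from special-casing.
- `make_taxonomy_pair` — one record per planted cell; study labels drawn
  row-wise from a row-stochastic mixing matrix at a fixed seed. This is the
  ground truth for harmonization recovery: with n cells per reference
  label, empirical conditional frequencies converge to the matrix at the
  binomial rate √(p(1−p)/n).
- `make_numeric_fixture` — k clusters assigned round-robin; coordinates
  Gaussian around centers spaced 6 units apart (SD 1) and a feature spaced
  4 units (SD 1), i.e. well-separated clusters whose planted means are
  recoverable within CLT error.

What these emulate is the *annotation structure* of real studies —
overlapping categorical labelings, partial coverage, missingness, planted
conditional dependence. What they do not emulate: gene expression, doublets
and ambient contamination, donor and batch structure, or label noise that
correlates with cluster boundary geometry. Passing tests therefore
establish the correctness of the bookkeeping and the estimators under their
stated models, not the biological validity of any particular crosswalk.

## Test and acceptance problem sizes

The suite verifies exact agreement of crosstab/Jaccard/fraction/river with
a per-record brute-force enumeration on 1,000 random tables of up to 500
records; harmonization recovery uses a 5×4 mixing matrix with 50,000 cells
per reference label, checked at a fixed seed and as a 100-seed battery
whose 3-SE exceedance rate must stay near the ~0.27% the normal
approximation predicts; the subsampling check runs a 600,000-record,
10-cluster table at the default cap. These sizes make the binomial and
hypergeometric tolerances tight enough to catch estimator errors while the
whole suite runs in about a minute.

## Rendering

Plots are dot plots, node/ribbon polygons, jittered swarms and scatters in
matplotlib (Agg). Dot areas scale linearly from `min_dot` (at 0) to
`max_dot` (at the metric's maximum). Direction colors are four fixed,
distinct defaults (up `#d7301f`, down `#0570b0`, unchanged `#4daf4a`,
unknown `#bdbdbd`). Every renderer can emit its plot-ready numbers (sizes,
positions, ribbon geometry) as a CSV/JSON sidecar; tests assert on those
sidecars, never on pixels, which are brittle across backends. Raster output
embeds fixed metadata so reruns at the same seed are byte-identical.

## Known limitations

- No statistical tests of association (chi-square and relatives) and no
  differential-abundance modeling: the package compares and tallies, it
  does not re-estimate disease effects.
- Kind inference cannot distinguish integer-coded categories from counts
  without an override.
- csv round trips of categorical columns whose every value parses as a
  number require the same override on reload; feather preserves the tag.
- River layout is a simple stacked layout without crossing minimization;
  very many categories per column will overlap labels.
- Harmonization treats cells as exchangeable within a reference label;
  any within-label substructure a study resolved is deliberately averaged
  over by the conditional-proportion model.
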