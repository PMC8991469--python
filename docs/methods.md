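# Methods

## Data model

A dataset is a typed schema plus a list of samples; each sample pairs a
sorted region list with a metadata multiset. Design choices that the model
itself leaves open:

- **Coordinates** are 0-based half-open `[left, right)`. This is the BED
  convention, makes adjacency (`a.right == b.left`) unambiguous, and gives
  `length = right − left` with no off-by-one. Zero-length regions are
  rejected.
- **Strand alphabet** is `{+, -, *}` with `*` meaning "either strand". Two
  regions are strand-compatible when equal or when either side is `*`.
- **Metadata are schemaless strings.** One key may carry several values;
  exact duplicate pairs collapse; keys and values are stored verbatim with no
  case folding. Numeric interpretation is attempted only at comparison time:
  a comparison is numeric when both sides parse as numbers, `==`/`!=` fall
  back to string comparison otherwise, and order operators on a non-numeric
  value raise an error naming the key and value rather than silently
  comparing lexicographically.
- **Aggregates**: `MEDIAN` of an even count is the mean of the two central
  values; `STD` is the sample standard deviation (n−1 divisor) and is
  missing for fewer than two values; `BAG` joins the sorted distinct string
  forms with `;`, making it order-independent and deterministic. An
  aggregate over an empty region set is 0 for `COUNT` and missing otherwise;
  missing aggregate values add no metadata pair in `extend`.
- Metadata attribute names are matched exactly. Namespace-prefix matching
  (treating `a.b.key` as a match for `key`) is a possible extension but is
  not implemented; the `left.`/`right.` prefixes added by binary operators
  are therefore ordinary, fully spelled-out key names.

## Operator semantics

- **Signed distance** between same-chromosome regions is
  `later.left − earlier.right` under half-open coordinates: overlap is
  negative, adjacency exactly 0. `DLE(n)`/`DGE(n)` bound this quantity.
- **MD(k) ranking** uses `max(dist, 0)`: every overlapping candidate ranks
  equally closest, so a gene overlapping its anchor is always the
  minimum-distance match. Ties break by larger overlap length, then smaller
  candidate `left`, then smaller `right` — a total order, so results are
  deterministic.
- **UP/DOWN** are measured strand-aware from the anchor's 5′ end, with `*`
  treated like `+`; a candidate must lie entirely on the named side, so
  overlapping candidates satisfy neither clause. Whether the upstream side
  should be measured from the region start instead is an open interpretation;
  the 5′-end reading is the one implemented.
- **Samples emptied by region filtering are retained** with zero regions.
  This preserves metadata-level bookkeeping — after a region filter,
  `extend(COUNT)` can still observe a 0 — at the cost of carrying empty
  samples forward.
- **`order`** re-sorts regions by coordinates after applying `rtop`, because
  the sample invariant (regions always coordinate-sorted) takes precedence;
  region-key ordering is therefore observable only through which regions
  `rtop` keeps. Missing sort keys place last ascending (first descending);
  sample ties break by id, giving a stable, deterministic order.
- **`cover` strand classes**: regions are partitioned into `{+,*}` and
  `{-,*}` classes and covered per class, but a stranded class is emitted only
  when at least one region of that literal strand exists. A dataset of only
  `*` regions forms a single unstranded class — without this rule, unstranded
  inputs would be covered twice whenever the other class existed. `AccIndex`
  is the maximum accumulation inside a run; run aggregates are computed over
  the input regions overlapping the run.
- **Derived sample ids** are `<op>_<8-hex sha1 of parent ids>`, and
  `union` prefixes ids with `left_`/`right_`; both are pure functions of the
  parent ids, which keeps every materialized output byte-deterministic.
- **`map`'s implicit count attribute** is named `count_<ref>_<exp>` from the
  dataset labels (directory stem on read, step name in pipelines), matching
  the naming a user sees in their query.

## Lazy evaluation

Graph construction stores only operator names, parameters and parent links;
path existence is validated eagerly (fail fast on typos) but no region row
is parsed until `execute`/`take`. The I/O layer counts opened region files
and parsed rows, which is how the laziness contract is tested rather than
merely asserted. Caching is per-execution only — a node shared by two
branches runs once within one `execute`, and nothing persists between runs,
keeping repeated executions byte-identical. A failing node marks its
descendants skipped while independent branches still materialize. No query
optimization (e.g. predicate pushdown) is performed; deferral exists for
API symmetry and caching, and optimizations can be added behind the same
interface later.

## HOT-zone analysis

1. **Length threshold.** All region lengths pooled over samples are sorted
   ascending and the length at 1-based index `ceil(p·n)` is taken (default
   p = 0.95). Regions at least as wide as this superior threshold, or not
   wider than the inferior threshold (default 100 bp), are discarded: very
   wide binding regions would inflate the TF count over every base they
   span, and very short ones are likely artifacts.
2. **Accumulation vector.** For each base of the covered span
   `[min left, max right)` of the chosen chromosome, the number of
   *distinct* TF labels with a region covering the base — replicate regions
   of one TF count once. A half-window `w` widens every region by `w` bases
   on each side before counting (and widens the span accordingly); the
   default `w = 0` counts exact overlap.
3. **Zone calling ("overlaps" method).** `TH = mean + 2·sd` computed over
   every base of the span, including interior zero bases — the span-based
   reading of "all and only the bases of the accumulation vector"; whether
   zero bases outside any region's span should also enter the mean is an
   open interpretation, and this implementation excludes them by
   construction. The sd is the sample standard deviation, the prevailing
   statistical default. Zones are maximal runs with accumulation strictly
   above TH; a constant vector therefore yields no zone.

## Synthetic data

The generators define the study conditions for all tests; they are seeded
`numpy` RNG functions whose outputs are byte-identical per seed.

- **Chromosome model**: 2 chromosomes of 100 kbp — desk scale, large enough
  for coverage statistics to be non-degenerate, small enough for per-base
  oracles.
- **Mutations + genes** (default 20 patients, 50 genes, rate 0.5): gene
  regions 500–2000 bp, non-overlapping with 50–200 bp gaps, so every 1-bp
  mutation lies in exactly one gene; per-(patient, gene) mutation counts are
  Poisson(rate) and recorded in a truth table, making the stochastic fixture
  an exact oracle for the map pipeline. Patient ages are uniform over 40–85
  so an under-65 filter selects a non-trivial subset.
- **TF peaks** (default 10 TFs, 30 peaks each): peak lengths are mostly
  150–400 bp, with ~5% short (30–80 bp) and ~7% wide (3–8 kbp) peaks so the
  length-percentile filter has genuine outliers to remove. A planted zone
  `(chrom, left, right, k)` gives each of the first k TFs one peak exactly
  covering the interval while background peaks avoid it, so the true
  accumulation there is exactly k.

What these fixtures do **not** emulate: realistic mutation signatures,
biology-faithful peak shape or clustering along the genome, batch effects,
or any correlation between metadata and region content. Passing tests
demonstrate the correctness of the operator semantics and pipelines on data
of this shape, not biological conclusions about real cohorts.

## Numerical and degenerate-input choices

- Floats are serialized with Python's shortest round-tripping `str`, so
  write→read is exact; missing values are `"."` on disk and `None` in
  memory.
- Cover and accumulation use breakpoint sweeps / difference arrays, exact in
  integer arithmetic; no floating point enters until zone thresholding.
- Empty datasets are legal everywhere they can be: a 0-sample dataset, a
  0-region sample, `difference` against an empty right side (identity),
  `merge` of nothing (one empty sample). The length percentile and the
  accumulation of an empty region set raise, since no value exists to
  return.
- Problem sizes in tests and the acceptance script (≤ 4 samples × ≤ 100
  regions for oracle sweeps; 20 × 50 for the mutation miniature; 10 TFs × 30
  peaks for the zone miniature) were chosen so brute-force per-base and
  per-pair references stay exact and the whole suite runs in seconds.

## Known limitations

- Cover implements only the accumulation-bounds variant (no flat/summit/
  histogram outputs); difference has no exact-coordinate mode; UP/DOWN
  distances are not measured from annotated TSSs.
- The CLI pipeline format maps 1:1 onto the DAG but offers no expression
  over materialized intermediate reuse across separate runs (no on-disk
  cache by design).
- Interval lookup uses an interval tree per (sample, chromosome); the engine
  targets desk-scale data and makes no attempt at out-of-core or parallel
  execution.
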