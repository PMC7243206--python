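# Methods

## The integration procedure

`peakgene` quantifies the enrichment of differentially accessible (DA)
ATAC-seq peaks near differentially expressed (DE) genes. It deliberately does
*not* re-fit the upstream models: the inputs are the result tables of the two
differential analyses (genes with `de_log2FC`/`de_padj`, split into a DE set
and a non-DE "other" set by the upstream tests; peaks with
`da_log2FC`/`da_padj`). Everything downstream of those tables is in scope:

1. **Peak filter.** Peaks are kept when `da_padj < alpha` (strict inequality;
   missing `padj` never passes). Default `alpha = 0.01`.
2. **Resampled null.** The observed DE set is compared against R = 10
   subsamples drawn without replacement from the non-DE pool, each of size
   `|de_set|`. The DE set is coded `origin = de, resample = 0`; draw *r* is
   `origin = not_de, resample = r`. Replicating the subsample reduces the
   sampling variance of the null counts. The same non-DE gene may appear in
   several draws; normalization by `n_distinct(resample)` (below) keeps
   pooled counts on the scale of one draw.
3. **Promoter windows.** Each gene is anchored at its 5′ end and resized to
   width 1 (the TSS: `start` on `+` genes, `end` on `−` genes), then
   center-anchored and resized to `2F` (default F = 10 kb). The TSS therefore
   sits at offset F + 1 from the window start, i.e. a TSS at position p maps
   to the window [p − F, p + F − 1].
4. **Overlap join.** A left overlap join pairs every window with every peak
   sharing at least one base (closed-interval arithmetic, any strand);
   windows with no peak keep one row with missing peak columns. The join
   preserves all metadata from both sides, which is what makes the grouped
   summaries below one-liners.
5. **Summaries.** Two grouped aggregations are used, and they are not
   interchangeable:
   * per `(gene_id, origin)`: `peak_count = count_non_missing(da_padj) /
     n_distinct(resample)` and `peak_max_lfc = max |da_log2FC|` (missing
     exactly when the gene has no peak);
   * per `(gene_id, origin, resample)` then per `(origin, threshold)`: the
     threshold sweep, where per-gene exceedance counts at each grid point are
     expanded to long form and summarized as
     `gene_count = #(genes with count > 0) / n_distinct(resample)` and
     `peak_count = sum(count) / n_distinct(resample)`.
6. **Enrichment.** Per threshold, `enrichment = peak_count(de) /
   peak_count(not_de)`; the analogous gene-count ratio is emitted alongside.
   Ratios with a zero denominator are explicit missing values in the output
   files, never silently dropped.

The threshold grid is linear with 100 points from min to max |`da_log2FC`|
of the filtered peaks, endpoints included. Every threshold comparison in the
package is strict (`>`), so counts at the largest grid point are zero by
construction. Fixed reference thresholds {1, 2} are also reported
(`fixed_thresholds.tsv`); their peak counts are computed by the one-stage
origin-grouped route and their gene counts by the two-stage gene-then-origin
route — the peak counts of the two routes are algebraically equal, which a
unit test asserts.

## Interval semantics and numerical choices

* Coordinates are 1-based fully closed (`width = end − start + 1`). BED I/O
  converts to/from 0-based half-open at the boundary; GFF3 and TSV are
  1-based closed (TSV can declare `0-half-open`).
* Center anchoring uses `new_start = start + floor((old_width − new_width)/2)`
  with floor toward −∞ — the rule that maps a width-1 TSS at p to
  [p − 10000, p + 9999] at width 20000.
* Strand `*` anchors like `+` for 5′/3′ resizing.
* Overlap joins are strand-agnostic by default (ATAC peaks are unstranded);
  a `same_strand=True` mode exists but is off.
* Grouped reduction (`reduce_ranges_directed`) merges ranges within a group
  only when they share seqname *and* strand and overlap or are book-ended
  (gap 0). In this pipeline groups hold duplicated identical windows, so the
  merge is a collapse, but the general rule is implemented and tested.
* Missing-value policy: sums, counts and `max_abs` drop missing values;
  `max_abs` of an all-missing group is missing. `n_distinct` counts missing
  as a value if present (the pipeline never feeds it one).
* Name collisions in joins suffix the right side (`.y`); the left (gene)
  table is the analysis backbone.
* Windows that would extend below position 1 are an error by default;
  `clip=True` truncates to 1 with a warning (the clipped window is then
  narrower than 2F).
* Sampling uses `numpy.random.Generator.choice(..., replace=False)` from an
  integer seed. Reports are byte-stable for a fixed seed and inputs.

## The synthetic generator

`SimConfig`/`simulate_universe`/`simulate_peaks` emulate the two result
tables with planted structure on a toy genome:

* **Genome.** `n_chrom = 8` chromosomes of 1.25 Gb. This is deliberately
  sparse (~1 gene per 5 Mb at the default G = 2000): promoter windows of
  distinct genes then essentially never overlap, so each planted proximal
  peak is counted for exactly one gene and the closed-form oracle below is
  unbiased. Real genomes cluster genes far more densely; the generator does
  not emulate gene clustering, shared promoters, or correlated peak
  placement, so passing recovery tests demonstrate correctness of the
  *computation*, not robustness to those biological complications.
* **Genes.** G genes, strand by fair coin, TSS uniform per chromosome but
  kept `w + max peak width + max gene length` away from ends so nothing
  runs off a sequence. Exactly `round(pi_de * G)` genes are DE. DE genes get
  `|de_log2FC| = 1 + Exp(1)` with random sign (the upstream DE test requires
  |LFC| > 1); non-DE genes get `Normal(0, 0.2)`. Both sets draw
  `de_padj ~ U(0, 0.005)` — already below the 0.01 filter — mirroring
  pre-filtered upstream sets, so set sizes are exact while the filter code
  path still executes.
* **Peaks.** Per DE gene `Poisson(lambda_de)` peaks (default 3), per non-DE
  gene `Poisson(lambda_0)` (default 1), midpoints uniform on
  [TSS − w, TSS + w] with w = 10 kb matching the analysis flank; background
  peaks arrive at `rho_bg` per bp genome-wide (default 1e-7; 0 in recovery
  tests). Widths uniform on [200, 1000] bp; all unstranded;
  `da_padj ~ U(0, 0.005)`. |`da_log2FC`| is exponential with per-class mean
  (defaults: 1.0 near DE genes, 0.5 elsewhere — accessibility changes near
  responding genes tend to be larger) and random sign.
* **Oracle.** With exponential magnitudes the survival at threshold t is
  `exp(−t/scale)`, so the expected peak-count enrichment is
  `(lambda_de·S_de + 2w·rho_bg·S_bg) / (lambda_0·S_0 + 2w·rho_bg·S_bg)`.
  Peak class membership is defined by the *midpoint* falling within ±w, while
  the pipeline overlaps the full peak interval against the window; the small
  halo this creates affects both origins equally and is absorbed by the
  recovery tolerance — the price of keeping the oracle closed-form.

The recovery test runs the full pipeline on 20 seeds with
`lambda_de = 3, lambda_0 = 1, rho_bg = 0`, equal LFC scales, G = 2000,
pi_de = 0.25, R = 10 and checks that the mean enrichment at the smallest
grid threshold is within 3 Monte-Carlo standard errors of 3.0.

## Testing strategy and problem sizes

Randomized equivalence tests compare every stage against an independent
nested-loop brute-force recomputation (no interval index, plain dict
records): the overlap join on 100s of random intervals, interval merging
against a fix-point pairwise merger, and the full pipeline (gene summaries
and sweep) on 100 random instances of up to 50 genes and 200 peaks. pyranges
provides a second, external cross-check of the join on one instance.
Structural identities (universe rows = |de| + R·size; sweep rows =
2 × grid points; window width = 2F), monotonicity of counts along the grid,
and worked single-gene window coordinates are asserted exactly. Simulation
checks use sizes of a few hundred to a few thousand genes — large enough for
3-SE Monte-Carlo bands to be meaningful, small enough that the whole suite
runs in about a minute.

## Known limitations

* The resampling is subsampling without replacement (matching the upstream
  implementation), not a bootstrap; no variance or confidence band is
  computed for the enrichment curve (a natural extension — the per-resample
  counts are already available in the long table).
* A peak overlapping the windows of several genes is counted once per gene,
  following the upstream code; no deduplication across genes is attempted.
* Only canonical chromosome names (1–22, X, Y, MT) are restyled between
  Ensembl and UCSC conventions; scaffolds pass through with a warning.
* The DE/other split is consumed, not computed; genes belonging to neither
  upstream set are invisible to the analysis.
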