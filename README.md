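# peakgene

Are differentially accessible (DA) chromatin peaks enriched near
differentially expressed (DE) genes? `peakgene` answers that question for
paired ATAC-seq / RNA-seq experiments by integrating the *results* of the two
upstream differential analyses — it consumes a gene table
(`gene_id, de_log2FC, de_padj`, pre-split into a DE set and a non-DE "other"
set) and a peak table (`peak_id, da_log2FC, da_padj`) — and reports how the
enrichment of DA peaks near DE genes changes with the accessibility
fold-change threshold. It is aimed at analysts who have already run their
DESeq2/limma-style fits and want a reproducible, testable integration step.

## The statistic

Peaks are filtered at FDR α (default 0.01, strict `<`). A null gene universe
is built by drawing R = 10 subsamples, each the size of the DE set, without
replacement from the non-DE pool; draw *r* is tagged `resample = r` and the
DE set itself is `resample = 0`. Each gene is reduced to its transcription
start site (5′-anchored resize to width 1 — the start on `+` genes, the end
on `−` genes) and grown to a 2F = 20 kb window centered on the TSS. A left
overlap join pairs every window with every overlapping peak, keeping both
sides' metadata. For a threshold *t* and origin *o* ∈ {not_de, de},

    peak_count(o, t) = (# joined rows with |da_log2FC| > t) / n_distinct(resample)
    gene_count(o, t) = (# genes with at least one such peak) / n_distinct(resample)
    enrichment(t)    = peak_count(de, t) / peak_count(not_de, t)

Dividing by the number of distinct resamples makes the pooled null counts
comparable to the single observed DE set. The threshold grid is 100 points,
linear from min to max |da_log2FC|.

## Worked example

The package ships a synthetic-data generator with planted structure, so the
whole analysis runs without downloads. Here DE genes carry on average 3
proximal DA peaks and non-DE genes 1, so the true enrichment near threshold
0 is 3.0:

```python
import numpy as np
import peakgene as pg
from peakgene.pipeline import ResampleDesign, WindowSpec

cfg = pg.SimConfig(G=2000, pi_de=0.25, lambda_de=3.0, lambda_0=1.0,
                   rho_bg=0.0, lfc_scale_de=1.0, lfc_scale_0=1.0, seed=1)
rng = np.random.default_rng(cfg.seed)
universe, truth = pg.simulate_universe(cfg, rng)
peaks = pg.simulate_peaks(cfg, universe, truth, rng)

da = pg.filter_by_fdr(peaks, "da_padj", 0.01)
resampled = pg.build_resampled_universe(universe, ResampleDesign(seed=1))
windows = pg.tss_windows(resampled, WindowSpec(flank=10_000))
joined = pg.overlap_genes_peaks(windows, da)

print(pg.fixed_threshold_summary(joined).to_string(index=False))
```

```
origin  peak_count  lfc1_gene_count  lfc1_peak_count  lfc2_gene_count  lfc2_peak_count
not_de       492.8            154.2            191.1             64.5             72.7
    de      1429.0            331.0            531.0            179.0            211.0
```

Reading: the 500 DE genes have 1429 DA peaks within 10 kb of their TSSs,
while an equally sized null set averages 492.8 (fractional because it is a
mean over 10 resamples) — roughly the planted 3:1 ratio, which sharpens or
holds as the |LFC| cut rises. The full threshold sweep:

```python
grid = pg.make_threshold_grid(da, 100)
curve = pg.enrichment_ratios(pg.sweep_thresholds(joined, grid))
print(curve[["threshold", "peak_count_not_de", "peak_count_de",
             "enrichment"]].head(3).to_string(index=False))
```

```
 threshold  peak_count_not_de  peak_count_de  enrichment
  0.000007              492.8         1428.0    2.897727
  0.093778              454.0         1286.0    2.832599
  0.187550              421.5         1176.0    2.790036
```

The estimate at the smallest threshold (2.90) recovers the planted ratio
`pg.expected_enrichment(cfg, 0.0) == 3.0` up to Monte-Carlo noise.

The same analysis from the shell:

```
peakgene simulate --seed 1 --out-dir sim/
peakgene enrich --de sim/genes_de.tsv --other sim/genes_other.tsv \
    --peaks sim/peaks.tsv --out-dir report/ --seed 1 --summary
peakgene plot --report-dir report/
```

`enrich` writes `universe.tsv`, `windows.gff3`, `gene_peak_summary.tsv`,
`fixed_thresholds.tsv`, `enrichment_curve.tsv` and a `manifest.json`
(parameters, seed, input checksums) that suffices to reproduce the report
byte-for-byte.

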