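"""The DA-peak / DE-gene integration pipeline.

Given a DE gene set, a non-DE ("other") gene pool and an FDR-filtered set of
differentially accessible peaks, the analysis asks whether DA peaks are
enriched near DE genes:

1. build a null universe by drawing ``R`` subsamples (without replacement,
   each the size of the DE set) from the non-DE pool and binding them with
   the DE set (``origin`` in {not_de, de}; ``resample`` 0 for the DE set,
   1..R for the draws);
2. reduce each gene to its transcription start site (5'-anchored width 1)
   and grow a promoter window of ``2F`` bp centered on the TSS;
3. left-overlap-join the windows with the peaks, keeping peak metadata;
4. aggregate peak counts per gene and per origin, dividing pooled null
   counts by the number of distinct resamples so they are comparable to the
   single observed DE set;
5. sweep a linear grid of |log2FC| thresholds and report, per origin and
   threshold, the normalized number of peaks (and of genes with >= 1 peak)
   exceeding the threshold, plus the de / not_de enrichment ratio.

All threshold comparisons are strict (``>``), matching the upstream
convention; missing values never count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregate as agg
from .errors import RangeValidationError
from .ranges import (Anchor, RangeTable, anchored_set_width, bind_ranges,
                     expand_list_columns, join_overlap_left,
                     reduce_ranges_directed, slice_sample, summarize_groups)
from .results_io import GeneUniverse, PeakResults

__all__ = [
    "ResampleDesign",
    "WindowSpec",
    "ThresholdGrid",
    "ORIGIN_LEVELS",
    "build_resampled_universe",
    "tss_windows",
    "overlap_genes_peaks",
    "summarize_gene_peaks",
    "fixed_threshold_summary",
    "make_threshold_grid",
    "count_if_above_threshold",
    "sweep_thresholds",
    "enrichment_ratios",
    "stat_enrichment",
]

ORIGIN_LEVELS = ("not_de", "de")


@dataclass(frozen=True)
class ResampleDesign:
    """How to subsample the non-DE pool: R draws of ``size`` genes each."""

    n_resamples: int = 10
    size: int | None = None  # None -> |de_set|
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 0:
            raise ValueError("n_resamples must be >= 0")


@dataclass(frozen=True)
class WindowSpec:
    """Promoter window: ``flank`` bp on either side of the TSS (total 2F)."""

    flank: int = 10_000

    def __post_init__(self):
        if self.flank < 1:
            raise ValueError("flank must be >= 1")

    @property
    def total_width(self) -> int:
        return 2 * self.flank


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing |log2FC| thresholds."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) < 2 or not (np.diff(v) > 0).all():
            raise ValueError("threshold grid must be strictly increasing "
                             "with at least 2 points")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def n_points(self) -> int:
        return len(self.values)


def _origin_categorical(values) -> pd.Categorical:
    return pd.Categorical(values, categories=list(ORIGIN_LEVELS), ordered=True)


def build_resampled_universe(universe: GeneUniverse,
                             design: ResampleDesign) -> RangeTable:
    """DE set plus R independent without-replacement draws from the non-DE pool.

    The result has ``|de_set| + R * size`` rows; ``origin`` is a categorical
    with level order (not_de, de) and ``resample`` is 0 for the DE set and
    1..R for the draws. The same non-DE gene may recur across draws — the
    downstream ``n_distinct(resample)`` normalization accounts for that.
    """
    de, other = universe.de_set, universe.other_set
    size = design.size if design.size is not None else len(de)
    if size > len(other):
        raise ValueError(
            f"resample size {size} exceeds non-DE pool of {len(other)}")
    rng = np.random.default_rng(design.seed)
    draws = {str(i): slice_sample(other, size, rng)
             for i in range(1, design.n_resamples + 1)}
    if draws:
        boot = bind_ranges(draws, id_column="resample")
    else:
        empty = other.df.iloc[:0].copy()
        empty["resample"] = pd.Series([], dtype=object)
        boot = RangeTable(empty, genome=other.genome, validate=False)
    out = bind_ranges({"de": RangeTable(de.df, genome=de.genome, validate=False),
                       "not_de": boot}, id_column="origin")
    df = out.df
    df["resample"] = (pd.to_numeric(df["resample"], errors="coerce")
                      .fillna(0).astype(np.int64))
    df["origin"] = _origin_categorical(df["origin"])
    return RangeTable(df, genome=out.genome, validate=False)


def tss_windows(genes: RangeTable, spec: WindowSpec = WindowSpec(),
                clip: bool = False) -> RangeTable:
    """Promoter windows: 5'-anchor each gene to width 1 (the TSS), then grow
    to total width 2F around the center.

    The TSS sits at offset ``F + 1`` from the window start (1-based). Windows
    that would extend below position 1 raise; with ``clip=True`` they are
    truncated to start at 1 with a warning (their width is then < 2F).
    """
    tss = anchored_set_width(genes, Anchor.FIVE_PRIME, 1)
    try:
        return anchored_set_width(tss, Anchor.CENTER, spec.total_width)
    except RangeValidationError:
        if not clip:
            raise
    df = tss.df.copy()
    s = df["start"].to_numpy()
    new_start = s - spec.flank
    clipped = new_start < 1
    warnings.warn(f"clipping {int(clipped.sum())} window(s) at the "
                  "chromosome start", stacklevel=2)
    df["start"] = np.maximum(new_start, 1)
    df["end"] = s + spec.flank - 1
    return genes._replace(df)


def overlap_genes_peaks(windows: RangeTable,
                        da_peaks: PeakResults) -> RangeTable:
    """Left overlap join of gene windows with (already FDR-filtered) DA peaks.

    One row per (window, overlapping peak); windows without any peak keep a
    single row with missing peak columns.
    """
    return join_overlap_left(windows, da_peaks)


def summarize_gene_peaks(joined: RangeTable) -> RangeTable:
    """Per (gene_id, origin): resample-normalized peak count and max |LFC|.

    ``peak_count = (# rows with non-missing da_padj) / (# distinct resample
    values in the group)``; ``peak_max_lfc`` is missing exactly when the gene
    has no overlapping peak.
    """
    return reduce_ranges_directed(
        joined,
        group_keys=("gene_id", "origin"),
        aggregators={
            "peak_count": agg.Ratio(agg.count_non_missing("da_padj"),
                                    agg.n_distinct("resample")),
            "peak_max_lfc": agg.max_abs("da_log2FC"),
        },
    )


def _lfc_name(t: float) -> str:
    return f"lfc{t:g}"


def fixed_threshold_summary(joined: RangeTable,
                            thresholds=(1.0, 2.0)) -> pd.DataFrame:
    """Per-origin normalized peak and gene counts at fixed |LFC| thresholds.

    Peak counts come from a one-stage origin-grouped aggregation; gene counts
    require the two-stage route (count per gene/origin/resample first, then
    count genes with a positive count per origin). The two routes give
    identical peak counts; both are computed faithfully.
    """
    thresholds = [float(t) for t in thresholds]
    if any(t <= 0 for t in thresholds):
        raise ValueError("fixed thresholds must be positive")

    one_stage_aggs = {
        "peak_count": agg.Ratio(agg.count_non_missing("da_padj"),
                                agg.n_distinct("resample")),
    }
    for t in thresholds:
        one_stage_aggs[f"{_lfc_name(t)}_peak_count"] = agg.Ratio(
            agg.count_above("da_log2FC", t), agg.n_distinct("resample"))
    one = summarize_groups(joined, keys=("origin",), aggregators=one_stage_aggs)

    per_gene = reduce_ranges_directed(
        joined,
        group_keys=("gene_id", "origin", "resample"),
        aggregators={_lfc_name(t): agg.count_above("da_log2FC", t)
                     for t in thresholds},
    )
    two_stage_aggs = {}
    for t in thresholds:
        name = _lfc_name(t)
        two_stage_aggs[f"{name}_gene_count"] = agg.Ratio(
            agg.count_above(name, 0), agg.n_distinct("resample"))
    two = summarize_groups(per_gene.df, keys=("origin",),
                           aggregators=two_stage_aggs)

    out = one.merge(two, on="origin")
    out["origin"] = _origin_categorical(out["origin"].astype(str))
    out = out.sort_values("origin", kind="mergesort").reset_index(drop=True)
    cols = ["origin", "peak_count"]
    for t in thresholds:
        cols += [f"{_lfc_name(t)}_gene_count", f"{_lfc_name(t)}_peak_count"]
    return out[cols]


def make_threshold_grid(da_peaks: PeakResults,
                        n_points: int = 100) -> ThresholdGrid:
    """Linear grid from min to max |da_log2FC| inclusive of both endpoints."""
    if len(da_peaks) == 0:
        raise ValueError("cannot build a threshold grid from an empty peak set")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    a = np.abs(pd.to_numeric(da_peaks.df["da_log2FC"]).to_numpy())
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("no non-missing da_log2FC values")
    return ThresholdGrid(tuple(np.linspace(a.min(), a.max(), n_points)))


def count_if_above_threshold(values, grid) -> list[int]:
    """For each grid point t: how many |value| are strictly above t
    (missing values dropped)."""
    t = grid.values if isinstance(grid, ThresholdGrid) else grid
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"),
                   dtype=float)
    a = np.sort(np.abs(v[~np.isnan(v)]))
    counts = a.size - np.searchsorted(a, np.asarray(t, dtype=float),
                                      side="right")
    return [int(c) for c in counts]


def sweep_thresholds(joined: RangeTable, grid: ThresholdGrid) -> pd.DataFrame:
    """Two-stage threshold sweep: per-gene exceedance counts, then per-origin
    normalized gene and peak counts at every grid point.

    Output is long: one row per (origin, threshold), origins in level order
    then thresholds ascending — ``2 * n_points`` rows when both origins are
    present.
    """
    thresholds = list(grid.values)
    reduced = reduce_ranges_directed(
        joined,
        group_keys=("gene_id", "origin", "resample"),
        aggregators={
            "value": agg.count_above("da_log2FC", thresholds),
            "threshold": agg.constant_list(thresholds),
        },
    )
    expanded = expand_list_columns(reduced, ["value", "threshold"])
    long = summarize_groups(
        expanded.df,
        keys=("origin", "threshold"),
        aggregators={
            # value >= 0, so counting |value| > 0 counts genes with any peak
            "gene_count": agg.Ratio(agg.count_above("value", 0),
                                    agg.n_distinct("resample")),
            "peak_count": agg.Ratio(agg.sum_("value"),
                                    agg.n_distinct("resample")),
        },
    )
    long["origin"] = _origin_categorical(long["origin"].astype(str))
    long = long.sort_values(["origin", "threshold"],
                            kind="mergesort").reset_index(drop=True)
    return long


def enrichment_ratios(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the sweep to wide form and derive per-threshold enrichment.

    ``enrichment = peak_count[de] / peak_count[not_de]`` (the headline
    statistic); ``gene_enrichment`` is the analogous gene-count ratio,
    emitted alongside. Ratios with a zero denominator are explicit missing
    values, never dropped.
    """
    for origin in ORIGIN_LEVELS:
        if origin not in set(long["origin"].astype(str)):
            raise ValueError(f"origin level {origin!r} absent from the sweep")
    wide = long.pivot_table(index="threshold", columns="origin",
                            values=["gene_count", "peak_count"],
                            aggfunc="first", observed=True)
    out = pd.DataFrame({"threshold": wide.index.to_numpy()})
    for stat in ("gene_count", "peak_count"):
        for origin in ORIGIN_LEVELS:
            out[f"{stat}_{origin}"] = wide[(stat, origin)].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        gene_ratio = out["gene_count_de"] / out["gene_count_not_de"]
        peak_ratio = out["peak_count_de"] / out["peak_count_not_de"]
    out["gene_enrichment"] = gene_ratio.where(out["gene_count_not_de"] > 0)
    out["enrichment"] = peak_ratio.where(out["peak_count_not_de"] > 0)
    return out


def stat_enrichment(origin_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a per-origin summary (one row per origin, numeric statistic
    columns) into (name, not_de, de, enrichment = de / not_de) rows."""
    df = origin_table.copy()
    df["origin"] = df["origin"].astype(str)
    stats = [c for c in df.columns if c != "origin"]
    rows = []
    by_origin = df.set_index("origin")
    for name in stats:
        not_de = float(by_origin.loc["not_de", name])
        de = float(by_origin.loc["de", name])
        rows.append({
            "name": name,
            "not_de": not_de,
            "de": de,
            "enrichment": de / not_de if not_de != 0 else np.nan,
        })
    return pd.DataFrame(rows)
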