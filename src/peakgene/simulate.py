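"""Synthetic gene and peak result tables with planted enrichment structure.

The generator emulates the two upstream result tables the pipeline consumes —
stranded genes (a DE set and a non-DE "other" set) on a toy genome, and
unstranded peaks — with a known, analytically tractable truth:

* each DE gene carries ``Poisson(lambda_de)`` proximal peaks, each non-DE
  gene ``Poisson(lambda_0)``, with peak *midpoints* uniform within ``w`` bp
  of the TSS;
* background peaks arrive at ``rho_bg`` per bp genome-wide;
* peak |log2FC| magnitudes are exponential with a per-class mean, so the
  survival at threshold t is ``exp(-t / scale)`` and the expected enrichment
  curve has a closed form (:func:`expected_enrichment`).

The toy genome is deliberately sparse (~1 gene per 5 Mb at the default
G = 2000) so promoter windows of distinct genes essentially never overlap and
the closed form stays unbiased; real genomes cluster genes far more densely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import RangeValidationError
from .ranges import GenomeInfo, RangeTable
from .results_io import GeneResults, GeneUniverse, PeakResults

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_universe",
    "simulate_peaks",
    "expected_enrichment",
]

PEAK_CLASSES = ("de_proximal", "notde_proximal", "background")


@dataclass(frozen=True)
class SimConfig:
    """Planted parameters for the synthetic study.

    Rates are per-gene means (``lambda_de``, ``lambda_0``) or per-bp
    (``rho_bg``); ``w`` must match the analysis window flank for the
    closed-form oracle to apply.
    """

    n_chrom: int = 8
    chrom_length: int = 1_250_000_000
    G: int = 2000
    pi_de: float = 0.25
    gene_length_range: tuple[int, int] = (1_000, 100_000)
    w: int = 10_000
    lambda_de: float = 3.0
    lambda_0: float = 1.0
    rho_bg: float = 1e-7
    lfc_scale_de: float = 1.0
    lfc_scale_0: float = 0.5
    lfc_scale_bg: float = 0.5
    peak_width_range: tuple[int, int] = (200, 1_000)
    seed: int = 0
    genome_label: str = "toy1"

    def __post_init__(self):
        if not 0 < self.pi_de < 1:
            raise ValueError("pi_de must be in (0, 1)")
        if min(self.lambda_de, self.lambda_0, self.rho_bg) < 0:
            raise ValueError("rates must be >= 0")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        margin = self.w + self.peak_width_range[1] + self.gene_length_range[1]
        if 2 * margin >= self.chrom_length:
            raise ValueError("chromosomes too short for the requested margins")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chrom + 1)]

    @property
    def genome(self) -> GenomeInfo:
        return GenomeInfo(self.genome_label,
                          {c: self.chrom_length for c in self.chrom_names})

    @property
    def total_length(self) -> int:
        return self.n_chrom * self.chrom_length


@dataclass
class SimTruth:
    """Planted per-gene/per-peak assignments plus the analytic oracle config."""

    genes: pd.DataFrame   # gene_id, seqname, tss, strand, is_de
    peaks: pd.DataFrame   # peak_id, peak_class
    config: SimConfig

    def expected_enrichment(self, threshold: float) -> float:
        return expected_enrichment(self.config, threshold)


def simulate_universe(config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[GeneUniverse, SimTruth]:
    """Place G stranded genes on the toy genome and split them into an exact
    DE fraction and a non-DE pool.

    Both sets draw ``padj`` already below the 0.01 filter (uniform on
    (0, 0.005)), mirroring pre-filtered upstream sets, so downstream set
    sizes are exact while the FDR filter code path still runs. DE genes get
    ``|de_log2FC| = 1 + Exp(1)`` with a random sign; non-DE genes get
    ``Normal(0, 0.2)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G = config.G
    n_de = int(round(config.pi_de * G))

    # keep TSSs away from chromosome ends so windows, peaks and gene bodies
    # never run off the sequence
    margin = config.w + config.peak_width_range[1] + config.gene_length_range[1]
    lo, hi = 1 + margin, config.chrom_length - margin
    if hi <= lo:
        raise RangeValidationError("infeasible gene placement")

    chrom = rng.integers(0, config.n_chrom, size=G)
    tss = rng.integers(lo, hi + 1, size=G)
    strand = np.where(rng.random(G) < 0.5, "+", "-")
    length = rng.integers(config.gene_length_range[0],
                          config.gene_length_range[1] + 1, size=G)
    start = np.where(strand == "+", tss, tss - length + 1)
    end = np.where(strand == "+", tss + length - 1, tss)

    is_de = np.zeros(G, dtype=bool)
    is_de[rng.permutation(G)[:n_de]] = True

    lfc = np.empty(G)
    sign = np.where(rng.random(G) < 0.5, 1.0, -1.0)
    lfc[is_de] = sign[is_de] * (1.0 + rng.exponential(1.0, size=is_de.sum()))
    lfc[~is_de] = rng.normal(0.0, 0.2, size=(~is_de).sum())
    padj = rng.uniform(0.0, 0.005, size=G)

    names = np.array(config.chrom_names)
    df = pd.DataFrame({
        "seqname": names[chrom],
        "start": start,
        "end": end,
        "strand": strand,
        "gene_id": [f"SIMG{i + 1:06d}" for i in range(G)],
        "de_log2FC": lfc,
        "de_padj": padj,
    })
    de_df = df.loc[is_de].reset_index(drop=True)
    other_df = df.loc[~is_de].reset_index(drop=True)
    universe = GeneUniverse(
        de_set=GeneResults(de_df, genome=config.genome),
        other_set=GeneResults(other_df, genome=config.genome),
    )
    truth_genes = pd.DataFrame({
        "gene_id": df["gene_id"],
        "seqname": df["seqname"],
        "tss": tss,
        "strand": strand,
        "is_de": is_de,
    })
    truth = SimTruth(genes=truth_genes, peaks=pd.DataFrame(
        columns=["peak_id", "peak_class"]), config=config)
    return universe, truth


def simulate_peaks(config: SimConfig, universe: GeneUniverse, truth: SimTruth,
                   rng: np.random.Generator | None = None) -> PeakResults:
    """Plant unstranded DA peaks near DE and non-DE TSSs plus a uniform
    background, with class-specific |log2FC| distributions.

    Peak counts per gene are Poisson; proximal peak midpoints are uniform on
    ``[TSS - w, TSS + w]``. ``truth.peaks`` is filled in with each peak's
    planted class.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    g = truth.genes
    records = []

    def _plant_proximal(sub: pd.DataFrame, lam: float, scale: float,
                        klass: str) -> None:
        if lam == 0 or len(sub) == 0:
            return
        counts = rng.poisson(lam, size=len(sub))
        total = int(counts.sum())
        if total == 0:
            return
        tss_rep = np.repeat(sub["tss"].to_numpy(), counts)
        seq_rep = np.repeat(sub["seqname"].to_numpy(), counts)
        mids = rng.integers(tss_rep - config.w, tss_rep + config.w + 1)
        records.append(_peak_frame(seq_rep, mids, total, scale, klass, rng,
                                   config))

    _plant_proximal(g.loc[g["is_de"]], config.lambda_de,
                    config.lfc_scale_de, "de_proximal")
    _plant_proximal(g.loc[~g["is_de"]], config.lambda_0,
                    config.lfc_scale_0, "notde_proximal")

    n_bg = rng.poisson(config.rho_bg * config.total_length)
    if n_bg > 0:
        seq = np.asarray(config.chrom_names)[
            rng.integers(0, config.n_chrom, size=n_bg)]
        half = config.peak_width_range[1]
        mids = rng.integers(1 + half, config.chrom_length - half, size=n_bg)
        records.append(_peak_frame(seq, mids, n_bg, config.lfc_scale_bg,
                                   "background", rng, config))

    if records:
        peaks = pd.concat(records, ignore_index=True)
    else:
        peaks = pd.DataFrame(columns=["seqname", "start", "end", "strand",
                                      "da_log2FC", "da_padj", "peak_class"])
    peaks["peak_id"] = [f"SIMP{i + 1:06d}" for i in range(len(peaks))]
    truth.peaks = peaks[["peak_id", "peak_class"]].copy()
    cols = ["seqname", "start", "end", "strand", "peak_id",
            "da_log2FC", "da_padj"]
    return PeakResults(peaks[cols], genome=config.genome)


def _peak_frame(seqnames, mids, n, scale, klass, rng, config) -> pd.DataFrame:
    widths = rng.integers(config.peak_width_range[0],
                          config.peak_width_range[1] + 1, size=n)
    start = mids - widths // 2
    end = start + widths - 1
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lfc = sign * rng.exponential(scale, size=n)
    return pd.DataFrame({
        "seqname": seqnames,
        "start": start,
        "end": end,
        "strand": "*",
        "da_log2FC": lfc,
        "da_padj": rng.uniform(0.0, 0.005, size=n),
        "peak_class": klass,
    })


def expected_enrichment(config: SimConfig, threshold: float) -> float:
    """Closed-form expected peak-count enrichment at an |LFC| threshold.

    With exponential |LFC| magnitudes the per-class survival is
    ``S_c(t) = exp(-t / scale_c)``, so

        enrichment(t) = (lambda_de * S_de + 2w * rho_bg * S_bg)
                      / (lambda_0  * S_0  + 2w * rho_bg * S_bg)

    NaN when the denominator is zero.
    """
    s_de = np.exp(-threshold / config.lfc_scale_de)
    s_0 = np.exp(-threshold / config.lfc_scale_0)
    s_bg = np.exp(-threshold / config.lfc_scale_bg)
    bg = 2 * config.w * config.rho_bg * s_bg
    den = config.lambda_0 * s_0 + bg
    if den == 0:
        return float("nan")
    return (config.lambda_de * s_de + bg) / den
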