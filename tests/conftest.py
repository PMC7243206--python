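import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import peakgene as pg

settings.register_profile(
    "det", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20190802)


def make_gene_frame(rng, n, chrom_length=20_000, flank=60, id_prefix="G",
                    seqnames=("chr1", "chr2")):
    """Small random stranded gene table whose TSS windows never underflow."""
    lo = flank + 2
    hi = chrom_length - flank - 2
    tss = rng.integers(lo, hi, size=n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    length = rng.integers(5, 200, size=n)
    start = np.where(strand == "+", tss, np.maximum(tss - length + 1, 1))
    end = np.where(strand == "+", tss + length - 1, tss)
    return pd.DataFrame({
        "seqname": rng.choice(seqnames, size=n),
        "start": start,
        "end": end,
        "strand": strand,
        "gene_id": [f"{id_prefix}{i}" for i in range(n)],
        "de_log2FC": rng.normal(0, 2, size=n),
        "de_padj": rng.uniform(0, 0.009, size=n),
    })


def make_peak_frame(rng, n, chrom_length=20_000, seqnames=("chr1", "chr2"),
                    na_frac=0.1):
    start = rng.integers(1, chrom_length - 300, size=n)
    width = rng.integers(1, 300, size=n)
    lfc = rng.normal(0, 1.5, size=n)
    padj = rng.uniform(0, 0.05, size=n)
    padj[rng.random(n) < na_frac] = np.nan
    return pd.DataFrame({
        "seqname": rng.choice(seqnames, size=n),
        "start": start,
        "end": start + width - 1,
        "strand": "*",
        "peak_id": [f"P{i}" for i in range(n)],
        "da_log2FC": lfc,
        "da_padj": padj,
    })


def make_instance(rng, n_genes, n_peaks, n_resamples=3, flank=60):
    """Random small analysis instance: universe, peaks and a resampled null."""
    genes = make_gene_frame(rng, n_genes, flank=flank)
    n_de = max(1, n_genes // 3)
    de = pg.GeneResults(genes.iloc[:n_de])
    other = pg.GeneResults(genes.iloc[n_de:])
    universe = pg.GeneUniverse(de_set=de, other_set=other)
    peaks = pg.PeakResults(make_peak_frame(rng, n_peaks))
    design = pg.ResampleDesign(n_resamples=n_resamples,
                               size=min(n_de, len(other)),
                               seed=int(rng.integers(2**31)))
    return universe, peaks, design


@pytest.fixture
def small_instance(rng):
    return make_instance(rng, 20, 60)


@pytest.fixture
def paper_gene_table():
    """The four genes whose TSS windows are printed end to end."""
    return pg.validate_ranges(pd.DataFrame({
        "seqname": ["chr1", "chr6", "chr17", "chr20"],
        "start": [196651878, 46129993, 43527844, 63895182],
        "end": [196747504, 46146699, 43579620, 63936031],
        "strand": ["+", "+", "-", "+"],
        "gene_id": ["ENSG00000000971.15", "ENSG00000001561.6",
                    "ENSG00000175832.12", "ENSG00000101152.10"],
    }))
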