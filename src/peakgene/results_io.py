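"""Read, validate, filter and write DE-gene and DA-peak result tables.

The pipeline consumes the *outputs* of upstream differential tests: a gene
table carrying ``gene_id, de_log2FC, de_padj`` (pre-split into a DE set and a
non-DE "other" set) and a peak table carrying ``peak_id, da_log2FC, da_padj``.
Three on-disk formats are supported:

* TSV with named columns, 1-based closed coordinates by default
  (``coord_convention="0-half-open"`` shifts on read);
* BED6+3 — 0-based half-open, converted at the boundary; the ``name`` field
  is the id and the two fields after ``strand`` hold log2FC and padj;
* GFF3 — 1-based closed; ids and statistics travel in the attribute column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import gffutils

from .errors import FormatError, RangeValidationError
from .ranges import COORD_COLS, GenomeInfo, RangeTable, _as_genome

__all__ = [
    "GeneResults",
    "PeakResults",
    "GeneUniverse",
    "read_results",
    "write_results",
    "filter_by_fdr",
]

_KIND_COLUMNS = {
    "genes": ("gene_id", "de_log2FC", "de_padj"),
    "peaks": ("peak_id", "da_log2FC", "da_padj"),
}


class GeneResults(RangeTable):
    """Gene-level differential-expression results on genomic ranges."""

    id_column, lfc_column, padj_column = _KIND_COLUMNS["genes"]

    def _validate(self) -> None:
        super()._validate()
        _check_results_columns(self)
        if not set(self.df["strand"].unique()) <= {"+", "-"}:
            raise RangeValidationError("genes must be stranded (+ or -)")


class PeakResults(RangeTable):
    """Peak-level differential-accessibility results; typically unstranded."""

    id_column, lfc_column, padj_column = _KIND_COLUMNS["peaks"]

    def _validate(self) -> None:
        super()._validate()
        _check_results_columns(self)


def _check_results_columns(t) -> None:
    df = t.df
    for col in (t.id_column, t.lfc_column, t.padj_column):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    ids = df[t.id_column]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise RangeValidationError(f"duplicate {t.id_column}: {dup!r}")
    padj = pd.to_numeric(df[t.padj_column], errors="coerce")
    ok = padj.isna() | ((padj >= 0) & (padj <= 1))
    if not ok.all():
        raise RangeValidationError(f"{t.padj_column} outside [0, 1]")


@dataclass
class GeneUniverse:
    """The two pre-split gene sets: DE and the non-DE ("other") null pool."""

    de_set: GeneResults
    other_set: GeneResults

    def __post_init__(self):
        de_ids = set(self.de_set.df["gene_id"])
        other_ids = set(self.other_set.df["gene_id"])
        common = de_ids & other_ids
        if common:
            raise RangeValidationError(
                f"gene_id sets of de_set and other_set overlap: "
                f"{sorted(common)[:5]}...")
        lde = self.de_set.genome.label if self.de_set.genome else None
        lot = self.other_set.genome.label if self.other_set.genome else None
        if lde != lot:
            raise RangeValidationError(
                f"de_set and other_set genomes differ: {lde!r} vs {lot!r}")


def _kind_class(kind: str):
    if kind == "genes":
        return GeneResults
    if kind == "peaks":
        return PeakResults
    raise ValueError(f"kind must be 'genes' or 'peaks', got {kind!r}")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tsv", ".txt"):
        return "tsv"
    if ext == ".bed":
        return "bed"
    if ext in (".gff", ".gff3"):
        return "gff3"
    raise FormatError(f"cannot infer format from extension {ext!r}")


def read_results(path, kind: str, format: str | None = None,
                 coord_convention: str = "1-closed",
                 column_map: Mapping[str, str] | None = None,
                 genome=None):
    """Read a gene or peak result table into a validated typed range table.

    ``column_map`` maps canonical names (``seqname``, ``start``, ..., and the
    kind's id/log2FC/padj columns) to the names used in the file, e.g.
    ``{"de_log2FC": "log2FoldChange"}``. BED input is always treated as
    0-based half-open regardless of ``coord_convention``.
    """
    cls = _kind_class(kind)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        df = _read_tsv(path, column_map)
        if coord_convention == "0-half-open":
            df["start"] = pd.to_numeric(df["start"]) + 1
        elif coord_convention != "1-closed":
            raise ValueError(f"unknown coordinate convention {coord_convention!r}")
    elif fmt == "bed":
        df = _read_bed(path, cls)
    elif fmt == "gff3":
        df, file_genome = _read_gff3(path, cls)
        genome = genome if genome is not None else file_genome
    else:
        raise FormatError(f"unsupported format {fmt!r}")
    return cls(df, genome=_as_genome(genome))


def _read_tsv(path, column_map=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [s for s in rename if s not in df.columns]
        if missing:
            raise FormatError(f"column_map names absent from file: {missing}")
        df = df.rename(columns=rename)
    for c in ("seqname", "start", "end"):
        if c not in df.columns:
            raise FormatError(f"missing required column {c!r}")
    return df


def _read_bed(path, cls) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    if df.shape[1] < 6:
        raise FormatError("BED input needs at least 6 fields "
                          "(chrom start end name score strand)")
    out = pd.DataFrame({
        "seqname": df[0],
        "start": pd.to_numeric(df[1]) + 1,  # 0-based half-open -> 1-based closed
        "end": pd.to_numeric(df[2]),
        "strand": df[5].replace(".", "*"),
        cls.id_column: df[3],
    })
    out[cls.lfc_column] = pd.to_numeric(df[6], errors="coerce") \
        if df.shape[1] > 6 else np.nan
    out[cls.padj_column] = pd.to_numeric(df[7], errors="coerce") \
        if df.shape[1] > 7 else np.nan
    return out


_GFF_GENOME_PRAGMA = "##genome-build"


def _read_gff3(path, cls):
    rows = []
    genome = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(_GFF_GENOME_PRAGMA):
                genome = line.split()[-1]
                continue
            if line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line)
            attrs = {k: v[0] for k, v in feat.attributes.items()}
            row = {
                "seqname": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": "*" if feat.strand in (".", "?") else feat.strand,
                cls.id_column: attrs.get("ID"),
            }
            for col in (cls.lfc_column, cls.padj_column):
                row[col] = float(attrs[col]) if col in attrs else np.nan
            rows.append(row)
    cols = ["seqname", "start", "end", "strand",
            cls.id_column, cls.lfc_column, cls.padj_column]
    df = pd.DataFrame(rows, columns=cols)
    return df, genome


def filter_by_fdr(t, padj_column: str, alpha: float):
    """Keep rows with adjusted p strictly below ``alpha``; missing padj drops.

    Idempotent and order-preserving; returns the same table type.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    padj = pd.to_numeric(t.df[padj_column], errors="coerce")
    keep = padj.notna() & (padj < alpha)
    return t._replace(t.df.loc[keep].reset_index(drop=True))


def write_results(t, path, format: str | None = None) -> None:
    """Write a range table; TSV and GFF3 round-trip exactly, BED through the
    +/-1 coordinate shift."""
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        _write_tsv(t, path)
    elif fmt == "bed":
        _write_bed(t, path)
    elif fmt == "gff3":
        _write_gff3(t, path)
    else:
        raise FormatError(f"unsupported format {fmt!r}")


def write_table(df: pd.DataFrame, path) -> None:
    """Plain deterministic TSV writer for coordinate-free report tables."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _write_tsv(t, path) -> None:
    t.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _write_bed(t, path) -> None:
    df = t.df
    id_col = getattr(t, "id_column", None)
    lfc_col = getattr(t, "lfc_column", None)
    padj_col = getattr(t, "padj_column", None)
    out = pd.DataFrame({
        "chrom": df["seqname"],
        "chromStart": df["start"] - 1,
        "chromEnd": df["end"],
        "name": df[id_col] if id_col in df.columns else ".",
        "score": 0,
        "strand": df["strand"].replace("*", "."),
    })
    if lfc_col in df.columns:
        out["lfc"] = df[lfc_col]
    if padj_col in df.columns:
        out["padj"] = df[padj_col]
    out.to_csv(path, sep="\t", index=False, header=False, na_rep="NA")


def _write_gff3(t, path) -> None:
    id_col = getattr(t, "id_column", "id")
    lfc_col = getattr(t, "lfc_column", None)
    padj_col = getattr(t, "padj_column", None)
    feature_type = "gene" if isinstance(t, GeneResults) else "region"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if t.genome is not None:
            fh.write(f"{_GFF_GENOME_PRAGMA} . {t.genome.label}\n")
        for _, row in t.df.iterrows():
            attrs = []
            if id_col in t.df.columns:
                attrs.append(f"ID={row[id_col]}")
            for col in (lfc_col, padj_col):
                if col in t.df.columns and pd.notna(row[col]):
                    # repr of a Python float is its shortest exact form
                    attrs.append(f"{col}={float(row[col])!r}")
            feat = gffutils.Feature(
                seqid=row["seqname"], source="peakgene",
                featuretype=feature_type,
                start=int(row["start"]), end=int(row["end"]),
                score=".", strand="." if row["strand"] == "*" else row["strand"],
                frame=".", attributes=";".join(attrs))
            fh.write(str(feat) + "\n")
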