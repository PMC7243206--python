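"""Genomic-interval data model and the verb set the pipeline composes.

Coordinates are 1-based and fully closed throughout: a range ``[start, end]``
has ``width = end - start + 1`` and a single base is ``[p, p]``. BED input and
output converts at the boundary (see :mod:`peakgene.results_io`). Strand is
one of ``+``, ``-``, ``*`` (unstranded). Every table may carry a genome label
(e.g. ``hg38``) and operations that combine two tables refuse to mix labels —
cheap book-keeping that prevents comparing coordinates across incompatible
reference builds.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import aggregate as agg
from .errors import AggregatorError, GenomeMismatchError, RangeValidationError

__all__ = [
    "GenomeInfo",
    "Anchor",
    "RangeTable",
    "validate_ranges",
    "with_genome",
    "restyle_seqnames",
    "anchored_set_width",
    "bind_ranges",
    "join_overlap_left",
    "reduce_ranges_directed",
    "expand_list_columns",
    "summarize_groups",
    "slice_sample",
]

COORD_COLS = ("seqname", "start", "end", "strand")
STRANDS = frozenset({"+", "-", "*"})


@dataclass(frozen=True)
class GenomeInfo:
    """Reference-build tag, optionally with per-sequence lengths."""

    label: str
    lengths: Mapping[str, int] | None = None

    def __post_init__(self):
        if not self.label:
            raise RangeValidationError("genome label must be non-empty")
        if self.lengths is not None:
            for name, n in self.lengths.items():
                if n < 1:
                    raise RangeValidationError(
                        f"sequence length for {name!r} must be positive, got {n}"
                    )


class Anchor(str, enum.Enum):
    """Which point of a range stays fixed when its width changes.

    ``five_prime``/``three_prime`` resolve through the strand (``*`` is
    treated as ``+``); ``center`` keeps the midpoint, rounding the new start
    down when the width change is odd.
    """

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    CENTER = "center"
    FIX_START = "fix_start"
    FIX_END = "fix_end"


class RangeTable:
    """Stranded 1-based closed genomic intervals with metadata columns.

    Thin immutable-by-convention wrapper around a :class:`pandas.DataFrame`
    whose first four columns are ``seqname, start, end, strand``; every other
    column is metadata and travels untouched through the interval verbs.
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeInfo | None = None,
                 validate: bool = True):
        self._df = _normalize_frame(df)
        self.genome = genome
        if validate:
            self._validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def width(self) -> pd.Series:
        return self._df["end"] - self._df["start"] + 1

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self._df.columns if c not in COORD_COLS]

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        g = self.genome.label if self.genome else "unset"
        return (f"<RangeTable: {len(self)} ranges, "
                f"{len(self.metadata_columns)} metadata columns, genome {g}>")

    def equals(self, other: "RangeTable") -> bool:
        if _label(self) != _label(other):
            return False
        return self._df.reset_index(drop=True).equals(
            other._df.reset_index(drop=True))

    def _replace(self, df: pd.DataFrame, genome: GenomeInfo | None = None,
                 validate: bool = False) -> "RangeTable":
        out = self.__class__.__new__(self.__class__)
        RangeTable.__init__(out, df, genome if genome is not None else self.genome,
                            validate=validate)
        return out

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        df = self._df
        if (df["start"] < 1).any():
            bad = df.loc[df["start"] < 1].index[0]
            raise RangeValidationError(f"start < 1 at row {bad}")
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"]].index[0]
            raise RangeValidationError(f"start > end at row {bad}")
        strands = set(df["strand"].unique())
        unknown = strands - STRANDS
        if unknown:
            raise RangeValidationError(f"unknown strand symbol(s): {sorted(unknown)}")
        if self.genome is not None and self.genome.lengths is not None:
            lens = df["seqname"].map(self.genome.lengths)
            over = lens.notna() & (df["end"] > lens)
            if over.any():
                bad = df.loc[over].iloc[0]
                raise RangeValidationError(
                    f"end {bad['end']} exceeds declared length of {bad['seqname']!r}"
                )

    # -- fluent method sugar (delegates to module verbs) ---------------------

    def with_genome(self, label, force: bool = False) -> "RangeTable":
        return with_genome(self, label, force=force)

    def restyle_seqnames(self, style: str) -> "RangeTable":
        return restyle_seqnames(self, style)

    def anchored_set_width(self, anchor, new_width: int) -> "RangeTable":
        return anchored_set_width(self, anchor, new_width)

    def join_overlap_left(self, right: "RangeTable", **kw) -> "RangeTable":
        return join_overlap_left(self, right, **kw)

    def reduce_ranges_directed(self, group_keys, aggregators) -> "RangeTable":
        return reduce_ranges_directed(self, group_keys, aggregators)

    def expand_list_columns(self, cols) -> "RangeTable":
        return expand_list_columns(self, cols)

    def summarize_groups(self, keys, aggregators) -> pd.DataFrame:
        return summarize_groups(self, keys, aggregators)

    def slice_sample(self, size: int, rng) -> "RangeTable":
        return slice_sample(self, size, rng)


def _normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(df).copy()
    missing = [c for c in ("seqname", "start", "end") if c not in df.columns]
    if missing:
        raise RangeValidationError(f"missing required column(s): {missing}")
    if "strand" not in df.columns:
        df["strand"] = "*"
    df["strand"] = df["strand"].fillna("*").astype(str)
    for c in ("start", "end"):
        v = pd.to_numeric(df[c], errors="raise")
        iv = v.astype(np.int64)
        if not np.array_equal(iv.to_numpy(), v.to_numpy()):
            raise RangeValidationError(f"column {c!r} has non-integer coordinates")
        df[c] = iv
    df["seqname"] = df["seqname"].astype(str)
    order = list(COORD_COLS) + [c for c in df.columns if c not in COORD_COLS]
    return df[order].reset_index(drop=True)


def _label(t: RangeTable) -> str | None:
    return t.genome.label if t.genome is not None else None


def _as_genome(genome) -> GenomeInfo | None:
    if genome is None or isinstance(genome, GenomeInfo):
        return genome
    return GenomeInfo(label=str(genome))


# ---------------------------------------------------------------------------
# verbs
# ---------------------------------------------------------------------------

def validate_ranges(rows, genome=None) -> RangeTable:
    """Build a validated :class:`RangeTable` from raw records.

    ``rows`` may be a DataFrame or any iterable of mappings providing
    ``seqname``/``start``/``end`` (``strand`` optional, default ``*``).
    """
    if isinstance(rows, RangeTable):
        df = rows.df
    elif isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    return RangeTable(df, genome=_as_genome(genome))


def with_genome(t: RangeTable, label, force: bool = False) -> RangeTable:
    """Attach a genome label; changing an existing one requires ``force``."""
    new = _as_genome(label)
    if new is None or not new.label:
        raise RangeValidationError("genome label must be non-empty")
    old = t.genome
    if old is not None and old.label != new.label and not force:
        raise GenomeMismatchError(
            f"table already labeled {old.label!r}; pass force=True to relabel "
            f"as {new.label!r}"
        )
    return t._replace(t.df, genome=new)


# canonical chromosomes only; scaffolds/patches pass through with a warning
_ENSEMBL_TO_UCSC = {str(i): f"chr{i}" for i in range(1, 23)}
_ENSEMBL_TO_UCSC.update({"X": "chrX", "Y": "chrY", "MT": "chrM"})
_UCSC_TO_ENSEMBL = {v: k for k, v in _ENSEMBL_TO_UCSC.items()}


def restyle_seqnames(t: RangeTable, style: str) -> RangeTable:
    """Map sequence names between Ensembl ("1", "MT") and UCSC ("chr1", "chrM").

    Names already in the target style are left alone (idempotent); names in
    neither style pass through with a warning.
    """
    if style not in ("UCSC", "Ensembl"):
        raise ValueError(f"style must be 'UCSC' or 'Ensembl', got {style!r}")
    table = _ENSEMBL_TO_UCSC if style == "UCSC" else _UCSC_TO_ENSEMBL
    known_target = set(table.values())
    names = t.df["seqname"]
    unmapped = sorted(set(names) - set(table) - known_target)
    if unmapped:
        warnings.warn(
            f"seqnames not in the {style} mapping pass through unchanged: "
            f"{unmapped}", stacklevel=2)
    df = t.df.copy()
    df["seqname"] = names.map(lambda s: table.get(s, s))
    return t._replace(df)


def anchored_set_width(t: RangeTable, anchor, new_width: int) -> RangeTable:
    """Set every range's width while holding an anchor point fixed.

    5'/3' anchors resolve via strand (``*`` treated as ``+``). Center
    anchoring uses ``new_start = start + floor((old_width - new_width) / 2)``
    with floor toward -inf, so a width-1 range grown to an even width places
    the original base just left of the new midpoint. Strand, metadata and row
    order are unchanged.
    """
    anchor = Anchor(anchor)
    if new_width < 1:
        raise RangeValidationError(f"new_width must be >= 1, got {new_width}")
    df = t.df.copy()
    s = df["start"].to_numpy()
    e = df["end"].to_numpy()
    minus = (df["strand"] == "-").to_numpy()
    w = np.int64(new_width)
    if anchor is Anchor.FIVE_PRIME:
        new_start = np.where(minus, e - w + 1, s)
    elif anchor is Anchor.THREE_PRIME:
        new_start = np.where(minus, s, e - w + 1)
    elif anchor is Anchor.CENTER:
        old_w = e - s + 1
        new_start = s + (old_w - w) // 2  # int // floors toward -inf
    elif anchor is Anchor.FIX_START:
        new_start = s
    else:  # FIX_END
        new_start = e - w + 1
    if (new_start < 1).any():
        i = int(np.argmax(new_start < 1))
        raise RangeValidationError(
            f"anchored resize pushes start below 1 at row {i} "
            f"({df['seqname'].iloc[i]}:{s[i]}-{e[i]})"
        )
    df["start"] = new_start
    df["end"] = new_start + w - 1
    return t._replace(df)


def bind_ranges(parts, id_column: str) -> RangeTable:
    """Row-wise concatenation of named tables, recording each part's name.

    ``parts`` is an ordered mapping (or sequence of ``(name, table)`` pairs).
    Metadata columns are unioned; values absent from a part are filled as
    missing. All parts must agree on the genome label (unset labels are
    adopted from labeled parts, with a warning).
    """
    if isinstance(parts, Mapping):
        items = list(parts.items())
    else:
        items = list(parts)
    if not items:
        raise ValueError("bind_ranges requires at least one part")
    labels = {_label(t) for _, t in items}
    set_labels = labels - {None}
    if len(set_labels) > 1:
        raise GenomeMismatchError(
            f"conflicting genome labels in bind_ranges: {sorted(set_labels)}")
    if None in labels and set_labels:
        warnings.warn("binding labeled and unlabeled tables; adopting "
                      f"label {next(iter(set_labels))!r}", stacklevel=2)
    genome = next((t.genome for _, t in items if t.genome is not None), None)
    frames = []
    for name, t in items:
        f = t.df.copy()
        f[id_column] = name
        frames.append(f)
    out = pd.concat(frames, ignore_index=True, sort=False)
    return RangeTable(out, genome=genome, validate=False)


def join_overlap_left(left: RangeTable, right: RangeTable, *,
                      suffix: str = ".y",
                      same_strand: bool = False) -> RangeTable:
    """Left overlap join: pair each left range with every overlapping right range.

    Overlap means same seqname and at least one shared base under
    closed-interval arithmetic. Left rows with no overlap emit exactly one row
    with the right-hand metadata missing. Output keeps the LEFT coordinates
    and strand; right metadata columns are appended (suffixed with ``.y`` on
    a name collision). With ``same_strand=True`` only identical strands match.
    """
    ll, rl = _label(left), _label(right)
    if ll is not None and rl is not None and ll != rl:
        raise GenomeMismatchError(
            f"cannot join ranges across genomes {ll!r} and {rl!r}")
    if (ll is None) != (rl is None):
        warnings.warn("joining a genome-labeled table with an unlabeled one",
                      stacklevel=2)

    ldf = left.df.reset_index(drop=True)
    rdf = right.df.reset_index(drop=True)

    trees: dict[str, IntervalTree] = {}
    for seq, sub in rdf.groupby("seqname", sort=False):
        # closed [start, end] -> half-open [start, end + 1)
        trees[seq] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"] + 1, sub.index))

    left_idx: list[int] = []
    right_idx: list[int] = []
    lseq = ldf["seqname"].to_numpy()
    lstart = ldf["start"].to_numpy()
    lend = ldf["end"].to_numpy()
    lstrand = ldf["strand"].to_numpy()
    rstrand = rdf["strand"].to_numpy() if same_strand else None
    for i in range(len(ldf)):
        tree = trees.get(lseq[i])
        hits = sorted(iv.data for iv in tree.overlap(lstart[i], lend[i] + 1)) \
            if tree is not None else []
        if same_strand:
            hits = [j for j in hits if rstrand[j] == lstrand[i]]
        if hits:
            left_idx.extend([i] * len(hits))
            right_idx.extend(hits)
        else:
            left_idx.append(i)
            right_idx.append(-1)

    out = ldf.iloc[left_idx].reset_index(drop=True)
    rmeta = rdf.drop(columns=list(COORD_COLS))
    rename = {c: c + suffix for c in rmeta.columns if c in out.columns}
    rmeta = rmeta.rename(columns=rename)
    # reindexing with -1 (absent from the fresh RangeIndex) yields missing rows
    taken = rmeta.reindex(np.asarray(right_idx)).reset_index(drop=True)
    out = pd.concat([out, taken], axis=1)
    genome = left.genome if left.genome is not None else right.genome
    return RangeTable(out, genome=genome, validate=False)


def _merge_clusters(df: pd.DataFrame, keys: Sequence[str]) -> pd.Series:
    """Assign a cluster id merging overlapping/book-ended same-strand ranges
    within each (keys, seqname, strand) group. ``df`` must be sorted by
    keys + seqname + strand + start."""
    gcols = list(keys) + ["seqname", "strand"]
    gid = df.groupby(gcols, sort=False, observed=True, dropna=False).ngroup()
    cummax_end = df.groupby(gid.to_numpy())["end"].cummax()
    prev_cm = cummax_end.groupby(gid.to_numpy()).shift(1)
    new_cluster = prev_cm.isna() | (df["start"] > prev_cm + 1)
    return new_cluster.cumsum()


def _apply_aggregators(grouped, aggregators: dict) -> pd.DataFrame:
    cols = {}
    for name, fn in aggregators.items():
        cols[name] = grouped.apply(lambda g, f=fn: f(g))
    return pd.DataFrame(cols)


def reduce_ranges_directed(t: RangeTable, group_keys, aggregators) -> RangeTable:
    """Merge overlapping/book-ended same-strand ranges within groups and aggregate.

    Within each combination of ``group_keys``, ranges on the same seqname and
    strand that overlap or touch (gap 0) are merged into their union —
    "directed" because strand is part of the merge key and is preserved. Each
    aggregator is computed over the input rows contributing to a merged range.
    """
    keys = list(group_keys)
    agg.validate_aggregators(aggregators, t.df.columns)
    for k in keys:
        if k not in t.df.columns:
            raise AggKeyError(k)
    df = t.df.reset_index(drop=True)
    sort_cols = keys + ["seqname", "strand", "start", "end"]
    sdf = df.sort_values(sort_cols, kind="mergesort")
    cluster = _merge_clusters(sdf, keys)
    grouped = sdf.groupby(cluster.to_numpy())
    head = grouped[keys + ["seqname", "strand"]].first() if keys else \
        grouped[["seqname", "strand"]].first()
    coords = pd.DataFrame({
        "start": grouped["start"].min(),
        "end": grouped["end"].max(),
    })
    aggs = _apply_aggregators(grouped, aggregators)
    out = pd.concat([head, coords, aggs], axis=1)
    order = ["seqname", "start", "end", "strand"] + keys + list(aggregators)
    out = out.reset_index(drop=True)[order]
    if keys:
        out = out.sort_values(keys, kind="mergesort").reset_index(drop=True)
    return RangeTable(out, genome=t.genome, validate=False)


class AggKeyError(AggregatorError):
    def __init__(self, key):
        super().__init__(f"grouping key references absent column {key!r}")


def expand_list_columns(t: RangeTable, cols) -> RangeTable:
    """Unlist list-valued columns jointly, lengthening the table.

    Every named column must hold a list in each row and, within a row, all
    named columns must have equal lengths; scalar columns and coordinates are
    repeated.
    """
    cols = list(cols)
    df = t.df.reset_index(drop=True)
    for c in cols:
        if c not in df.columns:
            raise AggKeyError(c)
    lengths = pd.DataFrame({c: df[c].map(len) for c in cols})
    if cols and (lengths.nunique(axis=1) > 1).any():
        bad = int((lengths.nunique(axis=1) > 1).idxmax())
        raise RangeValidationError(
            f"per-row list length mismatch across {cols} at row {bad}")
    out = df.explode(cols, ignore_index=True)
    for c in cols:
        out[c] = _maybe_numeric(out[c])
    return t._replace(out)


def _maybe_numeric(s: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(s)
    except (ValueError, TypeError):
        return s


def summarize_groups(t, keys, aggregators) -> pd.DataFrame:
    """Coordinate-free grouped aggregation: one row per key combination.

    Aggregator semantics are identical to :func:`reduce_ranges_directed`;
    :class:`~peakgene.aggregate.Ratio` provides the divide-one-aggregate-by-
    another post-operation. Output rows are sorted by the keys (categorical
    key columns sort by their level order).
    """
    df = t.df if isinstance(t, RangeTable) else pd.DataFrame(t)
    keys = list(keys)
    agg.validate_aggregators(aggregators, df.columns)
    for k in keys:
        if k not in df.columns:
            raise AggKeyError(k)
    # group by renamed key Series so the key columns stay visible to the
    # aggregators without pandas treating them as grouping columns
    grouped = df.groupby([df[k].rename(f"__key_{k}") for k in keys],
                         sort=True, observed=True, dropna=False)
    aggs = _apply_aggregators(grouped, aggregators)
    out = aggs.reset_index()
    return out.rename(columns={f"__key_{k}": k for k in keys})


def slice_sample(t: RangeTable, size: int, rng: np.random.Generator) -> RangeTable:
    """Sample ``size`` distinct rows without replacement, in draw order."""
    n = len(t)
    if size < 0 or size > n:
        raise ValueError(f"sample size {size} outside [0, {n}]")
    idx = rng.choice(n, size=size, replace=False)
    out = t.df.iloc[idx].reset_index(drop=True)
    return t._replace(out)
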