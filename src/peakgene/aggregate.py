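"""Aggregation vocabulary for grouped range reductions.

The pipeline only ever needs a small, fixed set of reductions: sums and
counts with missing values dropped, a max of absolute values, the number of
distinct resample indices, threshold-exceedance counts, and list columns.
Each aggregator is a small callable applied to the rows of one group; a
:class:`Ratio` combines two of them (used for resample normalization, e.g.
``count_non_missing(da_padj) / n_distinct(resample)``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AggregatorError

__all__ = [
    "Aggregator",
    "Ratio",
    "sum_",
    "max_abs",
    "count_non_missing",
    "n_distinct",
    "count_above",
    "collect_list",
    "constant_list",
]


class Aggregator:
    """One named reduction over a single column of a group of rows."""

    kind = "abstract"

    def __init__(self, column: str | None):
        self.column = column

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.column,) if self.column is not None else ()

    def _values(self, group: pd.DataFrame) -> pd.Series:
        if self.column not in group.columns:
            raise AggregatorError(
                f"aggregator {self.kind!r} references absent column {self.column!r}"
            )
        return group[self.column]

    def __call__(self, group: pd.DataFrame):  # pragma: no cover - abstract
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{self.kind}({self.column!r})"


class _Sum(Aggregator):
    """Sum with missing values dropped; empty/all-missing groups sum to 0."""

    kind = "sum"

    def __call__(self, group: pd.DataFrame):
        v = pd.to_numeric(self._values(group), errors="coerce")
        return v.sum(skipna=True)


class _MaxAbs(Aggregator):
    """max(|x|) over non-missing values; NaN when none are present."""

    kind = "max_abs"

    def __call__(self, group: pd.DataFrame):
        v = pd.to_numeric(self._values(group), errors="coerce").dropna()
        if len(v) == 0:
            return np.nan
        return float(np.abs(v.to_numpy()).max())


class _CountNonMissing(Aggregator):
    kind = "count_non_missing"

    def __call__(self, group: pd.DataFrame):
        return int(self._values(group).notna().sum())


class _NDistinct(Aggregator):
    """Number of distinct values (missing counts as one value, if present)."""

    kind = "n_distinct"

    def __call__(self, group: pd.DataFrame):
        return int(self._values(group).nunique(dropna=False))


class _CountAbove(Aggregator):
    """Count of |x| strictly above each threshold, missing dropped.

    With a scalar threshold the result is a single integer; with a sequence
    it is a list of integers aligned with the thresholds (a list column,
    suitable for later expansion).
    """

    kind = "count_above"

    def __init__(self, column: str, thresholds):
        super().__init__(column)
        self.thresholds = thresholds

    def __call__(self, group: pd.DataFrame):
        v = pd.to_numeric(self._values(group), errors="coerce").to_numpy()
        a = np.sort(np.abs(v[~np.isnan(v)]))
        t = np.asarray(self.thresholds, dtype=float)
        # strictly greater: everything after the rightmost insertion point
        counts = a.size - np.searchsorted(a, t, side="right")
        if np.isscalar(self.thresholds):
            return int(counts)
        return [int(c) for c in np.atleast_1d(counts)]

    def __repr__(self) -> str:
        return f"count_above({self.column!r}, {self.thresholds!r})"


class _CollectList(Aggregator):
    kind = "collect_list"

    def __call__(self, group: pd.DataFrame):
        return list(self._values(group))


class _ConstantList(Aggregator):
    """Attach the same list to every group (e.g. the threshold grid)."""

    kind = "constant_list"

    def __init__(self, values: Sequence):
        super().__init__(None)
        self.values = list(values)

    def __call__(self, group: pd.DataFrame):
        return list(self.values)

    def __repr__(self) -> str:
        return f"constant_list(<{len(self.values)} values>)"


class Ratio:
    """Quotient of two aggregators, evaluated on the same group."""

    kind = "ratio"

    def __init__(self, numerator: Aggregator, denominator: Aggregator):
        check_aggregator(numerator)
        check_aggregator(denominator)
        self.numerator = numerator
        self.denominator = denominator

    @property
    def required_columns(self) -> tuple[str, ...]:
        return self.numerator.required_columns + self.denominator.required_columns

    def __call__(self, group: pd.DataFrame):
        num = self.numerator(group)
        den = self.denominator(group)
        return num / den if den != 0 else np.nan

    def __repr__(self) -> str:
        return f"ratio({self.numerator!r}, {self.denominator!r})"


def sum_(column: str) -> Aggregator:
    return _Sum(column)


def max_abs(column: str) -> Aggregator:
    return _MaxAbs(column)


def count_non_missing(column: str) -> Aggregator:
    return _CountNonMissing(column)


def n_distinct(column: str) -> Aggregator:
    return _NDistinct(column)


def count_above(column: str, thresholds) -> Aggregator:
    return _CountAbove(column, thresholds)


def collect_list(column: str) -> Aggregator:
    return _CollectList(column)


def constant_list(values: Sequence) -> Aggregator:
    return _ConstantList(values)


def check_aggregator(agg) -> None:
    """Reject anything outside the fixed aggregator vocabulary."""
    if not isinstance(agg, (Aggregator, Ratio)):
        raise AggregatorError(f"unknown aggregator: {agg!r}")


def validate_aggregators(aggregators: dict, columns) -> None:
    cols = set(columns)
    for name, agg in aggregators.items():
        check_aggregator(agg)
        for c in agg.required_columns:
            if c not in cols:
                raise AggregatorError(
                    f"aggregator {name!r} references absent column {c!r}"
                )
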