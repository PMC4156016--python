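"""Contingency tables and Pearson chi-square tests.

Used for three jobs in the pipeline: feature use by subgroup,
engagement-pattern membership by subgroup, and attrition checks
comparing the analysis sample against participants excluded from it.
Tests are plain Pearson chi-square without continuity correction;
tables with small expected cells are flagged, never silently switched
to a different test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass(frozen=True)
class ContingencyTable:
    """Observed counts with row/column labels."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def column_proportions(self) -> pd.DataFrame:
        """Share of each column falling in each row (class-share style)."""
        totals = self.col_totals
        if (totals == 0).any():
            raise ValueError("column proportions undefined with an empty column")
        return self.to_frame() / totals


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test outcome with its expected-count matrix."""

    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    min_expected: float

    @property
    def small_cells(self) -> bool:
        """True when any expected count falls below the usual threshold of 5."""
        return self.min_expected < 5.0


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, the convention of printed tables."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def pearson_chisq(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Raises ``ValueError`` for degenerate tables (fewer than two rows or
    columns, empty margins), for which independence has no content.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(f"need a table of at least 2x2, got {counts.shape}")
    if table.grand_total == 0:
        raise ValueError("empty table")
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    stat, p, df, expected = chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        expected=expected,
        min_expected=float(expected.min()),
    )


def attrition_table(
    full_counts: Sequence[int],
    subset_counts: Sequence[int],
    categories: Sequence[str] | None = None,
) -> ContingencyTable:
    """Retained-vs-excluded table from a full sample and a retained subset.

    Columns are the retained subset and the difference ``full - subset``
    (the excluded participants); rows are the baseline categories.
    """
    full = np.asarray(full_counts, dtype=np.int64)
    subset = np.asarray(subset_counts, dtype=np.int64)
    if full.shape != subset.shape or full.ndim != 1:
        raise ValueError("full_counts and subset_counts must be 1-D and equal length")
    excluded = full - subset
    if (excluded < 0).any():
        raise ValueError("subset counts exceed full counts")
    if categories is None:
        categories = [f"cat{i}" for i in range(len(full))]
    return ContingencyTable(
        row_labels=tuple(categories),
        col_labels=("retained", "excluded"),
        counts=np.column_stack([subset, excluded]),
    )


def crosstab_classes(
    assignments: Sequence[str],
    subgroups: Sequence[str],
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> tuple[ContingencyTable, ChiSquareResult, pd.DataFrame]:
    """Engagement-class by subgroup cross-tab with its chi-square test.

    Returns the count table, the test result, and the column-proportion
    table (the share of each subgroup falling in each class).
    """
    assignments = pd.Series(list(assignments), name="class")
    subgroups = pd.Series(list(subgroups), name="subgroup")
    if len(assignments) != len(subgroups):
        raise ValueError(
            f"assignments ({len(assignments)}) and subgroups "
            f"({len(subgroups)}) must cover the same participants"
        )
    ct = pd.crosstab(assignments, subgroups)
    if row_order is not None:
        missing = set(ct.index) - set(row_order)
        if missing:
            raise ValueError(f"row_order missing observed classes: {sorted(missing)}")
        ct = ct.reindex([r for r in row_order if r in ct.index])
    if col_order is not None:
        missing = set(ct.columns) - set(col_order)
        if missing:
            raise ValueError(f"col_order missing observed subgroups: {sorted(missing)}")
        ct = ct.reindex(columns=[c for c in col_order if c in ct.columns])
    table = ContingencyTable(
        row_labels=tuple(str(i) for i in ct.index),
        col_labels=tuple(str(c) for c in ct.columns),
        counts=ct.to_numpy(),
    )
    result = pearson_chisq(table)
    return table, result, table.column_proportions()


def feature_use_tables(
    counts_by_feature: Mapping[str, Sequence[Sequence[int]]],
    level_labels: Mapping[str, Sequence[str]],
    col_labels: Sequence[str],
) -> dict[str, tuple[ContingencyTable, ChiSquareResult]]:
    """Build and test one feature-by-subgroup table per feature."""
    out = {}
    for feature, counts in counts_by_feature.items():
        table = ContingencyTable(
            row_labels=tuple(level_labels[feature]),
            col_labels=tuple(col_labels),
            counts=np.asarray(counts),
        )
        out[feature] = (table, pearson_chisq(table))
    return out
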