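"""Closed-form group comparison statistics from published summary data.

One-way ANOVA, Pearson chi-square, pooled moments and category
proportions computed directly from (n, mean, sd) triplets and
contingency counts, so cohort tables can be checked without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "anova_from_summary",
    "chi_square_independence",
    "pooled_moments",
    "category_proportion",
    "AnovaResult",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and standard deviation."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled nonnegative integer counts with positive margins."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def row_margin(self, label: str) -> float:
        return float(self.counts[self.row_labels.index(label)].sum())

    def col_margin(self, label: str) -> float:
        return float(self.counts[:, self.col_labels.index(label)].sum())


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    eta_squared: float
    p_value: float
    ss_between: float
    ss_within: float


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA recovered exactly from per-group (n, mean, sd).

    SSB = sum n_i (mean_i - grand)^2 and SSW = sum (n_i - 1) sd_i^2
    reproduce the raw-data decomposition whenever the summaries are exact.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    n_total = n.sum()
    k = len(groups)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = float((n * m).sum() / n_total)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * sd**2).sum())
    df_b = k - 1
    df_w = int(n_total) - k
    f_stat = (ssb / df_b) / (ssw / df_w)
    eta2 = ssb / (ssb + ssw)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(f_stat, df_b, df_w, eta2, p, ssb, ssw)


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns (chi2, df, p).
    """
    observed = table.counts
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all margins must be positive")
    expected = row @ col / observed.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def pooled_moments(groups: Sequence[GroupSummary]) -> tuple[float, float]:
    """Pooled mean and SD of the concatenated sample implied by summaries."""
    if not groups:
        raise ValueError("need at least one group")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    n_total = n.sum()
    mean = float((n * m).sum() / n_total)
    ssb = float((n * (m - mean) ** 2).sum())
    ssw = float(((n - 1) * sd**2).sum())
    if n_total < 2:
        return mean, 0.0
    var = (ssb + ssw) / (n_total - 1)
    return mean, float(np.sqrt(var))


def category_proportion(table: ContingencyTable, category: str) -> float:
    """Percentage of the total count falling in a row category."""
    if table.total <= 0:
        raise ValueError("empty table")
    if category in table.row_labels:
        margin = table.row_margin(category)
    elif category in table.col_labels:
        margin = table.col_margin(category)
    else:
        raise KeyError(f"unknown category {category!r}")
    return 100.0 * margin / table.total


def summaries_from_frame(frame: pd.DataFrame) -> list[GroupSummary]:
    """Build summaries from a CSV-shaped frame with label/n/mean/sd columns."""
    required = {"label", "n", "mean", "sd"}
    if not required.issubset(frame.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    return [
        GroupSummary(str(r.label), int(r.n), float(r.mean), float(r.sd))
        for r in frame.itertuples(index=False)
    ]
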