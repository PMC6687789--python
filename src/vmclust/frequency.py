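"""Contingency tables and chi-square tests of label frequency by group.

Each trial is the unit of observation: tables cross group membership
(e.g. sex-by-phase) with the shape or shape-by-magnitude category the
pipeline assigned.  Besides the Pearson statistic and its asymptotic
p-value, per-cell contributions (O - E)^2 / E are reported, since they
localize which group/category combinations drive a significant test.

When expected counts fall below 5 the asymptotic reference distribution
is unreliable; a fixed-margin Monte-Carlo test is provided instead: it
samples random tables from the conditional null distribution given the
observed row and column totals (Patefield's algorithm) and estimates
p = (1 + #{simulated statistic >= observed}) / (n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError


@dataclass
class ContingencyTable:
    """Counts of trials per (group, category) cell."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape must match row/column labels")
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        if c.sum() < 1:
            raise ValidationError("table grand total must be >= 1")
        self.counts = c.astype(np.int64)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def drop_empty(self) -> "ContingencyTable":
        """Return a copy without all-zero rows/columns."""
        rk = self.row_totals > 0
        ck = self.col_totals > 0
        return ContingencyTable(
            row_labels=[r for r, k in zip(self.row_labels, rk) if k],
            col_labels=[c for c, k in zip(self.col_labels, ck) if k],
            counts=self.counts[np.ix_(rk, ck)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class ChiSquareResult:
    """Pearson chi-square test output with cell-level detail."""

    statistic: float
    df: int
    expected: np.ndarray
    contributions: np.ndarray
    p_asymptotic: float
    p_monte_carlo: float | None = None
    n_sim: int = 0
    seed: int | None = None


def build_table(labeled: Iterable[tuple[Hashable, Hashable]]) -> ContingencyTable:
    """Cross-tabulate (group, category) pairs.

    Rows and columns are ordered by first appearance, which keeps tables
    deterministic without imposing an ordering on user-defined groups.
    """
    pairs = list(labeled)
    if not pairs:
        raise ValidationError("cannot tabulate an empty collection")
    rows: dict = {}
    cols: dict = {}
    for g, c in pairs:
        rows.setdefault(g, len(rows))
        cols.setdefault(c, len(cols))
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for g, c in pairs:
        counts[rows[g], cols[c]] += 1
    return ContingencyTable(row_labels=list(rows), col_labels=list(cols), counts=counts)


def _expected(table: ContingencyTable) -> np.ndarray:
    return np.outer(table.row_totals, table.col_totals) / table.grand_total


def chi_square(table: ContingencyTable, on_empty: str = "error") -> ChiSquareResult:
    """Pearson chi-square test of independence, uncorrected.

    No continuity correction is applied.  All-zero rows/columns make the
    statistic undefined; pass ``on_empty="drop"`` to discard them first.
    """
    if np.any(table.row_totals == 0) or np.any(table.col_totals == 0):
        if on_empty == "drop":
            table = table.drop_empty()
        else:
            raise ValidationError(
                "table has an all-zero row or column; pass on_empty='drop' to discard"
            )
    if len(table.row_labels) < 2 or len(table.col_labels) < 2:
        raise ValidationError("chi-square needs at least a 2x2 table")
    expected = _expected(table)
    contributions = (table.counts - expected) ** 2 / expected
    statistic = float(contributions.sum())
    df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        expected=expected,
        contributions=contributions,
        p_asymptotic=float(sstats.chi2.sf(statistic, df)),
    )


def monte_carlo_p(table: ContingencyTable, n_sim: int = 9999, seed: int = 0) -> float:
    """Fixed-margin Monte-Carlo p-value for the Pearson statistic.

    Random tables are drawn from the conditional null given the observed
    row and column totals (Patefield sampling); the estimator carries
    the +1 correction so it never returns exactly 0.
    """
    if n_sim < 999:
        raise ValidationError(f"n_sim must be >= 999, got {n_sim}")
    observed = chi_square(table)
    rng = np.random.default_rng(seed)
    sampler = sstats.random_table(table.row_totals, table.col_totals)
    sims = sampler.rvs(n_sim, method="patefield", random_state=rng)
    expected = observed.expected
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    exceed = int(np.count_nonzero(sim_stats >= observed.statistic))
    return (1 + exceed) / (n_sim + 1)


def frequency_report(table: ContingencyTable) -> pd.DataFrame:
    """Per-row relative frequencies, in percent.

    Rows with a zero total are reported as NaN rather than dropped.
    """
    totals = table.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals[:, None] > 0, table.counts / totals[:, None] * 100.0, np.nan)
    return pd.DataFrame(pct, index=table.row_labels, columns=table.col_labels)
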