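"""Between-condition statistics on per-cell mean intensities.

A comparison of two conditions ("before" vs "after" incubation) reports:

* a five-number percentile summary (10/25/50/75/90) per group, the numbers
  behind a whisker box plot;
* the two-sided Mann-Whitney U test for a location difference between the
  two intensity distributions;
* the fold change FC = mean(after) / mean(before) of the per-cell mean
  intensities (a median-ratio mode is also available).  FC < 1 means the
  fluorescence, hence the stained RNA content, decreased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .segmentation import ObjectMeasurement

logger = logging.getLogger(__name__)

#: largest n_a * n_b for which the exact permutation null is enumerated
EXACT_TEST_CUTOFF = 400


@dataclass
class CellTable:
    """Per-cell measurements surviving all filters for one group."""

    group: str
    rows: list[ObjectMeasurement] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([m.mean_intensity for m in self.rows], dtype=float)

    def extend(self, other: "CellTable") -> None:
        self.rows.extend(other.rows)


@dataclass
class ComparisonResult:
    """Statistics of one condition pair (a = before, b = after)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    fc: float
    u_stat: float
    p_value: float
    percentiles_a: tuple[float, float, float, float, float]
    percentiles_b: tuple[float, float, float, float, float]

    def display_p(self) -> str:
        """P value to 3 decimals, floored as '<= 0.001' in display."""
        return "<= 0.001" if self.p_value <= 0.001 else f"= {self.p_value:.3f}"


def boxplot_summary(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """10th, 25th, 50th, 75th and 90th percentiles of a sample.

    Percentiles use linear interpolation between order statistics (the
    inclusive method).  A single value yields five equal percentiles.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_summary needs at least one value")
    return tuple(np.percentile(arr, [10, 25, 50, 75, 90], method="linear"))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties and reported for
    sample ``a``.  The p-value is obtained by exact enumeration of the
    permutation null when ``n_a * n_b <= EXACT_TEST_CUTOFF`` and the pooled
    sample is tie-free, and otherwise by the normal approximation with tie
    and continuity corrections.  When every value in both samples is
    identical the test is degenerate and ``p = 1`` is returned (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.info("degenerate Mann-Whitney input: all values identical; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_TEST_CUTOFF and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fold_change(
    before: Sequence[float],
    after: Sequence[float],
    mode: Literal["mean", "median"] = "mean",
) -> float:
    """Fold change of the after-condition relative to the before-condition.

    Default is the ratio of means of the per-cell mean intensities;
    ``mode="median"`` uses the ratio of medians instead.  Values below 1
    indicate a fluorescence decrease.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("both samples must be nonempty")
    summary = np.mean if mode == "mean" else np.median
    denom = float(summary(before))
    if denom <= 0:
        raise ValueError(f"non-positive before-condition {mode} ({denom}); FC undefined")
    return float(summary(after)) / denom


def compare_cell_tables(
    before: CellTable, after: CellTable, fc_mode: Literal["mean", "median"] = "mean"
) -> ComparisonResult:
    """Full comparison of two cell tables (a = before, b = after)."""
    va, vb = before.intensities, after.intensities
    u, p = mann_whitney_u(va, vb)
    return ComparisonResult(
        group_a=before.group,
        group_b=after.group,
        n_a=before.n_cells,
        n_b=after.n_cells,
        fc=fold_change(va, vb, mode=fc_mode),
        u_stat=u,
        p_value=p,
        percentiles_a=boxplot_summary(va),
        percentiles_b=boxplot_summary(vb),
    )
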