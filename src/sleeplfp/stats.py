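"""Group-comparison statistics for per-animal metrics.

Test selection follows the conventional rule for small electrophysiology
group sizes: a Shapiro-Wilk normality screen (alpha 0.05) on each group
chooses between the parametric test (Student's t, paired or unpaired) and
its rank-based counterpart (Mann-Whitney U, or Wilcoxon signed-rank for
paired designs).  When more than two comparisons share one data set, the
reported significance threshold is Bonferroni-adjusted (alpha / m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComparisonResult:
    metric: str
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    normal: bool
    alpha: float
    alpha_adjusted: float
    n_comparisons: int

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Adjusted per-comparison threshold; applied when more than two
    comparisons share a data set, otherwise the raw alpha is kept."""
    if n_comparisons > 2:
        return alpha / n_comparisons
    return alpha


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False  # Shapiro-Wilk undefined; fall back to rank test
    return stats.shapiro(x).pvalue > alpha


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    paired: bool = False,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """Compare one metric between two groups (or conditions, if paired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal group sizes")
    normal = _is_normal(a, normality_alpha) and _is_normal(b, normality_alpha)
    if paired:
        if normal:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
    else:
        if normal:
            res = stats.ttest_ind(a, b)
            name = "Student's t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    return ComparisonResult(
        metric=metric,
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        normal=normal,
        alpha=alpha,
        alpha_adjusted=bonferroni_alpha(alpha, n_comparisons),
        n_comparisons=n_comparisons,
    )


def compare_band_powers(
    table: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    bands: Sequence[str] = ("SO", "delta", "sigma"),
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-band group comparison with a shared Bonferroni correction.

    ``table`` holds one row per animal with one column per band power; the
    three band comparisons share one data set, so each is reported against
    alpha / 3 (~0.017 for the default bands).
    """
    if groups is None:
        uniq = list(pd.unique(table[group_col]))
        if len(uniq) != 2:
            raise ValueError(f"expected 2 groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    g0 = table[table[group_col] == groups[0]]
    g1 = table[table[group_col] == groups[1]]
    return [
        group_compare(
            g0[band].to_numpy(),
            g1[band].to_numpy(),
            metric=band,
            alpha=alpha,
            n_comparisons=len(bands),
        )
        for band in bands
    ]
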