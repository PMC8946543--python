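"""Nonparametric genotype comparison.

The reporting protocol: Shapiro–Wilk normality is recorded for each group
(the pipeline proceeds nonparametrically regardless, since these intensity
and coefficient distributions are not normal), groups are compared with the
two-sample Mann–Whitney U test (two-tailed), and distributions are
summarized by medians with bootstrap percentile 95% confidence intervals.

Note on naming: the two-sample rank test for independent groups is the
Mann–Whitney U (rank-sum) test; the Wilcoxon *signed-rank* test applies to
paired data and is not used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "shapiro_gate", "mann_whitney", "median_ci",
           "compare_groups"]


@dataclass
class GroupComparison:
    """Wt-vs-TrJ comparison of one per-nucleus measure."""

    measure_name: str
    n_wt: int
    n_trj: int
    median_wt: float
    median_trj: float
    ci95_wt: Tuple[float, float] | None
    ci95_trj: Tuple[float, float] | None
    U: float
    p_two_tailed: float
    shapiro_p_wt: float
    shapiro_p_trj: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_two_tailed <= self.alpha)


def shapiro_gate(sample: Sequence[float]) -> float:
    """Shapiro–Wilk normality p-value (recorded, never used to switch tests).

    Raises
    ------
    ValueError
        Outside the supported range 3 <= n <= 5000.
    """
    x = np.asarray(sample, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:  # degenerate constant sample: normality undefined
        return float("nan")
    return float(stats.shapiro(x).pvalue)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Mann–Whitney U with a two-tailed p-value.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and there are no ties across samples; otherwise the normal
    approximation with tie correction (and continuity correction).  Returns
    ``(U, p)`` where U counts pairs won by *a*.
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def median_ci(sample: Sequence[float], level: float = 0.95, seed: int = 0,
              n_boot: int = 10_000) -> Tuple[float, Tuple[float, float] | None]:
    """Median with a bootstrap percentile confidence interval.

    Returns ``(median, (lo, hi))``; with fewer than 8 observations the
    interval is omitted (``None``) rather than reported from a bootstrap
    too coarse to mean anything.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    if x.size < 8:
        return med, None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = np.median(x[idx], axis=1)
    lo, hi = np.quantile(boots, [(1 - level) / 2, 1 - (1 - level) / 2])
    return med, (float(lo), float(hi))


def compare_groups(wt: Sequence[float], trj: Sequence[float],
                   measure_name: str = "", alpha: float = 0.05,
                   seed: int = 0) -> GroupComparison:
    """Full genotype comparison of one measure (NaN values dropped)."""
    x = np.asarray(wt, dtype=np.float64)
    y = np.asarray(trj, dtype=np.float64)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    u, p = mann_whitney(x, y)
    med_x, ci_x = median_ci(x, seed=seed)
    med_y, ci_y = median_ci(y, seed=seed + 1)

    def _shapiro(v: np.ndarray) -> float:
        try:
            return shapiro_gate(v)
        except ValueError:
            return float("nan")

    return GroupComparison(
        measure_name=measure_name,
        n_wt=int(x.size), n_trj=int(y.size),
        median_wt=med_x, median_trj=med_y,
        ci95_wt=ci_x, ci95_trj=ci_y,
        U=u, p_two_tailed=p,
        shapiro_p_wt=_shapiro(x), shapiro_p_trj=_shapiro(y),
        alpha=alpha,
    )
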