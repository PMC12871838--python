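"""Normality-gated two-sample comparisons, FDR correction, leakage normalization.

Condition comparisons use independent-samples t-tests (Welch variant) when
both groups pass the Shapiro-Wilk normality test at alpha = 0.05, and
two-sided Mann-Whitney U tests otherwise. Effect sizes are Cohen's d with
the pooled-variance denominator. Families of p-values are corrected for
false discovery rate with the Benjamini-Hochberg step-up procedure.

Liposome leakage traces are normalized between a no-leakage control and the
detergent (Triton X-100) maximum:

    leakage(%) = (F_sample - F_control) / (F_triton - F_control) * 100
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA_NORMALITY = 0.05


@dataclass
class GroupComparison:
    metric_name: str
    n1: int
    n2: int
    normal1: bool
    normal2: bool
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_value: float
    cohens_d: float
    p_adjusted: float = float("nan")


def cohens_d(x, y) -> float:
    """Cohen's d: (mean(x) - mean(y)) / pooled standard deviation.

    Returns NaN when the pooled SD is zero (undefined effect size).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group for Cohen's d")
    n1, n2 = len(x), len(y)
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return 0.0 if x.mean() == y.mean() else float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def compare_groups(
    x,
    y,
    alpha: float = ALPHA_NORMALITY,
    metric_name: str = "",
    equal_var: bool = False,
) -> GroupComparison:
    """Shapiro-Wilk-gated two-sample comparison.

    Welch's t-test if both groups pass normality at ``alpha``, otherwise a
    two-sided Mann-Whitney U test. Cohen's d is always reported.

    Raises
    ------
    ValueError
        If either group has fewer than 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("comparison refused: need n >= 3 per group")
    normal1 = bool(sps.shapiro(x).pvalue > alpha)
    normal2 = bool(sps.shapiro(y).pvalue > alpha)
    if normal1 and normal2:
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        test_used = "t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        test_used = "mann_whitney"
    return GroupComparison(
        metric_name=metric_name,
        n1=len(x),
        n2=len(y),
        normal1=normal1,
        normal2=normal2,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=cohens_d(x, y),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_comparisons(comparisons: list[GroupComparison]) -> list[GroupComparison]:
    """BH-adjust one family of comparisons in place and return it."""
    if comparisons:
        adj = bh_adjust([c.p_value for c in comparisons])
        for c, pa in zip(comparisons, adj):
            c.p_adjusted = float(pa)
    return comparisons


def leakage_percent(f_sample, f_control, f_triton):
    """Percentage dye leakage normalized between control and detergent maximum.

    Scalar inputs give a scalar; time series are handled pointwise. Values
    may fall outside [0, 100] and are reported raw (not clipped).

    Raises
    ------
    ValueError
        If the detergent and control fluorescence coincide anywhere
        (normalization undefined).
    """
    f_sample = np.asarray(f_sample, dtype=float)
    f_control = np.asarray(f_control, dtype=float)
    f_triton = np.asarray(f_triton, dtype=float)
    denom = f_triton - f_control
    if np.any(denom == 0):
        raise ValueError("leakage undefined: f_triton equals f_control")
    out = (f_sample - f_control) / denom * 100.0
    return float(out) if out.ndim == 0 else out
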