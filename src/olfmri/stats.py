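"""Shared frequentist statistics for the morphometry and connectivity stages.

Two-sample contrasts throughout the package are pooled-variance Student
t-tests with df = n1 + n2 - 2, reported with a two-sided p and the 95 %
confidence interval of the mean difference (group A minus group B).
Behaviour correlations are Pearson or Spearman with df = n_pairs - 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TTestResult", "CorrelationResult", "pooled_ttest", "correlate"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    mean_a: float
    mean_b: float
    note: str = ""


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    df: int
    p: float
    n: int
    method: str
    note: str = ""


def pooled_ttest(a, b, ci_level: float = 0.95) -> TTestResult:
    """Independent two-sample t-test with pooled variance.

    The sign convention is ``mean(a) - mean(b)``: a positive t means the
    first group has the larger mean.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t-test input")
    res = sps.ttest_ind(a, b, equal_var=True)
    ci = res.confidence_interval(ci_level)
    df = a.size + b.size - 2
    note = ""
    if np.var(a) == 0 and np.var(b) == 0:
        note = "degenerate: zero variance in both groups"
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        note=note,
    )


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson r or Spearman rho with pairwise-complete observations.

    Subjects with a missing value in either variable are dropped pairwise
    (the behavioural score may legitimately be absent for some subjects).
    Spearman uses midranks for ties. A zero-variance input yields a flagged
    NaN result rather than an exception so callers can tabulate it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    df = n - 2
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, df, np.nan, n, method, note="zero variance")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), df, float(p), n, method)
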