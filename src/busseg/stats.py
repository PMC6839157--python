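"""Model comparison by two-sample Student t-tests.

Architecture accuracies (per-image on a validation set, or per-fold
means under cross-validation) are compared with a pooled-variance
two-sample t-test with df = n1 + n2 - 2, two-tailed: the null is
rejected when |t| >= t_c, the Student quantile at
1 - (1 - confidence)/2.  The pooled (not Welch) form is used because
the degrees of freedom convention n1 + n2 - 2 identifies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TTestResult", "t_critical", "two_sample_t", "compare_models"]


@dataclass(frozen=True)
class TTestResult:
    t_value: float
    df: int
    confidence: float
    t_critical: float
    significant: bool
    direction: str  # "higher" | "lower" | "none" (for the first sample)


def t_critical(confidence: float, df: int) -> float:
    """Two-tailed Student critical value at the given confidence."""
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(sps.t.ppf(1.0 - (1.0 - confidence) / 2.0, df))


def two_sample_t(sample_a, sample_b, confidence: float = 0.95) -> TTestResult:
    """Pooled-variance two-sample t-test, two-tailed.

    Zero pooled variance yields t = 0 for equal means and a flagged
    infinite statistic (sign of the mean difference) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    diff = a.mean() - b.mean()
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    tc = t_critical(confidence, df)
    significant = abs(t) >= tc
    if not significant:
        direction = "none"
    else:
        direction = "higher" if t > 0 else "lower"
    return TTestResult(
        t_value=float(t),
        df=df,
        confidence=confidence,
        t_critical=tc,
        significant=significant,
        direction=direction,
    )


def compare_models(
    per_item_metric_a, per_item_metric_b, confidence: float = 0.95
) -> TTestResult:
    """Compare two models' per-item (or per-fold) metric collections.

    The collections must be the same length — per-image values on a
    shared validation set, or per-fold means from the same k-fold plan.
    ``direction`` reports which model (first = "higher") is
    significantly better, if either.
    """
    a = np.asarray(per_item_metric_a, dtype=float)
    b = np.asarray(per_item_metric_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"collections differ in length: {a.size} vs {b.size}")
    return two_sample_t(a, b, confidence)
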