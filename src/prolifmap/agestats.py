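"""Age-effect statistics for count and density tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: list) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across groups.

    Computed from the definitional between/within sum-of-squares
    decomposition: F = MSB/MSW with the p-value from the upper tail of
    F(df_between, df_within). When every value is identical the result is
    F = 0, p = 1 (no variance to apportion, not an error); a zero
    within-group variance with real between-group spread gives F = inf,
    p = 0.
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrs):
        raise ValueError("every group needs at least one value")
    n = sum(len(a) for a in arrs)
    k = len(arrs)
    if n - k < 1:
        raise ValueError("at least one group needs two or more values")
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(float(F), df_b, df_w, float(f_dist.sf(F, df_b, df_w)))


def decline_rate(
    n_start: float, n_end: float, months: float, method: str = "linear"
) -> float:
    """Rate of decrease in percent per month between two time points.

    The linear convention (default) is the total percentage drop relative to
    the starting value divided by the elapsed months; ``method="geometric"``
    gives the constant per-month percentage decline compounding to the same
    endpoint.
    """
    if n_start <= 0:
        raise ValueError("n_start must be positive")
    if months <= 0:
        raise ValueError("months must be positive")
    if method == "linear":
        return 100.0 * (n_start - n_end) / n_start / months
    if method == "geometric":
        if n_end <= 0:
            raise ValueError("geometric rate needs a positive n_end")
        return 100.0 * (1.0 - (n_end / n_start) ** (1.0 / months))
    raise ValueError(f"unknown method {method!r}")


def fold_change(value_start: float, value_end: float) -> float:
    """Ratio value_start / value_end; NaN (logged) when the end value is 0."""
    if value_end == 0:
        logger.warning("fold change undefined for zero end value")
        return float("nan")
    return value_start / value_end
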