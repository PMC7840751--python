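"""Shared statistics: the single Pearson implementation and group summaries.

The same product-moment routine backs both the PM-plane colocalization
coefficient and the panel-level CC-probability vs percent-PM correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps


class StatsError(ValueError):
    """Raised for undefined statistics (constant input, too few points)."""


def pearson_r(xs, ys) -> float:
    """Pearson product-moment correlation.

    Requires >= 3 paired finite values and non-constant input on both sides;
    a constant channel makes the coefficient undefined and is a hard error,
    never silently 0.
    """
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.shape != y.shape:
        raise StatsError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise StatsError(f"need >= 3 paired values, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for constant input")
    return float(_sps.pearsonr(x, y).statistic)


def sem(values) -> float:
    """Standard error of the mean, sd/sqrt(n) with the n-1 denominator.

    Undefined (NaN) for n = 1; callers flag that case rather than dropping it.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def compare_groups(groups: dict[str, list[float]]) -> dict:
    """Two-sample t test (2 groups) or one-way ANOVA (>2), via SciPy.

    Returns the test name, statistic and p value, plus the significance tier
    used in the figures' convention (0.05 / 0.01 / 0.001).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise StatsError("need at least two groups to compare")
    if len(arrays) == 2:
        res = _sps.ttest_ind(arrays[0], arrays[1])
        name = "t-test"
    else:
        res = _sps.f_oneway(*arrays)
        name = "one-way ANOVA"
    p = float(res.pvalue)
    if p < 0.001:
        tier = "***"
    elif p < 0.01:
        tier = "**"
    elif p < 0.05:
        tier = "*"
    else:
        tier = "ns"
    return {"test": name, "statistic": float(res.statistic), "pvalue": p, "tier": tier}
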