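"""Shared statistical primitives.

All hypothesis tests in the pipeline funnel through these helpers so that
the conventions (Welch's unequal-variance t-test, two-sided p-values,
t-distribution p for Pearson correlation) are applied uniformly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sided t-test between two independent samples.

    Degenerate inputs are resolved by convention rather than returned as
    NaN: two constant samples with equal value give (0.0, 1.0); two
    constant samples with different values give (+/-inf, 0.0).

    Parameters
    ----------
    a, b
        Replicate observations; each must contain at least 2 values.

    Returns
    -------
    (t, p)
        Welch t statistic and two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t requires at least 2 observations per sample")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("two_sample_t requires finite observations")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return (np.inf if a[0] > b[0] else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pearson_fit(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Pearson correlation with two-sided p plus the least-squares line.

    The p-value comes from the t-distribution with n-2 degrees of freedom,
    the classical test used when a correlation is read off a linear
    regression.

    Returns
    -------
    (r, p, slope, intercept)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.linregress(x, y)
    return float(res.rvalue), float(res.pvalue), float(res.slope), float(res.intercept)
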