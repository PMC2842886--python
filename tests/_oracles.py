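"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written as plain-Python loops / direct
library calls, independent of the vectorized implementation paths.
"""

import math

import numpy as np
from scipy import stats


def brute_force_features(x, r_ctm, r_d, r_cctm):
    """Naive per-point recomputation of ctm, d_mean and the cctm counts.

    Returns (ctm_count, d_mean_or_nan, [q1..q4 counts], n_points).
    Quadrants: Q1 xx>=0,yy>0 (origin included); Q2 xx<0,yy>=0;
    Q3 xx<=0,yy<0; Q4 xx>0,yy<=0.
    """
    x = list(map(float, x))
    n = len(x)
    ctm_count = 0
    q = [0, 0, 0, 0]
    in_d = []
    for i in range(n - 2):
        xx = x[i + 1] - x[i]
        yy = x[i + 2] - x[i + 1]
        d = math.sqrt(xx * xx + yy * yy)
        if d < r_ctm:
            ctm_count += 1
        if d < r_d:
            in_d.append(d)
        if d < r_cctm:
            if xx == 0.0 and yy == 0.0:
                q[0] += 1
            elif xx >= 0.0 and yy > 0.0:
                q[0] += 1
            elif xx < 0.0 and yy >= 0.0:
                q[1] += 1
            elif xx <= 0.0 and yy < 0.0:
                q[2] += 1
            elif xx > 0.0 and yy <= 0.0:
                q[3] += 1
    d_mean = sum(in_d) / len(in_d) if in_d else float("nan")
    return ctm_count, d_mean, q, n - 2


def reference_pooled_t(values_n, values_chf, alpha=0.05):
    """Pooled t-test via scipy.stats.ttest_ind, with its own CI."""
    res = stats.ttest_ind(values_n, values_chf, equal_var=True)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return {
        "p": float(res.pvalue),
        "t": float(res.statistic),
        "ci": (float(ci.low), float(ci.high)),
        "h": int(res.pvalue < alpha),
    }


def random_rr_series(rng, n=100, scale=0.02, mean=0.8):
    """A positive random-walk-flavored series exercising all quadrants."""
    steps = rng.normal(0.0, scale, size=n)
    x = mean + np.cumsum(steps) * 0.1 + rng.normal(0.0, scale, size=n)
    return np.clip(x, 0.05, None)
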