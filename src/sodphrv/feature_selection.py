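"""Radius-grid feature selection via the pooled two-sample t-test.

For each SODP feature the radius grid is swept, a pooled-variance
(Student) two-sample t-test is run between the two cohorts at each r,
and the r with the smallest p is selected.  The confidence interval is
for mean(N) - mean(CHF).  No multiple-testing correction is applied
across the grid (deliberate; logged as a caveat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError
from .rr_io import RRSeries
from .sodp_features import cctm, ctm, make_sodp, mean_in_radius_distance, sdrr

logger = logging.getLogger(__name__)

#: default radius grid, seconds: 0.005 .. 0.05 in steps of 0.005
DEFAULT_GRID = tuple(np.round(np.arange(1, 11) * 0.005, 6))

#: features whose value depends on the disc radius
RADIUS_FEATURES = ("ctm", "d_mean", "cctm1", "cctm2", "cctm3", "cctm4")


@dataclass(frozen=True)
class TTestResult:
    h: int
    p: float
    ci: tuple[float, float]
    t: float
    df: int


@dataclass(frozen=True)
class RadiusSelectionResult:
    """Argmin-p radius for one feature, with the full grid trace."""

    feature: str
    r_best: float
    p: float
    h: int
    ci: tuple[float, float]
    grid: tuple  # sequence of (r, p) pairs


def two_sample_t(values_n, values_chf, alpha: float = 0.05) -> TTestResult:
    """Pooled-variance two-sided two-sample t-test, N minus CHF.

    Returns the reject flag ``h`` (1 iff p < alpha), the p-value, and
    the (1 - alpha) confidence interval for mean(N) - mean(CHF).
    Zero pooled variance with identical means yields p = 1 (logged).
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    x = np.asarray(values_n, dtype=float)
    y = np.asarray(values_chf, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("t-test inputs must be finite")
    n1, n2 = len(x), len(y)
    diff = x.mean() - y.mean()
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if diff == 0.0:
            logger.info("zero pooled variance with identical means; returning p=1")
            return TTestResult(h=0, p=1.0, ci=(0.0, 0.0), t=0.0, df=df)
        # perfectly separated degenerate groups
        return TTestResult(h=1, p=0.0, ci=(diff, diff), t=np.inf * np.sign(diff), df=df)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    return TTestResult(h=int(p < alpha), p=float(p), ci=ci, t=float(t), df=df)


def radius_feature_table(
    series_list: list[RRSeries],
    grid=DEFAULT_GRID,
    features=RADIUS_FEATURES,
) -> pd.DataFrame:
    """Tidy table of radius-dependent feature values over the grid.

    Columns: subject_id, group, feature, r, value.  Each subject's SODP
    is built once and reused across the grid.
    """
    unknown = set(features) - set(RADIUS_FEATURES)
    if unknown:
        raise ParameterError(f"not radius-dependent features: {sorted(unknown)}")
    rows = []
    for s in series_list:
        points = make_sodp(s)
        for r in grid:
            vals = {}
            if "ctm" in features:
                vals["ctm"] = ctm(points, r)
            if "d_mean" in features:
                vals["d_mean"] = mean_in_radius_distance(points, r)
            if any(f.startswith("cctm") for f in features):
                c = cctm(points, r)
                for k in range(4):
                    name = f"cctm{k + 1}"
                    if name in features:
                        vals[name] = c[k]
            for feat, v in vals.items():
                rows.append(
                    {"subject_id": s.subject_id, "group": s.group,
                     "feature": feat, "r": float(r), "value": v}
                )
    return pd.DataFrame(rows)


def sweep_radius(table: pd.DataFrame, feature: str, grid, alpha: float = 0.05) -> RadiusSelectionResult:
    """Select the grid radius minimizing the t-test p for one feature.

    ``table`` is the tidy output of :func:`radius_feature_table`.  Ties
    on p are broken toward the smaller radius (logged).  A missing
    feature value for any subject at any grid point is an error naming
    the subject.
    """
    grid = [float(r) for r in grid]
    if not grid:
        raise ParameterError("grid must be nonempty")
    sub = table[table["feature"] == feature]
    if sub.empty:
        raise ParameterError(f"feature {feature!r} absent from table")
    trace = []
    best = None
    for r in grid:
        at_r = sub[np.isclose(sub["r"], r)]
        missing = at_r[~np.isfinite(at_r["value"])]
        if len(missing):
            raise ParameterError(
                f"feature {feature!r} undefined at r={r} for subject "
                f"{missing['subject_id'].iloc[0]!r}"
            )
        vn = at_r.loc[at_r["group"] == "N", "value"].to_numpy()
        vc = at_r.loc[at_r["group"] == "CHF", "value"].to_numpy()
        if len(vn) == 0 or len(vc) == 0:
            raise ParameterError(f"no values at r={r} for one of the groups")
        res = two_sample_t(vn, vc, alpha)
        trace.append((r, res.p))
        if best is None or res.p < best[1].p:
            best = (r, res)
        elif res.p == best[1].p:
            logger.info("p tie at r=%g vs r=%g; keeping smaller radius", r, best[0])
    r_best, res = best
    return RadiusSelectionResult(
        feature=feature, r_best=r_best, p=res.p, h=res.h, ci=res.ci, grid=tuple(trace)
    )


def selection_table(
    series_list: list[RRSeries],
    grid=DEFAULT_GRID,
    alpha: float = 0.05,
    include_sdrr: bool = True,
) -> pd.DataFrame:
    """Radius selection for every SODP feature, plus an SDRR t-test row.

    Mirrors the layout: feature, r_best, p, ci_low, ci_high, h.  SDRR is
    radius-free, so its r_best is NaN.
    """
    table = radius_feature_table(series_list, grid)
    rows = []
    for feature in RADIUS_FEATURES:
        res = sweep_radius(table, feature, grid, alpha)
        rows.append(
            {"feature": feature, "r_best": res.r_best, "p": res.p,
             "ci_low": res.ci[0], "ci_high": res.ci[1], "h": res.h}
        )
    if include_sdrr:
        vn = [sdrr(s) for s in series_list if s.group == "N"]
        vc = [sdrr(s) for s in series_list if s.group == "CHF"]
        res = two_sample_t(vn, vc, alpha)
        rows.append(
            {"feature": "sdrr", "r_best": float("nan"), "p": res.p,
             "ci_low": res.ci[0], "ci_high": res.ci[1], "h": res.h}
        )
    return pd.DataFrame(rows)
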