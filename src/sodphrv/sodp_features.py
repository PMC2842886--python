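"""Second-order difference plot (SODP) construction and its features.

The SODP scatters successive RR differences against each other:
``yy(i) = x(i+2) - x(i+1)`` versus ``xx(i) = x(i+1) - x(i)``.  Features:

* ``ctm(r)``   — fraction of points strictly inside the disc of radius r,
* ``d_mean(r)`` — mean origin distance of the in-disc points,
* ``cctm_k(r)`` — per-quadrant split of ctm (k = 1..4),
* ``sdrr``     — sample SD of the RR intervals themselves.

Quadrant convention (half-open so the four quadrants partition the
plane): Q1 xx>=0, yy>0; Q2 xx<0, yy>=0; Q3 xx<=0, yy<0; Q4 xx>0, yy<=0;
points exactly at the origin are assigned to Q1 so that the partition
identity sum_k cctm_k(r) == ctm(r) holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ParameterError
from .rr_io import RRSeries

logger = logging.getLogger(__name__)

#: canonical feature ordering used by vectors, tables and classifiers
FEATURE_NAMES = ("ctm", "d_mean", "cctm1", "cctm2", "cctm3", "cctm4", "sdrr")
FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: selected radii, seconds: ctm/cctm at 0.015, d_mean at 0.035
DEFAULT_RADII = {"ctm": 0.015, "d_mean": 0.035, "cctm": 0.015}


def _as_rr(series) -> np.ndarray:
    """Accept an RRSeries or a bare 1-D array of intervals."""
    rr = getattr(series, "rr_s", series)
    return np.asarray(rr, dtype=float)


@dataclass(frozen=True)
class SODPPoints:
    """The (xx, yy) difference pairs of one series.

    ``yy`` is ``xx`` shifted by one — both have length ``n_source - 2``.
    """

    xx: np.ndarray
    yy: np.ndarray
    n_source: int

    def __post_init__(self) -> None:
        if len(self.xx) != len(self.yy) or len(self.xx) != self.n_source - 2:
            raise ParameterError("inconsistent SODP point arrays")

    def __len__(self) -> int:
        return len(self.xx)

    @property
    def distances(self) -> np.ndarray:
        return np.hypot(self.xx, self.yy)


def make_sodp(series) -> SODPPoints:
    """Build the SODP point set from a series of at least 3 intervals."""
    rr = _as_rr(series)
    if len(rr) < 3:
        raise InsufficientDataError(f"need >= 3 intervals for an SODP, got {len(rr)}")
    diffs = np.diff(rr)
    return SODPPoints(xx=diffs[:-1], yy=diffs[1:], n_source=len(rr))


def _check_radius(r: float) -> float:
    r = float(r)
    if not r > 0:
        raise ParameterError(f"radius must be > 0, got {r}")
    return r


def in_disc_count(points: SODPPoints, r: float) -> int:
    """Number of SODP points strictly inside the disc of radius r."""
    r = _check_radius(r)
    return int(np.count_nonzero(points.distances < r))


def ctm(points: SODPPoints, r: float) -> float:
    """Fraction of SODP points strictly inside the disc of radius r."""
    return in_disc_count(points, r) / len(points)


def mean_in_radius_distance(points: SODPPoints, r: float) -> float:
    """Mean origin distance of points strictly inside radius r.

    Returns NaN (feature-unavailable) when no point lies inside; the
    classifier treats that as a misclassifying realization.
    """
    r = _check_radius(r)
    d = points.distances
    inside = d < r
    if not inside.any():
        logger.debug("empty disc at r=%g; mean distance undefined", r)
        return float("nan")
    return float(d[inside].mean())


def quadrant_masks(points: SODPPoints) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks of the half-open quadrant partition (origin -> Q1)."""
    xx, yy = points.xx, points.yy
    origin = (xx == 0) & (yy == 0)
    n_origin = int(np.count_nonzero(origin))
    if n_origin:
        logger.debug("%d SODP points at the exact origin assigned to Q1", n_origin)
    q1 = ((xx >= 0) & (yy > 0)) | origin
    q2 = (xx < 0) & (yy >= 0)
    q3 = (xx <= 0) & (yy < 0)
    q4 = (xx > 0) & (yy <= 0)
    return q1, q2, q3, q4


def cctm_counts(points: SODPPoints, r: float) -> tuple[int, int, int, int]:
    """Per-quadrant integer counts of in-disc points.

    These sum exactly to :func:`in_disc_count` — the partition identity
    at the integer level, immune to float rounding.
    """
    r = _check_radius(r)
    inside = points.distances < r
    return tuple(int(np.count_nonzero(inside & q)) for q in quadrant_masks(points))


def cctm(points: SODPPoints, r: float) -> tuple[float, float, float, float]:
    """Per-quadrant fractions of in-disc points (counts / (n_source - 2))."""
    n = len(points)
    return tuple(c / n for c in cctm_counts(points, r))


def sdrr(series) -> float:
    """Sample standard deviation (n-1 denominator) of the RR intervals."""
    rr = _as_rr(series)
    if len(rr) < 2:
        raise InsufficientDataError("need >= 2 intervals for SDRR")
    if np.all(rr == rr[0]):  # exact zero for constant input
        return 0.0
    return float(np.std(rr, ddof=1))


@dataclass(frozen=True)
class FeatureVector:
    """The six SODP features plus SDRR for one series or window."""

    ctm: float
    d_mean: float
    cctm: tuple[float, float, float, float]
    sdrr: float
    radii_used: dict
    window_id: int | None = None

    def as_array(self) -> np.ndarray:
        """Values in :data:`FEATURE_NAMES` order."""
        return np.array([self.ctm, self.d_mean, *self.cctm, self.sdrr])

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.as_array()))


def feature_array(series, radii: dict | None = None) -> np.ndarray:
    """All seven features, computed on one shared SODP, in canonical order."""
    if radii is None:
        radii = DEFAULT_RADII
    points = make_sodp(series)
    return np.array(
        [
            ctm(points, radii["ctm"]),
            mean_in_radius_distance(points, radii["d_mean"]),
            *cctm(points, radii["cctm"]),
            sdrr(series),
        ]
    )


def extract_features(series, radii: dict | None = None, window_id: int | None = None) -> FeatureVector:
    """Compute the full :class:`FeatureVector` for a series or window."""
    if radii is None:
        radii = DEFAULT_RADII
    for key in ("ctm", "d_mean", "cctm"):
        if key not in radii:
            raise ParameterError(f"radii must supply {key!r}")
    vals = feature_array(series, radii)
    return FeatureVector(
        ctm=float(vals[0]),
        d_mean=float(vals[1]),
        cctm=tuple(float(v) for v in vals[2:6]),
        sdrr=float(vals[6]),
        radii_used=dict(radii),
        window_id=window_id,
    )


def feature_table(series_list: list[RRSeries], radii: dict | None = None) -> pd.DataFrame:
    """Per-subject feature table (one row per series, full length)."""
    if radii is None:
        radii = DEFAULT_RADII
    rows = []
    for s in series_list:
        fv = extract_features(s, radii)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "window_id": 0,
                **fv.as_dict(),
                "r_ctm": radii["ctm"],
                "r_d_mean": radii["d_mean"],
                "r_cctm": radii["cctm"],
            }
        )
    return pd.DataFrame(rows)
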