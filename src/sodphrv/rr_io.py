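"""Reading and preprocessing of RR-interval series.

Input files are plain text, one RR interval per line, seconds (a
milliseconds heuristic is applied when every value exceeds 10 s).
Preprocessing removes ectopic beats with a running-median percentage
filter and slow trends with a centered moving average; both are
standard HRV practice and their thresholds are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
    RRParseError,
)

logger = logging.getLogger(__name__)

GROUPS = ("N", "CHF", "unknown")

#: default tolerance of the running-median ectopic filter (fraction of median)
DEFAULT_ECTOPIC_TOLERANCE = 0.2
#: default width, in beats, of the moving-average detrender (odd)
DEFAULT_DETREND_WINDOW = 501
#: number of preceding accepted beats used for the running median
_MEDIAN_HISTORY = 11


@dataclass
class RRSeries:
    """One subject's ordered RR intervals, in seconds.

    Invariants: all intervals strictly positive and finite, and length
    at least 3 (the second-order difference plot needs triples).
    """

    subject_id: str
    group: str
    rr_s: np.ndarray
    preprocessed: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.rr_s = np.asarray(self.rr_s, dtype=float)
        if self.rr_s.ndim != 1:
            raise ParameterError("rr_s must be one-dimensional")
        if len(self.rr_s) < 3:
            raise InsufficientDataError(
                f"RR series {self.subject_id!r} has {len(self.rr_s)} beats; need >= 3"
            )
        if not np.all(np.isfinite(self.rr_s)):
            raise ParameterError(f"RR series {self.subject_id!r} contains non-finite values")
        if np.any(self.rr_s <= 0):
            raise ParameterError(f"RR series {self.subject_id!r} contains non-positive intervals")

    def __len__(self) -> int:
        return len(self.rr_s)


def read_rr_file(path: str | Path, subject_id: str | None = None, group: str = "unknown") -> RRSeries:
    """Read a single-column plain-text RR file into an :class:`RRSeries`.

    Lines starting with ``#`` and blank lines are skipped.  If every
    parsed value exceeds 10 the file is interpreted as milliseconds and
    divided by 1000 (logged).

    Raises
    ------
    RRParseError
        On a non-numeric line (names the 1-based line number).
    EmptyInputError
        If the file holds no numeric data.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise RRParseError(
                    f"{path}: non-numeric value {stripped!r} on line {lineno}",
                    line_number=lineno,
                ) from None
    if not values:
        raise EmptyInputError(f"{path}: no RR intervals found")
    rr = np.asarray(values, dtype=float)
    if np.all(rr > 10.0):
        logger.info("%s: all values > 10; interpreting as milliseconds", path)
        rr = rr / 1000.0
    return RRSeries(subject_id=subject_id, group=group, rr_s=rr, preprocessed=False)


def read_manifest(path: str | Path) -> list[RRSeries]:
    """Read a manifest CSV (columns subject_id, group, path) into series.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = {"subject_id", "group", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"manifest {path} missing columns: {sorted(missing)}")
    series = []
    for row in table.itertuples(index=False):
        rr_path = Path(row.path)
        if not rr_path.is_absolute():
            rr_path = path.parent / rr_path
        series.append(read_rr_file(rr_path, subject_id=str(row.subject_id), group=str(row.group)))
    return series


def ectopic_keep_mask(rr: np.ndarray, tolerance_fraction: float = DEFAULT_ECTOPIC_TOLERANCE) -> np.ndarray:
    """Boolean mask of beats kept by the running-median percentage filter.

    A beat is rejected when it deviates from the median of the preceding
    11 *accepted* beats by more than ``tolerance_fraction`` of that
    median.  The first 11 beats seed the history and are always kept.
    """
    if not 0.0 < tolerance_fraction < 1.0:
        raise ParameterError("tolerance_fraction must be in (0, 1)")
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    keep = np.ones(n, dtype=bool)
    if n < _MEDIAN_HISTORY + 1:
        return keep
    history = list(rr[:_MEDIAN_HISTORY])
    for i in range(_MEDIAN_HISTORY, n):
        med = float(np.median(history))
        if abs(rr[i] - med) > tolerance_fraction * med:
            keep[i] = False
            continue
        history.append(rr[i])
        if len(history) > _MEDIAN_HISTORY:
            history.pop(0)
    return keep


def remove_ectopic(series: RRSeries, tolerance_fraction: float = DEFAULT_ECTOPIC_TOLERANCE) -> RRSeries:
    """Delete ectopic-looking beats; surviving intervals are unchanged.

    Series shorter than 12 beats are returned unchanged with a warning.
    """
    if len(series) < _MEDIAN_HISTORY + 1:
        warnings.warn(
            f"series {series.subject_id!r} has fewer than {_MEDIAN_HISTORY + 1} beats; "
            "ectopic filter skipped",
            stacklevel=2,
        )
        return replace(series, rr_s=series.rr_s.copy())
    keep = ectopic_keep_mask(series.rr_s, tolerance_fraction)
    n_removed = int(np.count_nonzero(~keep))
    if n_removed:
        logger.debug("%s: removed %d ectopic beats", series.subject_id, n_removed)
    return replace(series, rr_s=series.rr_s[keep])


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric shrinking windows at edges."""
    n = len(x)
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = idx - h
    hi = idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def remove_trend(series: RRSeries, window_beats: int = DEFAULT_DETREND_WINDOW) -> RRSeries:
    """Subtract a centered moving average and add back the global mean.

    Restoring the mean keeps the absolute RR scale, so disc radii in
    seconds stay meaningful downstream.  Series shorter than the window
    fall back to a global linear detrend (logged).  If detrending would
    produce a non-positive interval the input is considered pathological
    and an error is raised instead of clipping.
    """
    if window_beats < 3 or window_beats % 2 == 0:
        raise ParameterError("window_beats must be odd and >= 3")
    x = series.rr_s
    mean = x.mean()
    if len(x) < window_beats:
        logger.info(
            "%s: %d beats < window %d; using global linear detrend",
            series.subject_id, len(x), window_beats,
        )
        t = np.arange(len(x), dtype=float)
        slope, intercept = np.polyfit(t, x, 1)
        detrended = x - (slope * t + intercept) + mean
    else:
        detrended = x - _centered_moving_average(x, window_beats) + mean
    if np.any(detrended <= 0):
        raise ParameterError(
            f"detrending {series.subject_id!r} produced non-positive intervals; "
            "input looks pathological (clipping is deliberately not applied)"
        )
    return replace(series, rr_s=detrended)


def preprocess(
    series: RRSeries,
    ectopic_tolerance_fraction: float = DEFAULT_ECTOPIC_TOLERANCE,
    detrend_window_beats: int = DEFAULT_DETREND_WINDOW,
) -> RRSeries:
    """Ectopic removal followed by detrending; marks the result preprocessed."""
    cleaned = remove_ectopic(series, ectopic_tolerance_fraction)
    cleaned = remove_trend(cleaned, detrend_window_beats)
    return replace(cleaned, preprocessed=True)


def write_rr_file(series: RRSeries, path: str | Path) -> None:
    """Write one RR interval (seconds) per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for v in series.rr_s:
            fh.write(f"{v:.9f}\n")


def write_cohort(series_list: list[RRSeries], out_dir: str | Path) -> Path:
    """Write per-subject RR files plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series_list:
        fname = f"{s.subject_id}.txt"
        write_rr_file(s, out_dir / fname)
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
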