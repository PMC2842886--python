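"""Leave-one-subject-out 1-NN ensemble over SODP feature subsets.

Training vectors are each subject's features on its full training
stretch; the held-out subject is tested on ``mc`` windows taken at
evenly spaced starts inside that stretch.  For every non-empty subset
of the configured feature set, a subset flag P is raised when the
fraction of misclassified window realizations strictly exceeds the
realization threshold; the subject is declared misclassified when the
fraction of raised subset flags strictly exceeds the group threshold.

Distances: Euclidean on raw feature values, or Mahalanobis with the
covariance of the 71 training vectors (held-out subject excluded),
ridge-regularized when near-singular.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import InsufficientDataError, ParameterError
from .rr_io import RRSeries
from .sodp_features import DEFAULT_RADII, FEATURE_INDEX, FEATURE_NAMES, feature_array

logger = logging.getLogger(__name__)

DISTANCES = ("euclidean", "mahalanobis")

#: relative ridge added to a near-singular training covariance
RIDGE_FACTOR = 1e-8


@dataclass(frozen=True)
class EnsembleConfig:
    """Geometry and voting parameters of one classification run."""

    distance: str = "euclidean"
    k: int = 1
    window_length: int = 30000
    train_length: int = 70000
    mc: int = 31
    realization_threshold: float = 0.95
    group_threshold: float = 0.95
    feature_set: tuple = FEATURE_NAMES
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.distance not in DISTANCES:
            raise ParameterError(f"distance must be one of {DISTANCES}")
        if self.k < 1 or self.k % 2 == 0:
            raise ParameterError("k must be a positive odd integer")
        if self.window_length < 3 or self.train_length < 3:
            raise ParameterError("window_length and train_length must be >= 3")
        if self.window_length > self.train_length:
            raise ParameterError("window_length must be <= train_length")
        if self.mc < 1:
            raise ParameterError("mc must be >= 1")
        for name in ("realization_threshold", "group_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1]")
        fs = tuple(self.feature_set)
        if not fs:
            raise ParameterError("feature_set must be nonempty")
        unknown = set(fs) - set(FEATURE_NAMES)
        if unknown:
            raise ParameterError(f"unknown features: {sorted(unknown)}")
        object.__setattr__(self, "feature_set", fs)

    def feature_subsets(self) -> list[tuple]:
        """All 2^m - 1 non-empty subsets, in deterministic order."""
        fs = self.feature_set
        return [
            subset
            for size in range(1, len(fs) + 1)
            for subset in combinations(fs, size)
        ]


@dataclass
class ClassificationReport:
    """Per-subject vote matrix and cohort-level misclassification counts."""

    config: EnsembleConfig
    per_subject: dict = field(default_factory=dict)

    @property
    def n_misclassified_n(self) -> int:
        return sum(
            1 for v in self.per_subject.values()
            if v["true_group"] == "N" and v["misclassified"]
        )

    @property
    def n_misclassified_chf(self) -> int:
        return sum(
            1 for v in self.per_subject.values()
            if v["true_group"] == "CHF" and v["misclassified"]
        )

    @property
    def n_misclassified(self) -> int:
        return self.n_misclassified_n + self.n_misclassified_chf

    def summary_row(self) -> dict:
        return {
            "feature_set": "+".join(self.config.feature_set),
            "distance": self.config.distance,
            "n_misclassified": self.n_misclassified,
            "n_misclassified_n": self.n_misclassified_n,
            "n_misclassified_chf": self.n_misclassified_chf,
        }

    def to_json_dict(self) -> dict:
        cfg = {
            "distance": self.config.distance,
            "k": self.config.k,
            "window_length": self.config.window_length,
            "train_length": self.config.train_length,
            "mc": self.config.mc,
            "realization_threshold": self.config.realization_threshold,
            "group_threshold": self.config.group_threshold,
            "feature_set": list(self.config.feature_set),
        }
        return {
            "config": cfg,
            "per_subject": {
                sid: {
                    "true_group": v["true_group"],
                    "P": [int(p) for p in v["P"]],
                    "misclassified": bool(v["misclassified"]),
                }
                for sid, v in self.per_subject.items()
            },
            "n_misclassified_n": self.n_misclassified_n,
            "n_misclassified_chf": self.n_misclassified_chf,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))


def window_starts(train_length: int, window_length: int, mc: int) -> np.ndarray:
    """``mc`` evenly spaced window starts spanning [0, train - window]."""
    if window_length > train_length:
        raise ParameterError("window_length must be <= train_length")
    if mc < 1:
        raise ParameterError("mc must be >= 1")
    span = train_length - window_length
    if mc == 1:
        return np.array([0], dtype=int)
    j = np.arange(mc)
    return (j * span) // (mc - 1)


def vote_realizations(p_flags, mc: int | None = None, threshold: float = 0.95) -> int:
    """Subset flag P: 1 iff the wrong fraction strictly exceeds the threshold."""
    p_flags = np.asarray(p_flags)
    if mc is None:
        mc = len(p_flags)
    return int(p_flags.sum() / mc > threshold)


def vote_groups(P_flags, threshold: float = 0.95) -> bool:
    """Subject verdict: misclassified iff flagged-subset fraction strictly exceeds threshold."""
    P_flags = np.asarray(P_flags)
    if len(P_flags) == 0:
        raise ParameterError("need at least one feature subset")
    return bool(P_flags.sum() / len(P_flags) > threshold)


def _regularized_inverse_covariance(X: np.ndarray) -> np.ndarray:
    """Inverse covariance of training rows, ridge-added when near-singular."""
    if X.shape[0] < 2:
        raise InsufficientDataError("need >= 2 training vectors for a covariance")
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    dim = cov.shape[0]
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-10 * max(eigvals[-1], 1e-300):
        lam = RIDGE_FACTOR * np.trace(cov) / dim
        if lam <= 0:
            lam = RIDGE_FACTOR
        logger.debug("near-singular covariance; adding ridge %g", lam)
        cov = cov + lam * np.eye(dim)
    return np.linalg.inv(cov)


def nn_classify(test, train_X, train_y, distance: str = "euclidean", k: int = 1, VI=None) -> str:
    """Label of the majority among the k nearest training vectors.

    Distance ties resolve to the lowest training index (argsort is
    stable); for ``mahalanobis`` the inverse covariance ``VI`` is
    computed from ``train_X`` unless supplied.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test = np.asarray(test, dtype=float).reshape(1, -1)
    if train_X.shape[0] == 0:
        raise ParameterError("training set is empty")
    if not np.all(np.isfinite(train_X)) or not np.all(np.isfinite(test)):
        raise ParameterError("non-finite feature value in classifier input")
    if distance == "euclidean":
        d = cdist(test, train_X, metric="euclidean")[0]
    elif distance == "mahalanobis":
        if VI is None:
            VI = _regularized_inverse_covariance(train_X)
        d = cdist(test, train_X, metric="mahalanobis", VI=VI)[0]
    else:
        raise ParameterError(f"unknown distance {distance!r}")
    order = np.argsort(d, kind="stable")[:k]
    labels, counts = np.unique([train_y[i] for i in order], return_counts=True)
    return str(labels[np.argmax(counts)])


@dataclass(frozen=True)
class SubjectFeatures:
    """Precomputed vectors for one subject: full-length train vector and mc window rows."""

    subject_id: str
    group: str
    train: np.ndarray  # shape (7,)
    tests: np.ndarray  # shape (mc, 7)


def compute_subject_features(series: RRSeries, config: EnsembleConfig, radii: dict | None = None) -> SubjectFeatures:
    """Feature vectors for one subject under the run geometry.

    If the series is shorter than ``train_length`` the longest available
    stretch is used (logged); windows shrink likewise.
    """
    if radii is None:
        radii = DEFAULT_RADII
    x = series.rr_s
    usable = min(len(x), config.train_length)
    if usable < config.train_length:
        logger.info(
            "%s: only %d beats available (train_length=%d); using all of them",
            series.subject_id, usable, config.train_length,
        )
    wl = min(config.window_length, usable)
    train_vec = feature_array(x[:usable], radii)
    starts = window_starts(usable, wl, config.mc)
    tests = np.stack([feature_array(x[s:s + wl], radii) for s in starts])
    return SubjectFeatures(
        subject_id=series.subject_id, group=series.group, train=train_vec, tests=tests
    )


def precompute_features(cohort: list[RRSeries], config: EnsembleConfig, radii: dict | None = None) -> dict[str, SubjectFeatures]:
    """Feature vectors for every cohort member, keyed by subject id."""
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate subject_id in cohort")
    return {s.subject_id: compute_subject_features(s, config, radii) for s in cohort}


def training_arrays(features: dict[str, SubjectFeatures], held_out_id: str, cols) -> tuple[np.ndarray, list[str], list[str]]:
    """Training matrix, labels and ids with the held-out subject excluded.

    Leave-one-out hygiene lives here: the held-out subject's vectors
    never enter the training matrix, hence never the Mahalanobis
    covariance either.
    """
    if held_out_id not in features:
        raise ParameterError(f"held-out subject {held_out_id!r} not in cohort")
    ids = [sid for sid in features if sid != held_out_id]
    X = np.stack([features[sid].train[list(cols)] for sid in ids])
    y = [features[sid].group for sid in ids]
    return X, y, ids


def _classify_held_out(features: dict[str, SubjectFeatures], held_out_id: str, config: EnsembleConfig) -> tuple[bool, np.ndarray]:
    """Vote matrix row and verdict for one held-out subject."""
    subject = features[held_out_id]
    subsets = config.feature_subsets()
    P = np.zeros(len(subsets), dtype=int)
    for j, subset in enumerate(subsets):
        cols = [FEATURE_INDEX[f] for f in subset]
        X, y, _ = training_arrays(features, held_out_id, cols)
        if not np.all(np.isfinite(X)):
            raise ParameterError(
                f"non-finite training feature in subset {subset} "
                f"(held out {held_out_id!r})"
            )
        tests = subject.tests[:, cols]
        mu, sd = None, None
        if config.zscore:
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        VI = None
        if config.distance == "mahalanobis":
            VI = _regularized_inverse_covariance(X)
        p_flags = np.zeros(config.mc, dtype=int)
        for l in range(config.mc):
            t = tests[l]
            if not np.all(np.isfinite(t)):
                # feature unavailable (e.g. empty disc): realization counts wrong
                logger.debug(
                    "%s: non-finite test feature in subset %s, realization %d",
                    held_out_id, subset, l,
                )
                p_flags[l] = 1
                continue
            if config.zscore:
                t = (t - mu) / sd
            pred = nn_classify(t, X, y, distance=config.distance, k=config.k, VI=VI)
            p_flags[l] = int(pred != subject.group)
        P[j] = vote_realizations(p_flags, config.mc, config.realization_threshold)
    misclassified = vote_groups(P, config.group_threshold)
    return misclassified, P


def classify_subject(subject: RRSeries, cohort: list[RRSeries], config: EnsembleConfig, radii: dict | None = None) -> tuple[bool, np.ndarray]:
    """Leave-one-out classification of one subject against the cohort."""
    if all(s.subject_id != subject.subject_id for s in cohort):
        raise ParameterError("cohort must include the test subject")
    features = precompute_features(cohort, config, radii)
    return _classify_held_out(features, subject.subject_id, config)


def run_experiment(cohort: list[RRSeries], configs: list[EnsembleConfig], radii: dict | None = None) -> list[ClassificationReport]:
    """One report per config; feature computation shared across configs
    with identical geometry."""
    if len(cohort) < 2:
        raise ParameterError("need at least 2 subjects")
    cache: dict[tuple, dict[str, SubjectFeatures]] = {}
    reports = []
    for config in configs:
        geom = (config.window_length, config.train_length, config.mc)
        if geom not in cache:
            cache[geom] = precompute_features(cohort, config, radii)
        features = cache[geom]
        report = ClassificationReport(config=config)
        for s in cohort:
            mis, P = _classify_held_out(features, s.subject_id, config)
            report.per_subject[s.subject_id] = {
                "true_group": s.group, "P": P, "misclassified": mis,
            }
        reports.append(report)
    return reports


def table2_configs(
    train_length: int = 70000,
    window_length: int = 30000,
    mc: int = 31,
    feature_sets: list | None = None,
    distances=DISTANCES,
) -> list[EnsembleConfig]:
    """The reported grid: {ctm}, {ctm,d_mean}, all six, {sdrr} x both distances."""
    if feature_sets is None:
        feature_sets = [
            ("ctm",),
            ("ctm", "d_mean"),
            ("ctm", "d_mean", "cctm1", "cctm2", "cctm3", "cctm4"),
            ("sdrr",),
        ]
    base = EnsembleConfig(
        train_length=train_length, window_length=window_length, mc=mc
    )
    return [
        replace(base, feature_set=tuple(fs), distance=d)
        for fs in feature_sets
        for d in distances
    ]


def summary_table(reports: list[ClassificationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.summary_row() for r in reports])


def sdrr_threshold_baseline(feature_table: pd.DataFrame, threshold: float | None = None) -> tuple[int, float]:
    """Misclassification count of the simple SDRR threshold rule.

    Predict CHF iff sdrr < threshold.  When ``threshold`` is None the
    error-minimizing threshold is found over midpoints of the sorted
    sdrr values (plus the extremes); ties go to the smaller threshold.
    Returns (errors, threshold).
    """
    if "sdrr" not in feature_table.columns or "group" not in feature_table.columns:
        raise ParameterError("feature table must have 'sdrr' and 'group' columns")
    vals = feature_table["sdrr"].to_numpy(dtype=float)
    groups = feature_table["group"].to_numpy()
    if not np.all(np.isfinite(vals)):
        raise ParameterError("sdrr missing for some subjects")

    def errors_at(th: float) -> int:
        pred = np.where(vals < th, "CHF", "N")
        return int(np.count_nonzero(pred != groups))

    if threshold is not None:
        return errors_at(float(threshold)), float(threshold)
    u = np.unique(vals)
    candidates = np.concatenate([[u[0]], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    errs = np.array([errors_at(t) for t in candidates])
    best = int(np.argmin(errs))
    return int(errs[best]), float(candidates[best])
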