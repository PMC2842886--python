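"""Two-cohort synthetic RR-interval generator.

The clean signal is a stationary first-order autoregressive (AR(1))
process around ``mean_rr_s``.  AR(1) was chosen because its two natural
scales map one-to-one onto the two axes the downstream features probe:

* long-term SD ``s`` (``sd_base_s``): the stationary SD of the process,
* successive-difference SD ``d`` (``succ_diff_sd_s``): the SD of
  ``x(i+1) - x(i)``.

For AR(1) with coefficient ``phi`` and innovation SD ``sigma``::

    s^2 = sigma^2 / (1 - phi^2)        d^2 = 2 s^2 (1 - phi)

so  ``phi = 1 - d^2 / (2 s^2)``  and  ``sigma = s sqrt(1 - phi^2)``,
valid whenever ``0 < d < 2 s``.  A cohort where the CHF-like group has
the smaller ``succ_diff_sd_s`` reproduces the depressed short-term
variability the analysis assumes.

Optional contamination: a slow sinusoidal trend of given amplitude, and
ectopic beats injected as a short interval (0.6x the local mean)
followed by a compensatory pause (1.4x), replacing a clean pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import NamedTuple

import numpy as np
from scipy.signal import lfilter

from .exceptions import ParameterError
from .rr_io import RRSeries

_GROUP_CODES = {"N": 0, "CHF": 1}

#: short-beat factor applied to the local mean at an ectopic site
ECTOPIC_SHORT_FACTOR = 0.6
#: number of sinusoid cycles spanned by the trend over the full series
TREND_CYCLES = 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic group.

    ``succ_diff_sd_s = 0`` degenerates to a constant series at
    ``mean_rr_s`` (plus any trend/ectopics), which is handy for tests.
    """

    n_subjects_per_group: int
    n_beats: int = 70000
    mean_rr_s: float = 0.8
    sd_base_s: float = 0.05
    succ_diff_sd_s: float = 0.03
    trend_amplitude_s: float = 0.0
    ectopic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ParameterError("n_subjects_per_group must be >= 1")
        if self.n_beats < 3:
            raise ParameterError("n_beats must be >= 3")
        if self.mean_rr_s <= 0:
            raise ParameterError("mean_rr_s must be > 0")
        if self.sd_base_s < 0 or self.succ_diff_sd_s < 0 or self.trend_amplitude_s < 0:
            raise ParameterError("scale parameters must be >= 0")
        if not 0.0 <= self.ectopic_rate < 0.5:
            raise ParameterError("ectopic_rate must be in [0, 0.5)")
        if self.seed < 0:
            raise ParameterError("seed must be a non-negative integer")
        if self.succ_diff_sd_s > 0:
            if self.sd_base_s <= 0:
                raise ParameterError("sd_base_s must be > 0 when succ_diff_sd_s > 0")
            if self.succ_diff_sd_s >= 2 * self.sd_base_s:
                raise ParameterError(
                    "succ_diff_sd_s must be < 2 * sd_base_s for a stationary AR(1)"
                )

    def ar_coefficients(self) -> tuple[float, float]:
        """Return (phi, innovation_sd) implementing (sd_base_s, succ_diff_sd_s)."""
        if self.succ_diff_sd_s == 0:
            return 1.0, 0.0
        phi = 1.0 - self.succ_diff_sd_s**2 / (2.0 * self.sd_base_s**2)
        sigma = self.sd_base_s * np.sqrt(1.0 - phi**2)
        return phi, sigma


class SimulatedSubject(NamedTuple):
    """A generated series plus ground truth for contamination tests."""

    series: RRSeries
    ectopic_starts: np.ndarray  # indices k of injected short beats (pair k, k+1)


def _subject_rng(spec: CohortSpec, group: str, subject_index: int) -> np.random.Generator:
    # Per-subject substream keyed on (seed, group, index): cohorts are
    # order-independent and individual subjects reproducible.
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, _GROUP_CODES[group], subject_index])
    )


def simulate_subject(spec: CohortSpec, group: str, subject_index: int) -> SimulatedSubject:
    """Generate one subject, returning the series and injected-ectopic indices."""
    if group not in _GROUP_CODES:
        raise ParameterError(f"group must be one of {sorted(_GROUP_CODES)}, got {group!r}")
    if subject_index < 0:
        raise ParameterError("subject_index must be >= 0")
    rng = _subject_rng(spec, group, subject_index)
    n = spec.n_beats

    if spec.succ_diff_sd_s == 0:
        x = np.full(n, spec.mean_rr_s)
    else:
        phi, sigma = spec.ar_coefficients()
        z0 = rng.normal(0.0, spec.sd_base_s)
        eps = rng.normal(0.0, sigma, size=n)
        z, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * z0]))
        x = spec.mean_rr_s + z

    if spec.trend_amplitude_s > 0:
        t = np.arange(n, dtype=float)
        x = x + spec.trend_amplitude_s * np.sin(2.0 * np.pi * TREND_CYCLES * t / n)

    ectopic_starts = np.empty(0, dtype=int)
    if spec.ectopic_rate > 0:
        candidates = np.flatnonzero(rng.random(n) < spec.ectopic_rate)
        candidates = candidates[(candidates >= 1) & (candidates <= n - 2)]
        kept: list[int] = []
        clean = x.copy()
        for k in candidates:
            if kept and k - kept[-1] < 2:
                continue  # pair would overlap the previous injection
            lo, hi = max(0, k - 5), min(n, k + 6)
            m = clean[lo:hi].mean()
            x[k] = ECTOPIC_SHORT_FACTOR * m
            x[k + 1] = (2.0 - ECTOPIC_SHORT_FACTOR) * m
            kept.append(int(k))
        ectopic_starts = np.asarray(kept, dtype=int)

    if np.any(x <= 0):
        raise ParameterError(
            "generated series contains non-positive intervals; "
            "parameters are too extreme relative to mean_rr_s"
        )
    series = RRSeries(
        subject_id=f"{group}{subject_index:03d}",
        group=group,
        rr_s=x,
        preprocessed=False,
    )
    return SimulatedSubject(series=series, ectopic_starts=ectopic_starts)


def generate_subject(spec: CohortSpec, group: str, subject_index: int) -> RRSeries:
    """Generate one subject's RR series (see :func:`simulate_subject`)."""
    return simulate_subject(spec, group, subject_index).series


def generate_cohort(spec_n: CohortSpec, spec_chf: CohortSpec) -> list[RRSeries]:
    """Generate a labeled two-group cohort (all N subjects, then all CHF)."""
    cohort = [
        generate_subject(spec_n, "N", i) for i in range(spec_n.n_subjects_per_group)
    ]
    cohort += [
        generate_subject(spec_chf, "CHF", i) for i in range(spec_chf.n_subjects_per_group)
    ]
    return cohort


def paper_like_specs(
    n_subjects_per_group: int = 36,
    n_beats: int = 70000,
    succ_diff_sd_n: float = 0.04,
    succ_diff_sd_chf: float = 0.01,
    sd_base_n: float = 0.05,
    sd_base_chf: float = 0.03,
    seed: int = 0,
    **common,
) -> tuple[CohortSpec, CohortSpec]:
    """Convenience pair of specs with depressed CHF-like variability."""
    if not succ_diff_sd_chf < succ_diff_sd_n:
        raise ParameterError("CHF-like succ_diff_sd must be below the N-like value")
    spec_n = CohortSpec(
        n_subjects_per_group=n_subjects_per_group,
        n_beats=n_beats,
        sd_base_s=sd_base_n,
        succ_diff_sd_s=succ_diff_sd_n,
        seed=seed,
        **common,
    )
    spec_chf = dc_replace(spec_n, sd_base_s=sd_base_chf, succ_diff_sd_s=succ_diff_sd_chf)
    return spec_n, spec_chf
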