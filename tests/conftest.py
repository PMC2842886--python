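import numpy as np
import pytest

from sodphrv.rr_io import RRSeries
from sodphrv.synthetic_rr import generate_cohort, paper_like_specs


@pytest.fixture(scope="session")
def small_cohort():
    """5 N + 5 CHF subjects, 2000 beats, clearly separated variability."""
    spec_n, spec_chf = paper_like_specs(
        n_subjects_per_group=5,
        n_beats=2000,
        succ_diff_sd_n=0.04,
        succ_diff_sd_chf=0.015,
        seed=11,
    )
    return generate_cohort(spec_n, spec_chf)


@pytest.fixture
def constant_series():
    return RRSeries(subject_id="const", group="unknown", rr_s=np.full(50, 0.8))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
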