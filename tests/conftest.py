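import numpy as np
import pytest

from ctgcompress import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A short-duration cohort for feature/pipeline tests (cheap, 1 h)."""
    cfg = CohortConfig(n_nonacidemic=6, n_acidemic=3, duration_min=60.0,
                       jitter_min=0.5, effect_size=1.0, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def full_subject():
    """One full-length (~2 h) subject."""
    cfg = CohortConfig(n_nonacidemic=1, n_acidemic=0, seed=7)
    return generate_cohort(cfg)[0]
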