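import numpy as np
import pytest

from megfp import CANONICAL_BANDS, SyntheticConfig, generate_cohort

# mid-frequency bands keep filter lengths (and test runtimes) small
THETA, ALPHA, BETA, GAMMA = CANONICAL_BANDS[1:5]


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down cohort: 300 Hz, few ROIs, tens of seconds."""
    defaults = dict(
        n_subjects=8,
        n_sessions=2,
        n_rois=4,
        fs=300.0,
        duration=20.0,
        bands=(THETA, ALPHA, BETA),
        n_latents=3,
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
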