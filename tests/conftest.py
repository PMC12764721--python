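import numpy as np
import pytest

from thermoseg.synthio import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort shared across read-only tests."""
    return generate_cohort(SynthConfig(n_dm=8, n_cg=5, seed=42))
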