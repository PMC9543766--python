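import numpy as np
import pytest

from mixsvr.simulate import SynthConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete synthetic cohort (reused read-only)."""
    return generate(SynthConfig(n_patients=12, mean_recordings_per_patient=20,
                                seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
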