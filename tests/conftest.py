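import numpy as np
import pytest

from merdbs.cohort import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def micro_config():
    """Small, fast cohort: low sampling rate, short segments."""
    return CohortConfig(
        seed=42,
        n_patients=10,
        total_segments=30,
        duration_s=0.5,
        sampling_rate_hz=4_000,
        effect_band="50-500",
    )
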