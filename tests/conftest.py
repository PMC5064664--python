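import numpy as np
import pytest

from emgsketch.synthetic import SyntheticConfig, default_profiles, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact labeled session: 4 classes x 5 reps, strong bursts."""
    profiles = default_profiles(4, separation=1.0, seed=7)
    cfg = SyntheticConfig(
        classes=profiles, reps_per_class=5, baseline_sd=0.01, burst_sd=0.08, seed=7
    )
    rec, meta = generate_session(cfg)
    return rec, meta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
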