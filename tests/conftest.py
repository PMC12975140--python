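import numpy as np
import pytest

from m6ahd.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Two-condition synthetic bundle, small enough for unit tests."""
    cfg = SimConfig(n_transcripts=40, transcript_length=2000, n_conditions=2, seed=7)
    seqs, truth = simulate_bundle(cfg)
    return cfg, seqs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
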