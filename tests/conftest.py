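import pytest

from eccmirkit.simulate import SimConfig, simulate_sample_set


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-group simulated experiment shared across tests."""
    cfg = SimConfig(seed=11, n_circles=60, n_mir_circles=6)
    return simulate_sample_set(cfg)
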