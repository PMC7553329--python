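import numpy as np
import pytest

from prsum import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact four-cohort simulated study shared across test modules."""
    cfg = SimConfig(
        n_snps=120,
        splits={"train": 600, "tune1": 300, "tune2": 250, "test": 250},
        block_sizes=[30] * 4,
        within_block_rho=0.5,
        p_causal=0.05,
        h2=0.5,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
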