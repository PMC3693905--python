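import numpy as np
import pytest

from clovermap.popsim import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact two-population study used by several unit tests."""
    cfg = SimConfig(
        rng_seed=11,
        n_chromosome_pairs=2,
        markers_per_group=12,
        population_sizes=(60, 120),
        chromosome_length=80.0,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
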