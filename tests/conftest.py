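import numpy as np
import pytest
from hypothesis import settings

from cordatlas.simulate import SimConfig, simulate_counts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small five-stage dataset with the differentiation axis, reused across tests."""
    cfg = SimConfig(n_cells_per_stage=200, n_genes=300, pseudotime_axis=True, seed=42)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
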