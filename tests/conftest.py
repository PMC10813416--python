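import numpy as np
import pytest

from pbminer.pipeline import annotate_genome
from pbminer.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated genome: 3 families, 3 copies each, mixed divergence."""
    cfg = SimConfig(
        genome_length=250_000,
        n_types=3,
        copies_per_type=3,
        divergence_grid=(0.0, 0.02, 0.05),
        seed=9,
        min_spacing_bp=9_000,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_queries(small_dataset):
    return [t.transposase_prot() for t in small_dataset.templates.values()]


@pytest.fixture(scope="session")
def small_result(small_dataset, small_queries):
    """Full annotation of the small genome (shared across tests)."""
    return annotate_genome(small_dataset.genome, small_queries)
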