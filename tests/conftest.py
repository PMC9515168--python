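import numpy as np
import pytest

from pathdrp.datagen import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=100,
        n_pathways=10,
        pathway_size_range=(8, 12),
        n_cell_samples=120,
        n_tumor_samples=40,
        n_drugs=3,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
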