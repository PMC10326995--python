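import numpy as np
import pytest

from iqtl.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small gxcell cohort shared by read-only tests."""
    config = SimulationConfig(
        n_samples=150,
        n_phenotypes=6,
        variants_per_phenotype=10,
        scenario="gxcell",
        b_gxe=1.0,
        noise_sd=0.6,
        maf_range=(0.15, 0.5),
        seed=7,
    )
    bundle, truth = simulate_dataset(config)
    return config, bundle, truth
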