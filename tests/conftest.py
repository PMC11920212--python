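import numpy as np
import pytest

import perturbatlas as pa


@pytest.fixture(scope="session")
def small_library():
    return pa.synthetic_data.gen_library(5, clones_per_genotype=2, seed=2)


@pytest.fixture(scope="session")
def small_sim(small_library):
    cfg = pa.SimConfig(
        n_genotypes=5, n_cells_per_genotype=30, n_genes=150, seed=2
    )
    adata, truth = pa.synthetic_data.gen_counts(small_library, cfg)
    return cfg, adata, truth


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(0)
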