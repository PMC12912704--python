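import numpy as np
import pytest

from stimpute.core_data import ExpressionMatrix, Modality
from stimpute.synthetic import SimConfig, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        values=np.array([[0.0, 1.0], [2.0, 3.0]]),
        gene_names=["gA", "gB"],
        cell_names=["c1", "c2"],
        modality=Modality.SCRNA,
    )


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated reference/ST pair shared across tests."""
    cfg = SimConfig(
        n_ref_cells=80, n_st_cells=40, n_genes=20, n_modules=4,
        shared_fraction=0.6, noise_sd=0.05, seed=7,
    )
    return simulate_pair(cfg)
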