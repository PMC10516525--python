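import numpy as np
import pytest
import scipy.sparse as sp

from cicada.io_formats import CellExpressionMatrix
from cicada.simulate import SimulationConfig, simulate_singlecell, reference_from_simulation


def make_counts(n_genes: int, n_cells: int, seed: int = 0, max_count: int = 20) -> CellExpressionMatrix:
    """Small random count matrix with ~50% zeros."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, max_count, size=(n_genes, n_cells))
    x[rng.random(x.shape) < 0.5] = 0
    return CellExpressionMatrix(
        sp.csc_matrix(x),
        np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        np.array([f"c{j}" for j in range(n_cells)], dtype=object),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated dataset shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    return cfg, *simulate_singlecell(cfg)


@pytest.fixture(scope="session")
def default_gene_sets(default_sim):
    import cicada

    cfg = default_sim[0]
    return cicada.build_gene_sets(reference_from_simulation(cfg), 3.0)
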