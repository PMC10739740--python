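import numpy as np
import pandas as pd
import pytest

from comodmr.matrix import ExpressionMatrix
from comodmr.simulate import SimConfig


@pytest.fixture
def two_module_config():
    """Two planted 50-gene modules at loading 0.8 over 43 samples."""
    return SimConfig(
        seed=1,
        n_genes=400,
        module_sizes=(50, 50),
        n_assoc_modules=1,
        within_module_cor=0.8,
        n_celltypes=2,
        dirichlet_alpha=(6.0, 3.0),
        marker_genes_per_type=10,
        n_ppi_nodes=100,
    )


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(0)
    vals = rng.poisson(50, size=(30, 12))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=pd.Index([f"G{i:03d}" for i in range(30)], name="gene"),
            columns=[f"S{i:02d}" for i in range(12)],
        )
    )


@pytest.fixture
def random_expression():
    def make(n_genes=40, n_samples=20, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(n_genes, n_samples)),
                index=pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene"),
                columns=[f"S{i:02d}" for i in range(n_samples)],
            ),
            layer="transformed",
        )

    return make
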