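import numpy as np
import pytest

import chlnmf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    """Clean 60 genes x 40 cells, 3 planted clusters — fast end-to-end runs."""
    spec = chlnmf.SyntheticSpec(
        n_genes=60, n_cells=40, n_clusters=3, marker_genes_per_cluster=5, seed=7
    )
    return chlnmf.generate(spec)


@pytest.fixture
def default_dataset():
    """The standard benchmark condition (200 x 120, 3 clusters, no outliers)."""
    return chlnmf.generate(chlnmf.SyntheticSpec(seed=0))


def random_instance(seed, m=10, n=8, k=2):
    """A random non-negative matrix with seeded factors for update tests."""
    r = np.random.default_rng(seed)
    X = r.uniform(0, 2, size=(m, n))
    U = r.uniform(0.1, 1, size=(m, k))
    V = r.uniform(0.1, 1, size=(k, n))
    return X, U, V
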